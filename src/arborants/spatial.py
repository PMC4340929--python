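"""Spatial null model for foraging-but-not-nesting (F-N) ant records.

The question: do species foraging (but not nesting) in a tree nest
closer in the surrounding trees than expected if nests were shuffled
over trees at random, keeping each species' number of nest trees and
each tree's number of nesting species fixed?

Three observed statistics
-------------------------
* nearest-nest distance per F-N record (tree, species): the distance
  from the focal trunk to the nearest other trunk holding a nest of
  that species;
* the empirical cumulative curve of those distances;
* the nesting-probability profile: for radii d = 5, 10, ..., 30 m, the
  proportion of trees within d of the focal tree (focal excluded) that
  hold a nest of the record's species, averaged over records — this
  normalises by local tree density.

The null holds the F-N record set fixed and redraws only the nest
matrix by fixed-marginal randomization (quasiswap via curveball
trades), recomputing each statistic per draw.  Envelopes are empirical
2.5–97.5% order statistics across draws (plus the min–max band); the
observed mean is also ranked within the null means (two-sided
empirical p) and compared by a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .data import CommunityDataset, DataError, derive_fn_records, pairwise_distances

__all__ = [
    "DEFAULT_RADII",
    "DEFAULT_GRID_STEP",
    "nearest_nest_distances",
    "cumulative_curve",
    "nesting_probability_profile",
    "quasiswap_randomize",
    "NullModelResult",
    "null_test",
]

#: Maximum-distance radii (m) for the nesting-probability profile.
DEFAULT_RADII = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
DEFAULT_GRID_STEP = 1.0


# ---------------------------------------------------------------------------
# observed statistics (low-level kernels operate on integer-indexed arrays)


def _nearest_distances_array(
    D: np.ndarray, N: np.ndarray, t_idx: np.ndarray, s_idx: np.ndarray
) -> np.ndarray:
    """Per-record min over trees u != focal with N[u, s] = 1 of D[focal, u].

    Records whose species has no nest on any other tree (possible only
    for randomized layers placing a single nest on the focal tree) come
    back as +inf and are dropped from means by the callers.
    """
    out = np.full(t_idx.size, np.inf)
    for sp in np.unique(s_idx):
        cand = np.flatnonzero(N[:, sp])
        if cand.size == 0:
            continue
        rows = np.flatnonzero(s_idx == sp)
        sub = D[np.ix_(t_idx[rows], cand)]
        sub = np.where(cand[None, :] == t_idx[rows][:, None], np.inf, sub)
        out[rows] = sub.min(axis=1)
    return out


def _records_indices(
    ds: CommunityDataset, plot: str, records: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    nest = ds.layer("nest", plot)
    t_idx = nest.index.get_indexer(records["tree_id"])
    s_idx = nest.columns.get_indexer(records["species_code"])
    if (t_idx < 0).any() or (s_idx < 0).any():
        raise DataError("F-N records refer to unknown trees or species")
    return t_idx.astype(int), s_idx.astype(int), nest


def nearest_nest_distances(
    ds: CommunityDataset, plot: str, records: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Distance (m) from each F-N record's tree to the nearest nest of its species.

    Returns columns ``tree_id``, ``species_code``, ``distance_m``.  By
    the F-N definition the focal tree holds no nest of the species, so
    every distance is > 0 and always defined (every F-N species nests
    on >= 1 tree of the plot).
    """
    if records is None:
        records = derive_fn_records(ds, plot)
    t_idx, s_idx, nest = _records_indices(ds, plot, records)
    D = pairwise_distances(ds, plot).values
    d = _nearest_distances_array(D, nest.to_numpy(np.int8), t_idx, s_idx)
    return pd.DataFrame(
        {
            "tree_id": records["tree_id"].to_numpy(),
            "species_code": records["species_code"].to_numpy(),
            "distance_m": d,
        }
    )


def cumulative_curve(
    distances: pd.DataFrame | np.ndarray, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Empirical CDF of nearest-nest distances over an evaluation grid.

    Default grid: 0..max(30, ceil(max distance)) m in 1 m steps, so the
    curve always reaches 1 at its last point.
    """
    d = (
        distances["distance_m"].to_numpy()
        if isinstance(distances, pd.DataFrame)
        else np.asarray(distances, dtype=float)
    )
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise DataError("no F-N records: cumulative curve undefined")
    if grid is None:
        top = max(30.0, float(np.ceil(d.max())))
        grid = np.arange(0.0, top + DEFAULT_GRID_STEP / 2, DEFAULT_GRID_STEP)
    grid = np.asarray(grid, dtype=float)
    cum = np.searchsorted(np.sort(d), grid, side="right") / d.size
    return pd.DataFrame({"grid_m": grid, "cumulative": cum})


def _profile_arrays(
    within: list[np.ndarray], N: np.ndarray, t_idx: np.ndarray, s_idx: np.ndarray
) -> np.ndarray:
    """Per-radius mean of per-record nesting probabilities.

    ``within[r]`` is the boolean tree-by-tree reachability matrix at
    radius r with a False diagonal (focal tree excluded from numerator
    and denominator).  Records with no tree inside the radius are
    skipped at that radius.
    """
    out = np.full(len(within), np.nan)
    denom_all = [w.sum(axis=1) for w in within]
    for r, W in enumerate(within):
        denom = denom_all[r][t_idx].astype(float)
        num = np.zeros(t_idx.size)
        for sp in np.unique(s_idx):
            cand = np.flatnonzero(N[:, sp])
            rows = np.flatnonzero(s_idx == sp)
            if cand.size:
                num[rows] = W[np.ix_(t_idx[rows], cand)].sum(axis=1)
        ok = denom > 0
        if ok.any():
            out[r] = float(np.mean(num[ok] / denom[ok]))
    return out


def nesting_probability_profile(
    ds: CommunityDataset,
    plot: str,
    radii: tuple[float, ...] = DEFAULT_RADII,
    records: pd.DataFrame | None = None,
    per_tree: bool = False,
) -> pd.DataFrame:
    """Mean probability of finding a nest of an F-N species within each radius.

    For record (t, s) and radius d the probability is
    (# trees u != t with dist(t, u) <= d holding a nest of s) /
    (# trees u != t with dist(t, u) <= d); the per-radius mean runs
    over records with a nonzero denominator.  ``per_tree=True``
    averages records within each focal tree first (sensitivity mode);
    the default record-level mean weighs every (tree, species) pair
    equally.

    Returns columns ``radius_m``, ``mean_probability``, ``n_records``.
    """
    radii = tuple(float(r) for r in radii)
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    if records is None:
        records = derive_fn_records(ds, plot)
    t_idx, s_idx, nest = _records_indices(ds, plot, records)
    D = pairwise_distances(ds, plot).values
    within = []
    for r in radii:
        W = D <= r
        np.fill_diagonal(W, False)
        within.append(W)
    N = nest.to_numpy(np.int8)

    rows = []
    for r, W in zip(radii, within):
        denom = W.sum(axis=1)[t_idx].astype(float)
        num = np.zeros(t_idx.size)
        for sp in np.unique(s_idx):
            cand = np.flatnonzero(N[:, sp])
            rws = np.flatnonzero(s_idx == sp)
            if cand.size:
                num[rws] = W[np.ix_(t_idx[rws], cand)].sum(axis=1)
        ok = denom > 0
        if not ok.any():
            rows.append({"radius_m": r, "mean_probability": np.nan, "n_records": 0})
            continue
        p = num[ok] / denom[ok]
        if per_tree:
            mean = float(pd.Series(p).groupby(t_idx[ok]).mean().mean())
        else:
            mean = float(p.mean())
        rows.append({"radius_m": r, "mean_probability": mean, "n_records": int(ok.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixed-marginal randomization


def quasiswap_randomize(
    matrix: pd.DataFrame | np.ndarray,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    n_trades: int | None = None,
):
    """Randomize a binary matrix keeping all row and column sums fixed.

    Implemented with curveball trades: repeatedly pick two rows and
    redistribute the columns held by exactly one of them uniformly at
    random between the two, preserving both row degrees and every
    column's degree.  Run long enough (default: 10x the number of 1s in
    the matrix, at least 100 attempts) this samples (approximately)
    uniformly from the set of matrices sharing the observed marginals.
    Each call mixes afresh from the input, so successive draws are
    independent given the marginals.

    A matrix admitting no 2x2 checkerboard submatrix has a singleton
    margin class and is returned unchanged.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    A = matrix.to_numpy() if is_frame else np.asarray(matrix)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("quasiswap requires a binary matrix")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = A.shape[0]
    nnz = int(A.sum())
    if n_trades is None:
        n_trades = max(10 * nnz, 100)
    if m < 2 or nnz == 0:
        out = A.copy()
    else:
        row_sets = [set(np.flatnonzero(A[i]).tolist()) for i in range(m)]
        # pre-draw the row pairs in one call; per-trade draws dominate runtime
        ii = rng.integers(0, m, size=n_trades)
        jj = rng.integers(0, m - 1, size=n_trades)
        jj = jj + (jj >= ii)
        for i, j in zip(ii, jj):
            si, sj = row_sets[i], row_sets[j]
            only_i = si - sj
            only_j = sj - si
            if not only_i or not only_j:
                continue
            pool = np.fromiter(only_i | only_j, dtype=np.int64)
            rng.shuffle(pool)
            k = len(only_i)
            common = si & sj
            row_sets[i] = common | set(pool[:k].tolist())
            row_sets[j] = common | set(pool[k:].tolist())
        out = np.zeros_like(A)
        for i, s in enumerate(row_sets):
            if s:
                out[i, list(s)] = 1
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def _envelope(values: np.ndarray, lo: float = 0.025, hi: float = 0.975) -> tuple[float, float]:
    """Nearest-rank order-statistic envelope (3rd and 98th of 100 draws)."""
    srt = np.sort(values)
    n = srt.size
    i_lo = max(int(np.ceil(lo * n)) - 1, 0)
    i_hi = min(int(np.ceil(hi * n)) - 1, n - 1)
    return float(srt[i_lo]), float(srt[i_hi])


def _rank_p(observed: float, null_values: np.ndarray) -> float:
    """Two-sided empirical rank p of the observed value within the null draws."""
    n = null_values.size
    r_low = 1 + int(np.sum(null_values <= observed))
    r_high = 1 + int(np.sum(null_values >= observed))
    return min(1.0, 2.0 * min(r_low, r_high) / (n + 1))


@dataclass
class NullModelResult:
    """One plot's null-model comparison for one statistic.

    ``table`` holds the per-grid-point (curve) or per-radius (profile)
    observed value, null mean, 2.5–97.5% envelope, min–max band and an
    outside-envelope flag.  The scalar fields compare the headline
    observed mean (mean nearest-nest distance for the curve statistic;
    the smallest-radius mean probability for the profile) with the null
    means: empirical two-sided rank p and a rank-sum test (the
    Mann-Whitney-Wilcoxon style comparison of the observed mean against
    the per-permutation means).
    """

    plot: str
    statistic: str
    n_perm: int
    seed: int | None
    observed_mean: float
    null_means: np.ndarray
    rank_p: float
    ranksum_stat: float
    ranksum_p: float
    outside_envelope: bool
    table: pd.DataFrame
    fn_distances: pd.DataFrame = field(repr=False, default=None)

    def report(self) -> pd.DataFrame:
        env_lo, env_hi = _envelope(self.null_means)
        return pd.DataFrame(
            [
                {
                    "plot": self.plot,
                    "statistic": self.statistic,
                    "observed_mean": self.observed_mean,
                    "null_mean": float(np.mean(self.null_means)),
                    "env_lo": env_lo,
                    "env_hi": env_hi,
                    "outside_envelope": self.outside_envelope,
                    "rank_p": self.rank_p,
                    "ranksum_stat": self.ranksum_stat,
                    "ranksum_p": self.ranksum_p,
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                }
            ]
        )


def null_test(
    ds: CommunityDataset,
    plot: str,
    statistic: str = "nearest_distance_curve",
    n_perm: int = 100,
    seed: int | None = None,
    radii: tuple[float, ...] = DEFAULT_RADII,
    grid: np.ndarray | None = None,
    per_tree: bool = False,
) -> NullModelResult:
    """Fixed-marginal permutation test of one spatial statistic for one plot.

    The F-N record set stays at its observed value; only the nest layer
    is randomized (per plot, independently per draw from the observed
    matrix).  If a randomized nest lands on a record's focal tree the
    nearest distance is still taken over the other trees, keeping the
    observed and null computations structurally identical.  Species
    flagged ``exclude_from_spatial`` are dropped before both.

    statistic:
        ``nearest_distance_curve`` — cumulative nearest-nest distance
        curve; headline scalar is the mean nearest distance (m).
        ``probability_profile`` — per-radius mean nesting probability;
        headline scalar is the smallest-radius mean.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if statistic not in ("nearest_distance_curve", "probability_profile"):
        raise ValueError(f"unknown statistic {statistic!r}")
    records = derive_fn_records(ds, plot, apply_exclusions=True)
    if records.empty:
        raise DataError(f"no F-N records in plot {plot!r}; null test undefined")
    t_idx, s_idx, nest = _records_indices(ds, plot, records)
    D = pairwise_distances(ds, plot).values
    N_obs = nest.to_numpy(np.int8)
    row_sums, col_sums = N_obs.sum(axis=1), N_obs.sum(axis=0)

    if statistic == "nearest_distance_curve":
        d_obs = _nearest_distances_array(D, N_obs, t_idx, s_idx)
        observed_mean = float(d_obs[np.isfinite(d_obs)].mean())
        if grid is None:
            top = max(30.0, float(np.ceil(d_obs[np.isfinite(d_obs)].max())))
            grid = np.arange(0.0, top + DEFAULT_GRID_STEP / 2, DEFAULT_GRID_STEP)
        grid = np.asarray(grid, dtype=float)
        obs_curve = cumulative_curve(d_obs, grid)["cumulative"].to_numpy()
    else:
        radii = tuple(float(r) for r in radii)
        if any(r <= 0 for r in radii):
            raise ValueError("radii must be positive")
        within = []
        for r in radii:
            W = D <= r
            np.fill_diagonal(W, False)
            within.append(W)
        obs_profile = _profile_arrays(within, N_obs, t_idx, s_idx)
        observed_mean = float(obs_profile[0])

    ss = np.random.SeedSequence(seed)
    null_means = np.empty(n_perm)
    if statistic == "nearest_distance_curve":
        null_curves = np.empty((n_perm, grid.size))
    else:
        null_profiles = np.empty((n_perm, len(radii)))
    for k, child in enumerate(ss.spawn(n_perm)):
        rng = np.random.default_rng(child)
        N_k = quasiswap_randomize(N_obs, rng=rng)
        if not (np.array_equal(N_k.sum(axis=1), row_sums) and np.array_equal(N_k.sum(axis=0), col_sums)):
            raise AssertionError("randomization broke the marginal totals")
        if statistic == "nearest_distance_curve":
            d_k = _nearest_distances_array(D, N_k, t_idx, s_idx)
            finite = np.isfinite(d_k)
            null_means[k] = float(d_k[finite].mean())
            null_curves[k] = cumulative_curve(d_k[finite], grid)["cumulative"].to_numpy()
        else:
            prof_k = _profile_arrays(within, N_k, t_idx, s_idx)
            null_profiles[k] = prof_k
            null_means[k] = float(prof_k[0])

    env_lo, env_hi = _envelope(null_means)
    outside = bool(observed_mean < env_lo or observed_mean > env_hi)
    mw = mannwhitneyu([observed_mean], null_means, alternative="two-sided", method="exact")

    if statistic == "nearest_distance_curve":
        lo = np.empty(grid.size)
        hi = np.empty(grid.size)
        for g in range(grid.size):
            lo[g], hi[g] = _envelope(null_curves[:, g])
        table = pd.DataFrame(
            {
                "grid_m": grid,
                "observed_cum": obs_curve,
                "null_mean": null_curves.mean(axis=0),
                "null_min": null_curves.min(axis=0),
                "null_max": null_curves.max(axis=0),
                "env_lo": lo,
                "env_hi": hi,
            }
        )
        table["outside_envelope"] = (table["observed_cum"] < table["env_lo"]) | (
            table["observed_cum"] > table["env_hi"]
        )
        fn_dist = pd.DataFrame(
            {
                "tree_id": records["tree_id"].to_numpy(),
                "species_code": records["species_code"].to_numpy(),
                "distance_m": d_obs,
            }
        )
    else:
        lo = np.empty(len(radii))
        hi = np.empty(len(radii))
        for g in range(len(radii)):
            lo[g], hi[g] = _envelope(null_profiles[:, g])
        table = pd.DataFrame(
            {
                "radius_m": np.asarray(radii),
                "observed_mean": obs_profile,
                "null_mean": null_profiles.mean(axis=0),
                "null_min": null_profiles.min(axis=0),
                "null_max": null_profiles.max(axis=0),
                "env_lo": lo,
                "env_hi": hi,
            }
        )
        table["outside_envelope"] = (table["observed_mean"] < table["env_lo"]) | (
            table["observed_mean"] > table["env_hi"]
        )
        table["rank_p"] = [
            _rank_p(o, null_profiles[:, g]) for g, o in enumerate(obs_profile)
        ]
        fn_dist = None

    return NullModelResult(
        plot=plot,
        statistic=statistic,
        n_perm=n_perm,
        seed=seed,
        observed_mean=observed_mean,
        null_means=null_means,
        rank_p=_rank_p(observed_mean, null_means),
        ranksum_stat=float(mw.statistic),
        ranksum_p=float(mw.pvalue),
        outside_envelope=outside,
        table=table,
        fn_distances=fn_dist,
    )
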