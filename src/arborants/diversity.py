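"""Incidence-based diversity statistics.

Sample-based rarefaction (the analytic Mao Tau expectation), the Chao2
nonparametric richness estimator with its incidence variance, per-tree
richness tables by record layer, shared-species counts between plots,
and occupancy/abundance summaries.

Trees are the sampling units throughout; incidence frequency ``Y_i`` of
species *i* is the number of trees containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import CommunityDataset, derive_fn_records

__all__ = [
    "IncidenceSummary",
    "incidence_summary",
    "mao_tau",
    "rarefaction_curve",
    "Chao2Result",
    "chao2",
    "chao2_accumulation",
    "RichnessTable",
    "per_tree_richness",
    "richness_table",
    "shared_species",
    "occupancy_and_abundance_summary",
    "RICHNESS_LAYERS",
]

RICHNESS_LAYERS = ("all", "nest", "forage", "fn")


@dataclass(frozen=True)
class IncidenceSummary:
    """Sufficient statistics of an incidence matrix for richness estimation.

    H: number of samples (trees); S_obs: observed species; Y: per-species
    incidence frequencies (species with Y_i = 0 dropped); q1/q2: number of
    uniques / duplicates (species in exactly one / two samples).
    """

    H: int
    S_obs: int
    Y: np.ndarray
    q1: int
    q2: int


def incidence_summary(matrix: pd.DataFrame | np.ndarray) -> IncidenceSummary:
    """Summarise a binary samples-by-species matrix (rows = trees)."""
    vals = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("incidence matrix must be binary")
    H = int(vals.shape[0])
    Y = vals.sum(axis=0).astype(int)
    Y = Y[Y > 0]
    return IncidenceSummary(
        H=H,
        S_obs=int(Y.size),
        Y=Y,
        q1=int(np.sum(Y == 1)),
        q2=int(np.sum(Y == 2)),
    )


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    """log C(n, k) with C(n, k) := 0 (log -> -inf) when k > n."""
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(n >= k, out, -np.inf)


def mao_tau(summary: IncidenceSummary, h: int) -> float:
    """Expected richness in a random subset of ``h`` of the ``H`` samples.

    tau(h) = sum_i [1 - C(H - Y_i, h) / C(H, h)], the exact
    hypergeometric expectation of the sample-based accumulation curve;
    binomial coefficients are evaluated in log space.
    """
    H = summary.H
    if not 1 <= h <= H:
        raise ValueError(f"h must lie in [1, {H}], got {h}")
    log_denom = _log_choose(np.array([H]), float(h))[0]
    log_num = _log_choose(H - summary.Y, float(h))
    absent_prob = np.exp(log_num - log_denom)  # exp(-inf) -> 0
    return float(np.sum(1.0 - absent_prob))


def rarefaction_curve(
    summary: IncidenceSummary, sample_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Mao Tau expectation over a grid of sample counts (default 1..H)."""
    if sample_grid is None:
        sample_grid = np.arange(1, summary.H + 1)
    grid = np.asarray(sample_grid, dtype=int)
    tau = np.array([mao_tau(summary, int(h)) for h in grid])
    return pd.DataFrame({"h": grid, "tau": tau})


@dataclass(frozen=True)
class Chao2Result:
    estimate: float
    sd: float
    variant: str          # variant requested
    variant_used: str     # after any q2 = 0 fallback
    S_obs: int


def chao2(summary: IncidenceSummary, variant: str = "classic") -> Chao2Result:
    """Chao2 incidence-based richness estimate with analytic SD.

    ``classic`` uses S_obs + A * q1^2 / (2 q2) with the small-sample
    factor A = (H - 1) / H; ``bias_corrected`` uses
    S_obs + A * q1 (q1 - 1) / (2 (q2 + 1)).  The SD comes from the
    matching incidence variance (Chao 1987).  With q2 = 0 the classic
    form is undefined and falls back to bias_corrected with a warning.
    The estimate never falls below S_obs.
    """
    if variant not in ("classic", "bias_corrected"):
        raise ValueError(f"unknown Chao2 variant {variant!r}")
    H, S, q1, q2 = summary.H, summary.S_obs, summary.q1, summary.q2
    if H < 1:
        raise ValueError("need at least one sample")
    A = (H - 1) / H if H > 0 else 0.0
    used = variant
    if variant == "classic" and q2 == 0:
        warnings.warn("Chao2 classic undefined at q2 = 0; using bias_corrected", stacklevel=2)
        used = "bias_corrected"

    if q1 == 0:
        # no undetected-species signal; variance of the correction term is 0
        return Chao2Result(float(S), 0.0, variant, used, S)

    if used == "classic":
        est = S + A * q1 * q1 / (2.0 * q2)
        r = q1 / q2
        var = q2 * (0.5 * A * r**2 + A**2 * r**3 + 0.25 * A**2 * r**4)
    else:
        est = S + A * q1 * (q1 - 1) / (2.0 * (q2 + 1))
        var = (
            0.5 * A * q1 * (q1 - 1) / (q2 + 1)
            + 0.25 * A**2 * q1 * (2 * q1 - 1) ** 2 / (q2 + 1) ** 2
            + 0.25 * A**2 * q1**2 * q2 * (q1 - 1) ** 2 / (q2 + 1) ** 4
        )
    est = max(float(est), float(S))
    return Chao2Result(est, float(np.sqrt(max(var, 0.0))), variant, used, S)


def chao2_accumulation(
    matrix: pd.DataFrame | np.ndarray,
    n_randomizations: int = 100,
    seed: int | None = None,
    variant: str = "classic",
) -> pd.DataFrame:
    """Chao2 along the accumulation curve, averaged over sample orderings.

    For each accumulation level h the estimator is computed on the
    first h samples of ``n_randomizations`` random orderings (the
    EstimateS-style randomization).  At h = H all orderings agree, so
    the across-ordering SD collapses to zero there; the analytic SD of
    :func:`chao2` is the full-sample uncertainty.

    Returns columns ``h``, ``chao2_mean``, ``chao2_sd``.
    """
    vals = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    H = vals.shape[0]
    rng = np.random.default_rng(seed)
    ests = np.empty((n_randomizations, H))
    for r in range(n_randomizations):
        order = rng.permutation(H)
        cum = np.cumsum(vals[order], axis=0)
        for h in range(1, H + 1):
            Y = cum[h - 1]
            Y = Y[Y > 0]
            s = IncidenceSummary(
                H=h, S_obs=int(Y.size), Y=Y,
                q1=int(np.sum(Y == 1)), q2=int(np.sum(Y == 2)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ests[r, h - 1] = chao2(s, variant=variant).estimate
    return pd.DataFrame(
        {
            "h": np.arange(1, H + 1),
            "chao2_mean": ests.mean(axis=0),
            "chao2_sd": ests.std(axis=0, ddof=1) if n_randomizations > 1 else np.zeros(H),
        }
    )


# ---------------------------------------------------------------------------
# per-tree richness


@dataclass(frozen=True)
class RichnessTable:
    """Per-tree species counts for one layer with plot-level summaries."""

    plot: str
    layer: str
    per_tree: pd.Series  # indexed by tree_id, integer counts (ant-free trees = 0)
    mean: float
    se: float
    max: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tree_id": self.per_tree.index, "layer": self.layer, "count": self.per_tree.values}
        )


def _layer_matrix(ds: CommunityDataset, plot: str, layer: str) -> pd.DataFrame:
    """Binary matrix for a derived layer: all (union), nest, forage or fn.

    The fn layer marks species foraging-but-not-nesting on the tree that
    hold >= 1 nest in the plot (the tabulation convention: no
    spatial-exclusion flag applied).
    """
    nest = ds.layer("nest", plot)
    forage = ds.layer("forage", plot)
    if layer == "nest":
        return nest
    if layer == "forage":
        return forage
    if layer == "all":
        return ((nest + forage) > 0).astype(np.int8)
    if layer == "fn":
        recs = derive_fn_records(ds, plot, apply_exclusions=False)
        vals = np.zeros(nest.shape, dtype=np.int8)
        if len(recs):
            ti = nest.index.get_indexer(recs["tree_id"])
            si = nest.columns.get_indexer(recs["species_code"])
            vals[ti, si] = 1
        return pd.DataFrame(vals, index=nest.index, columns=nest.columns)
    raise ValueError(f"unknown layer {layer!r}; expected one of {RICHNESS_LAYERS}")


def per_tree_richness(ds: CommunityDataset, plot: str, layer: str = "all") -> RichnessTable:
    """Species count per tree for one layer, with mean +/- SE and max.

    Trees without any ants enter with a count of 0; the mean and SE are
    over all trees of the plot, on untransformed counts.
    """
    mat = _layer_matrix(ds, plot, layer)
    counts = mat.sum(axis=1).astype(int)
    n = len(counts)
    mean = float(counts.mean()) if n else float("nan")
    se = float(counts.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return RichnessTable(
        plot=plot, layer=layer, per_tree=counts, mean=mean, se=se,
        max=int(counts.max()) if n else 0,
    )


def richness_table(ds: CommunityDataset, plot: str) -> pd.DataFrame:
    """Summary over all four layers: mean, SE, max per-tree richness plus S_obs."""
    rows = []
    for layer in RICHNESS_LAYERS:
        rt = per_tree_richness(ds, plot, layer)
        s_obs = int((_layer_matrix(ds, plot, layer).sum(axis=0) > 0).sum())
        rows.append(
            {
                "plot": plot, "layer": layer, "S_obs": s_obs,
                "mean_per_tree": rt.mean, "se_per_tree": rt.se, "max_per_tree": rt.max,
            }
        )
    return pd.DataFrame(rows)


def shared_species(
    ds: CommunityDataset,
    plot_a: str,
    plot_b: str,
    layers: tuple[str, ...] = ("nest", "forage"),
) -> tuple[int, list[str]]:
    """Species with >= 1 occurrence (union of layers) in both plots."""
    present = []
    for plot in (plot_a, plot_b):
        union = np.zeros(len(ds.species), dtype=bool)
        for kind in layers:
            union |= ds.layer(kind, plot).sum(axis=0).to_numpy() > 0
        present.append(union)
    both = present[0] & present[1]
    codes = sorted(ds.species.index[both])
    return len(codes), codes


def occupancy_and_abundance_summary(ds: CommunityDataset, plot: str) -> dict:
    """Per-species occupancy by layer plus count-layer totals and invasive shares.

    Occupancy is the number of occupied trees (column sums).  Totals of
    nests / forager individuals come from the optional count layers and
    are reported as None when absent.  Invasive fractions are the share
    of occurrences (and of individuals, when counts exist) belonging to
    species flagged invasive.
    """
    per_species = pd.DataFrame(index=ds.species.index)
    for kind in ("nest", "forage"):
        per_species[f"occ_{kind}"] = ds.layer(kind, plot).sum(axis=0)
    per_species["occ_all"] = (
        ((ds.layer("nest", plot) + ds.layer("forage", plot)) > 0).sum(axis=0)
    )
    per_species["invasive"] = ds.species["invasive"]

    totals: dict[str, float | None] = {}
    invasive = ds.species["invasive"].to_numpy(bool)
    for kind in ("nest", "forage"):
        if kind in ds.counts:
            col = ds.counts[kind].loc[ds.plot_tree_ids(plot)].sum(axis=0)
            per_species[f"n_{kind}_records"] = col
            totals[f"total_{kind}"] = int(col.sum())
            totals[f"invasive_fraction_{kind}_individuals"] = (
                float(col[invasive].sum() / col.sum()) if col.sum() else float("nan")
            )
        else:
            totals[f"total_{kind}"] = None
    occ = per_species["occ_all"]
    totals["invasive_fraction_occurrences"] = (
        float(occ[invasive].sum() / occ.sum()) if occ.sum() else float("nan")
    )
    top5 = per_species.sort_values("occ_forage", ascending=False).head(5)
    return {"per_species": per_species, "totals": totals, "top5_foragers": top5}
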