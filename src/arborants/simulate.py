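"""Synthetic stem maps and ant incidence layers with known spatial structure.

The generator emulates the study conditions the pipeline targets: a
rectangular 40 x 80 m rainforest plot of a few hundred mapped stems
with a right-skewed DBH distribution, a species pool whose nest
occupancies follow a log-series (one to three common species, a long
tail of rare ones), nests optionally aggregated in space, and foraging
incidences produced mechanistically from the nests through an
exponential distance-decay kernel plus a uniform "tourist" component
(foragers arriving independently of any in-plot nest — out-of-plot or
ground-level colonies).

Because foraging is generated *from* nests, recovering the spatial
signal with the permutation null is a genuine inference problem, and
switching the kernel off (``emission_rate = 0``) gives an exact
no-signal regime for calibrating the test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import CommunityDataset, combine_plots

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "PRESETS",
    "preset_config",
    "generate_forest",
    "generate_nest_layer",
    "generate_forage_layer",
    "generate_community",
    "two_plot_study",
]

#: Genus stubs used to mint species codes in the field's 4-letter + 3-digit style.
_GENUS_STUBS = (
    "CAMP", "CREM", "POLY", "ANON", "TECH", "PHEI", "TETR", "MONO",
    "RHYT", "ODON", "APHA", "LORD", "STRU", "VOLL", "ACRO", "MYRM",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic plot.

    Spatial units are metres; the plot is the rectangle
    [0, width] x [0, height].

    position:
        ``"uniform"`` scatters trunks uniformly; ``"thomas"`` uses a
        Thomas cluster process (``thomas_parents`` cluster centres,
        Gaussian offspring scatter of SD ``thomas_sd``).
    logseries_p:
        Parameter of the log-series draw of per-species nest-tree
        occupancy (closer to 1 = more skew, longer rare tail).
    nest_aggregation_sd:
        Spatial clustering of each species' nest trees: 0/None places
        them as a uniform random subset; a finite value concentrates
        them around a random centre with an exponential weight of that
        range.
    kernel_range_m / emission_rate:
        Foraging kernel: a nest at distance d marks foraging on another
        tree with probability ``emission_rate * exp(-d / kernel_range_m)``
        (clipped to 1).  Every nest also marks foraging on its own tree.
    tourist_rate:
        Per-(tree, species) probability of a foraging record placed
        uniformly at random, independent of nest positions.
    ground_nester:
        Append one extra species emulating a ground-level super-colony:
        very few in-tree (satellite) nests, foragers on a large random
        fraction of trees, flagged invasive and excluded from spatial
        analyses.
    """

    width: float = 40.0
    height: float = 80.0
    n_trees: int = 350
    position: str = "uniform"
    thomas_parents: int = 10
    thomas_sd: float = 4.0
    n_species: int = 60
    logseries_p: float = 0.95
    nest_aggregation_sd: float | None = None
    kernel_range_m: float = 5.0
    emission_rate: float = 0.12
    tourist_rate: float = 0.01
    ground_nester: bool = False
    ground_nester_nests: int = 4
    ground_nester_forage_p: float = 0.42
    species_codes: tuple[str, ...] | None = None
    plot_label: str = "synthetic"

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.n_trees < 1 or self.n_species < 1:
            raise ValueError("need at least one tree and one species")
        if self.position not in ("uniform", "thomas"):
            raise ValueError(f"unknown position process {self.position!r}")
        if self.position == "thomas" and (self.thomas_parents < 1 or self.thomas_sd <= 0):
            raise ValueError("thomas process needs >= 1 parent and positive offspring sd")
        if not 0 < self.logseries_p < 1:
            raise ValueError("logseries_p must lie in (0, 1)")
        if self.kernel_range_m <= 0:
            raise ValueError("kernel_range_m must be positive")
        if self.emission_rate < 0 or self.tourist_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.nest_aggregation_sd is not None and self.nest_aggregation_sd < 0:
            raise ValueError("nest_aggregation_sd must be nonnegative")


@dataclass
class SyntheticTruth:
    """Generator ground truth stored alongside the data for recovery tests."""

    config: SimulationConfig
    seed: int
    nest_coordinates: dict[str, np.ndarray]  # species_code -> (k, 2) trunk coords
    kernel_range_m: float
    emission_rate: float


def _species_codes(n: int) -> tuple[str, ...]:
    codes = []
    for i in range(n):
        stub = _GENUS_STUBS[i % len(_GENUS_STUBS)]
        codes.append(f"{stub}{i // len(_GENUS_STUBS) + 1:03d}")
    return tuple(codes)


def generate_forest(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Stem map: tree_id, plot, x, y, dbh (cm).

    DBH is 5 + lognormal, giving the right-skew of a natural size
    structure with well over half the stems at or below 10 cm.
    """
    config.validate()
    n = config.n_trees
    if config.position == "uniform":
        x = rng.uniform(0, config.width, size=n)
        y = rng.uniform(0, config.height, size=n)
    else:
        px = rng.uniform(0, config.width, size=config.thomas_parents)
        py = rng.uniform(0, config.height, size=config.thomas_parents)
        parent = rng.integers(0, config.thomas_parents, size=n)
        x = np.empty(n)
        y = np.empty(n)
        for i in range(n):
            for _ in range(1000):
                cx = px[parent[i]] + rng.normal(0, config.thomas_sd)
                cy = py[parent[i]] + rng.normal(0, config.thomas_sd)
                if 0 <= cx <= config.width and 0 <= cy <= config.height:
                    x[i], y[i] = cx, cy
                    break
            else:  # pathological parameters: keep the point inside anyway
                x[i] = np.clip(px[parent[i]], 0, config.width)
                y[i] = np.clip(py[parent[i]], 0, config.height)
    dbh = 5.0 + rng.lognormal(mean=1.4, sigma=0.8, size=n)
    return pd.DataFrame(
        {
            "plot": config.plot_label,
            "x": np.round(x, 3),
            "y": np.round(y, 3),
            "dbh": np.round(dbh, 1),
        },
        index=pd.Index([f"{config.plot_label[:1].upper()}{i + 1:04d}" for i in range(n)], name="tree_id"),
    )


def _occupancies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    k = stats.logser.rvs(config.logseries_p, size=config.n_species, random_state=rng)
    return np.minimum(k, config.n_trees).astype(int)


def generate_nest_layer(
    trees: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    species_codes: tuple[str, ...],
) -> pd.DataFrame:
    """Binary nest incidence with log-series occupancies.

    Each species occupies k ~ logser(p) trees (truncated at n_trees).
    With ``nest_aggregation_sd`` set, the occupied trees cluster around
    a random centre tree by exponential distance weighting (weighted
    sampling without replacement via Gumbel top-k); otherwise they are
    a uniform random subset.
    """
    n = len(trees)
    xy = trees[["x", "y"]].to_numpy(float)
    occ = _occupancies(config, rng)
    mat = np.zeros((n, len(species_codes)), dtype=np.int8)
    for s, k in enumerate(occ):
        if config.nest_aggregation_sd:
            centre = xy[rng.integers(0, n)]
            d = np.hypot(xy[:, 0] - centre[0], xy[:, 1] - centre[1])
            logw = -d / config.nest_aggregation_sd
        else:
            logw = np.zeros(n)
        keys = logw + rng.gumbel(size=n)
        chosen = np.argsort(keys)[-k:]
        mat[chosen, s] = 1
    return pd.DataFrame(mat, index=trees.index, columns=list(species_codes))


def generate_forage_layer(
    trees: pd.DataFrame,
    nests: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Foraging incidence from nests through the distance-decay kernel.

    A nest always marks foraging on its own tree; it reaches any other
    tree at distance d with probability emission_rate * exp(-d /
    kernel_range_m) (independent per nest, union over nests).  Tourists
    are sprinkled uniformly on top at ``tourist_rate`` per (tree,
    species).  As kernel_range_m -> 0 with tourist_rate = 0, foraging
    collapses onto the nest trees and no F-N records exist.
    """
    config.validate()
    xy = trees[["x", "y"]].to_numpy(float)
    n = len(trees)
    N = nests.to_numpy(np.int8)
    forage = N.astype(bool).copy()  # own-tree foraging
    if config.emission_rate > 0:
        D = np.hypot(
            xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1]
        )
        reach = np.clip(config.emission_rate * np.exp(-D / config.kernel_range_m), 0.0, 1.0)
        np.fill_diagonal(reach, 0.0)  # own tree already marked
        for s in range(N.shape[1]):
            nest_trees = np.flatnonzero(N[:, s])
            if nest_trees.size == 0:
                continue
            # P(no nest of s reaches tree u) = prod over nests (1 - p)
            miss = np.prod(1.0 - reach[:, nest_trees], axis=1)
            forage[:, s] |= rng.random(n) < (1.0 - miss)
    if config.tourist_rate > 0:
        forage |= rng.random(forage.shape) < config.tourist_rate
    return pd.DataFrame(forage.astype(np.int8), index=trees.index, columns=nests.columns)


def generate_community(
    config: SimulationConfig, seed: int
) -> tuple[CommunityDataset, SyntheticTruth]:
    """Full synthetic dataset (stem map + layers + species register) and its truth.

    Regeneration from the same (config, seed) is bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    codes = config.species_codes or _species_codes(config.n_species)
    if len(codes) != config.n_species:
        raise ValueError("species_codes length must equal n_species")
    trees = generate_forest(config, rng)
    nests = generate_nest_layer(trees, config, rng, codes)
    forage = generate_forage_layer(trees, nests, config, rng)
    species = pd.DataFrame(
        {
            "full_name": [f"synthetic species {c}" for c in codes],
            "invasive": False,
            "exclude_from_spatial": False,
        },
        index=pd.Index(list(codes), name="species_code"),
    )
    if config.ground_nester:
        code = "GRND001"
        nests[code] = 0
        sat = rng.choice(len(trees), size=min(config.ground_nester_nests, len(trees)), replace=False)
        nests.iloc[sat, nests.columns.get_loc(code)] = 1
        forage[code] = (rng.random(len(trees)) < config.ground_nester_forage_p).astype(np.int8)
        forage.loc[nests[code] == 1, code] = 1
        species.loc[code] = ["synthetic ground-nesting super-colony", True, True]
    ds = CommunityDataset(
        trees=trees,
        layers={"nest": nests.astype(np.int8), "forage": forage.astype(np.int8)},
        species=species,
    )
    ds.validate()
    xy = trees[["x", "y"]].to_numpy(float)
    truth = SyntheticTruth(
        config=config,
        seed=seed,
        nest_coordinates={
            c: xy[nests[c].to_numpy(bool)] for c in nests.columns
        },
        kernel_range_m=config.kernel_range_m,
        emission_rate=config.emission_rate,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# presets rehearsing the two-plot study design

PRESETS: dict[str, SimulationConfig] = {
    # old-growth-like plot: 389 stems, ~102 species, strong distance-decay foraging
    "primary-like": SimulationConfig(
        n_trees=389,
        n_species=102,
        logseries_p=0.95,
        nest_aggregation_sd=10.0,
        kernel_range_m=3.5,
        emission_rate=0.15,
        tourist_rate=0.003,
        plot_label="primary",
    ),
    # young-regrowth-like plot: 295 stems, ~50 species (one ground-nesting
    # super-colony species appended and flagged for spatial exclusion),
    # weaker spatial signal
    "secondary-like": SimulationConfig(
        n_trees=295,
        n_species=50,
        logseries_p=0.96,
        nest_aggregation_sd=10.0,
        kernel_range_m=9.0,
        emission_rate=0.035,
        tourist_rate=0.010,
        ground_nester=True,
        plot_label="secondary",
    ),
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


def two_plot_study(
    seed: int, n_shared_species: int = 26
) -> tuple[CommunityDataset, dict[str, SyntheticTruth]]:
    """Generate the full two-plot scenario with a controlled species overlap.

    The secondary-like plot reuses ``n_shared_species`` codes from the
    primary-like pool (species occurring in both plots) and mints the
    rest fresh, so between-plot shared-species counts are meaningful.
    """
    ss = np.random.SeedSequence(seed)
    s_primary, s_secondary, s_pick = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    cfg_p = preset_config("primary-like")
    primary_codes = _species_codes(cfg_p.n_species)
    cfg_p = replace(cfg_p, species_codes=primary_codes)
    ds_p, truth_p = generate_community(cfg_p, s_primary)

    cfg_s = preset_config("secondary-like")
    pick = np.random.default_rng(s_pick).choice(
        len(primary_codes), size=n_shared_species, replace=False
    )
    shared = tuple(primary_codes[i] for i in sorted(pick))
    fresh = tuple(
        f"{stub}9{i:02d}"
        for i, stub in zip(
            range(cfg_s.n_species - n_shared_species),
            (_GENUS_STUBS * 10),
        )
    )
    cfg_s = replace(cfg_s, species_codes=shared + fresh)
    ds_s, truth_s = generate_community(cfg_s, s_secondary)

    ds = combine_plots(ds_p, ds_s)
    return ds, {"primary": truth_p, "secondary": truth_s}
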