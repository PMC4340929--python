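"""Data model and I/O for tree-level ant incidence surveys.

A :class:`CommunityDataset` couples a stem map (one row per tree: plot
membership, trunk coordinates in metres, DBH and optional size traits)
with binary trees-by-species incidence layers for two record kinds —
``nest`` and ``forage`` — plus species metadata carrying an invasive
flag and an ``exclude_from_spatial`` flag for species (typically
ground-nesting super-colonies) that must not enter the spatial
analyses.

All spatial statistics work on presence/absence.  Count layers (nests
per tree, forager individuals per tree) may accompany the binary
layers; they feed abundance summaries only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DataError",
    "AlignmentError",
    "ParseError",
    "CommunityDataset",
    "DistanceMatrix",
    "read_community",
    "write_community",
    "derive_fn_records",
    "pairwise_distances",
    "combine_plots",
    "LAYER_KINDS",
]

LAYER_KINDS = ("nest", "forage")

#: Optional per-tree size traits recognised by the tree table reader.
TRAIT_COLUMNS = (
    "height_m",
    "trunk_height_m",
    "crown_width_m",
    "crown_height_m",
    "leaf_weight_kg",
)

#: Census rule: stems below this DBH (cm) trigger a warning, not an error.
DBH_CENSUS_MIN = 5.0


class DataError(Exception):
    """Base class for dataset construction and validation failures."""


class AlignmentError(DataError):
    """Tree or species label sets disagree between files."""


class ParseError(DataError):
    """A field could not be parsed (message carries file and row context)."""


@dataclass
class CommunityDataset:
    """Aligned stem map, incidence layers and species register.

    Attributes
    ----------
    trees:
        DataFrame indexed by ``tree_id`` with columns ``plot``, ``x``,
        ``y``, ``dbh`` and any of :data:`TRAIT_COLUMNS`.
    layers:
        Mapping layer kind -> binary (0/1) DataFrame, rows aligned to
        ``trees.index``, columns aligned to ``species.index``.
    species:
        DataFrame indexed by ``species_code`` with columns
        ``full_name``, ``invasive``, ``exclude_from_spatial``.
    counts:
        Optional mapping layer kind -> nonnegative integer DataFrame of
        the same shape as the binary layer (raw nest / forager counts).
    """

    trees: pd.DataFrame
    layers: dict[str, pd.DataFrame]
    species: pd.DataFrame
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    # -- convenience ---------------------------------------------------
    def plots(self) -> list[str]:
        """Plot labels in order of first appearance."""
        return list(dict.fromkeys(self.trees["plot"]))

    def plot_tree_ids(self, plot: str) -> pd.Index:
        if plot not in set(self.trees["plot"]):
            raise DataError(f"unknown plot label: {plot!r}")
        return self.trees.index[self.trees["plot"] == plot]

    def layer(self, kind: str, plot: str | None = None) -> pd.DataFrame:
        """Binary incidence layer, optionally restricted to one plot's trees."""
        if kind not in self.layers:
            raise DataError(f"layer {kind!r} not present (have {sorted(self.layers)})")
        mat = self.layers[kind]
        if plot is None:
            return mat
        return mat.loc[self.plot_tree_ids(plot)]

    def validate(self) -> None:
        """Enforce the structural invariants; raise :class:`DataError` on violation."""
        trees, species = self.trees, self.species
        if trees.index.has_duplicates:
            dups = trees.index[trees.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate tree_id values: {dups}")
        if species.index.has_duplicates:
            dups = species.index[species.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate species_code values: {dups}")
        for col in ("plot", "x", "y", "dbh"):
            if col not in trees.columns:
                raise DataError(f"tree table missing required column {col!r}")
        xy = trees[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            bad = trees.index[~np.isfinite(xy).all(axis=1)].tolist()
            raise DataError(f"non-finite coordinates for trees: {bad}")
        dbh = trees["dbh"].to_numpy(float)
        if np.any(~np.isfinite(dbh)) or np.any(dbh <= 0):
            raise DataError("DBH must be finite and > 0 for every tree")
        if np.any(dbh < DBH_CENSUS_MIN):
            n = int(np.sum(dbh < DBH_CENSUS_MIN))
            warnings.warn(
                f"{n} tree(s) below the DBH >= {DBH_CENSUS_MIN:g} cm census rule",
                stacklevel=2,
            )
        for col in ("invasive", "exclude_from_spatial"):
            if col not in species.columns:
                raise DataError(f"species table missing required column {col!r}")
        for kind, mat in self.layers.items():
            if not mat.index.equals(trees.index):
                raise AlignmentError(f"{kind} layer rows do not match the tree register")
            if not mat.columns.equals(species.index):
                raise AlignmentError(f"{kind} layer columns do not match the species register")
            vals = mat.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise DataError(f"{kind} layer is not binary")
        for kind, mat in self.counts.items():
            if not mat.index.equals(trees.index) or not mat.columns.equals(species.index):
                raise AlignmentError(f"{kind} count layer is misaligned")
            vals = mat.to_numpy()
            if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
                raise DataError(f"{kind} count layer must hold nonnegative integers")


@dataclass
class DistanceMatrix:
    """Square symmetric trunk-to-trunk Euclidean distances (m) within one plot."""

    values: np.ndarray
    tree_ids: pd.Index

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise DataError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def summary(self) -> dict[str, float]:
        """Mean and SD of all pairwise (upper-triangle) distances."""
        if self.n < 2:
            return {"mean_m": float("nan"), "sd_m": float("nan"), "n_pairs": 0}
        d = self.upper_triangle()
        return {"mean_m": float(d.mean()), "sd_m": float(d.std(ddof=1)), "n_pairs": int(d.size)}


# ---------------------------------------------------------------------------
# reading / writing


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{what} file not found: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse {what} file {path}: {exc}") from exc


def _parse_bool(series: pd.Series, what: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = []
    for i, v in enumerate(series):
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
            continue
        if isinstance(v, (int, np.integer, float, np.floating)) and v in (0, 1):
            out.append(bool(v))
            continue
        key = str(v).strip().lower()
        if key not in mapping:
            raise ParseError(f"{what}: cannot interpret {v!r} as boolean (row {i + 2})")
        out.append(mapping[key])
    return pd.Series(out, index=series.index)


def _load_layer(path: str | Path, kind: str, transpose: bool = False) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Load one incidence matrix; return (binary layer, counts-or-None)."""
    raw = _read_csv(path, f"{kind} matrix")
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "tree_id"
    if transpose:
        raw = raw.T
        raw.index.name = "tree_id"
    try:
        mat = raw.astype(float)
    except ValueError as exc:
        raise ParseError(f"{kind} matrix {path}: non-numeric cell ({exc})") from exc
    vals = mat.to_numpy()
    if np.any(~np.isfinite(vals)) or np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        raise ParseError(f"{kind} matrix {path}: entries must be nonnegative integers")
    mat = mat.round().astype(int)
    counts = None
    if (mat.to_numpy() > 1).any():
        warnings.warn(
            f"{kind} matrix holds counts > 1; binarized for incidence work "
            "(raw counts retained for abundance summaries)",
            stacklevel=3,
        )
        counts = mat.copy()
    binary = (mat > 0).astype(np.int8)
    return binary, counts


def read_community(
    tree_table_path: str | Path,
    nest_matrix_path: str | Path,
    forage_matrix_path: str | Path,
    species_meta_path: str | Path,
    transpose_layers: bool = False,
) -> CommunityDataset:
    """Read a complete survey from four CSV files and align the registers.

    Matrices are trees-as-rows, species-as-columns with a ``tree_id``
    first column (pass ``transpose_layers=True`` for species-as-rows
    files).  Matrices holding counts are binarized with a warning and
    the counts are kept for abundance summaries.

    Raises
    ------
    AlignmentError
        If the tree or species label sets disagree between files
        (the message lists the offending labels).
    ParseError
        On non-numeric coordinates or matrix cells.
    """
    trees = _read_csv(tree_table_path, "tree table")
    trees = trees.set_index(trees.columns[0])
    trees.index = trees.index.astype(str)
    trees.index.name = "tree_id"
    for col in ("x", "y", "dbh"):
        if col not in trees.columns:
            raise DataError(f"tree table missing column {col!r}")
        try:
            trees[col] = trees[col].astype(float)
        except ValueError as exc:
            bad = trees[col][pd.to_numeric(trees[col], errors="coerce").isna()]
            row = trees.index.get_loc(bad.index[0]) + 2  # header + 1-based
            raise ParseError(
                f"tree table: non-numeric {col} for tree {bad.index[0]!r} (row {row})"
            ) from exc
    trees["plot"] = trees["plot"].astype(str)

    species = _read_csv(species_meta_path, "species metadata")
    species = species.set_index(species.columns[0])
    species.index = species.index.astype(str)
    species.index.name = "species_code"
    if "full_name" not in species.columns:
        species["full_name"] = species.index
    for col in ("invasive", "exclude_from_spatial"):
        if col not in species.columns:
            species[col] = False
        else:
            species[col] = _parse_bool(species[col], f"species metadata column {col!r}")

    layers: dict[str, pd.DataFrame] = {}
    counts: dict[str, pd.DataFrame] = {}
    for kind, path in (("nest", nest_matrix_path), ("forage", forage_matrix_path)):
        binary, cnt = _load_layer(path, kind, transpose=transpose_layers)
        binary.index = binary.index.astype(str)
        binary.columns = binary.columns.astype(str)
        layers[kind] = binary
        if cnt is not None:
            cnt.index = cnt.index.astype(str)
            cnt.columns = cnt.columns.astype(str)
            counts[kind] = cnt

    # label alignment
    tree_set = set(trees.index)
    for kind, mat in layers.items():
        mat_set = set(mat.index)
        if mat_set != tree_set:
            missing = sorted(tree_set - mat_set)
            extra = sorted(mat_set - tree_set)
            raise AlignmentError(
                f"{kind} matrix trees disagree with tree table; "
                f"missing from matrix: {missing}; unknown in matrix: {extra}"
            )
    sp_union = sorted(set().union(*(set(m.columns) for m in layers.values())))
    sp_known = set(species.index)
    unknown = sorted(set(sp_union) - sp_known)
    if unknown:
        raise AlignmentError(f"species in matrices absent from metadata: {unknown}")
    # metadata may list species never observed; keep the full register
    order = species.index
    for kind in list(layers):
        layers[kind] = layers[kind].reindex(index=trees.index, columns=order, fill_value=0).astype(np.int8)
    for kind in list(counts):
        counts[kind] = counts[kind].reindex(index=trees.index, columns=order, fill_value=0).astype(int)

    ds = CommunityDataset(trees=trees, layers=layers, species=species, counts=counts)
    ds.validate()
    return ds


def write_community(ds: CommunityDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset to the four-CSV layout read by :func:`read_community`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trees": outdir / "trees.csv",
        "nest": outdir / "nest_matrix.csv",
        "forage": outdir / "forage_matrix.csv",
        "species": outdir / "species.csv",
    }
    ds.trees.to_csv(paths["trees"], index_label="tree_id")
    ds.layers["nest"].to_csv(paths["nest"], index_label="tree_id")
    ds.layers["forage"].to_csv(paths["forage"], index_label="tree_id")
    ds.species.to_csv(paths["species"], index_label="species_code")
    for kind, mat in ds.counts.items():
        p = outdir / f"{kind}_counts.csv"
        mat.to_csv(p, index_label="tree_id")
        paths[f"{kind}_counts"] = p
    return paths


# ---------------------------------------------------------------------------
# derived structures


def derive_fn_records(
    ds: CommunityDataset, plot: str, apply_exclusions: bool = True
) -> pd.DataFrame:
    """F-N records for one plot: (tree, species) pairs foraged but not nested.

    A record (t, s) requires forage(t, s) = 1, nest(t, s) = 0 and at
    least one nest of s somewhere in the plot.  With
    ``apply_exclusions`` (the spatial-analysis convention), species
    flagged ``exclude_from_spatial`` never yield records.

    Returns a DataFrame with columns ``tree_id``, ``species_code``,
    ``plot``, ordered by tree then species.
    """
    nest = ds.layer("nest", plot)
    forage = ds.layer("forage", plot)
    has_nest = nest.sum(axis=0) >= 1
    keep = has_nest.to_numpy()
    if apply_exclusions:
        keep &= ~ds.species["exclude_from_spatial"].to_numpy(bool)
    mask = (forage.to_numpy(bool) & ~nest.to_numpy(bool)) & keep[None, :]
    ti, si = np.nonzero(mask)
    return pd.DataFrame(
        {
            "tree_id": nest.index.to_numpy()[ti],
            "species_code": nest.columns.to_numpy()[si],
            "plot": plot,
        }
    )


def pairwise_distances(ds: CommunityDataset, plot: str) -> DistanceMatrix:
    """Euclidean trunk-to-trunk distance matrix for one plot's trees."""
    ids = ds.plot_tree_ids(plot)
    xy = ds.trees.loc[ids, ["x", "y"]]
    bad = xy.index[xy.isna().any(axis=1)].tolist()
    if bad:
        raise DataError(f"missing coordinates for trees: {bad}")
    if len(ids) == 1:
        return DistanceMatrix(values=np.zeros((1, 1)), tree_ids=ids)
    vals = squareform(pdist(xy.to_numpy(float)))
    return DistanceMatrix(values=vals, tree_ids=ids)


def combine_plots(*datasets: CommunityDataset) -> CommunityDataset:
    """Stack independently generated plots into one multi-plot dataset.

    Species registers are merged on species_code (metadata must agree
    for shared codes); layers are outer-joined with absent incidences
    filled with 0.  Plot labels must be disjoint across inputs.
    """
    plots_seen: set[str] = set()
    for ds in datasets:
        overlap = plots_seen & set(ds.plots())
        if overlap:
            raise DataError(f"plot labels repeated across datasets: {sorted(overlap)}")
        plots_seen |= set(ds.plots())
        tree_overlap = set()
        for other in datasets:
            if other is not ds:
                tree_overlap |= set(ds.trees.index) & set(other.trees.index)
        if tree_overlap:
            raise DataError(f"tree_id repeated across datasets: {sorted(tree_overlap)[:5]}")

    trees = pd.concat([ds.trees for ds in datasets])
    species = pd.concat([ds.species for ds in datasets])
    dup = species.index.duplicated(keep="first")
    merged_species = species[~dup]
    # sanity: shared codes must carry identical flags
    for code in species.index[dup].unique():
        rows = species.loc[[code]]
        if rows[["invasive", "exclude_from_spatial"]].nunique().max() > 1:
            raise DataError(f"conflicting metadata for shared species {code!r}")
    order = merged_species.index
    layers = {}
    for kind in LAYER_KINDS:
        layers[kind] = pd.concat(
            [ds.layers[kind].reindex(columns=order, fill_value=0) for ds in datasets]
        ).astype(np.int8)
    counts: dict[str, pd.DataFrame] = {}
    kinds_with_counts = set().union(*(set(ds.counts) for ds in datasets))
    for kind in kinds_with_counts:
        parts = [
            ds.counts.get(kind, ds.layers[kind] * 0).reindex(columns=order, fill_value=0)
            for ds in datasets
        ]
        counts[kind] = pd.concat(parts).astype(int)
    out = CommunityDataset(trees=trees, layers=layers, species=merged_species, counts=counts)
    out.validate()
    return out
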