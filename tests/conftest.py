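"""Shared fixtures: hand-built toy communities and small synthetic plots."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from arborants.data import CommunityDataset


def build_dataset(
    tree_rows: list[tuple],
    nest_records: list[tuple[str, str]],
    forage_records: list[tuple[str, str]],
    species: list[str] | None = None,
    invasive: set[str] = frozenset(),
    excluded: set[str] = frozenset(),
) -> CommunityDataset:
    """Assemble a dataset from (tree_id, plot, x, y[, dbh]) rows and record pairs."""
    trees = pd.DataFrame(
        [
            {
                "tree_id": r[0],
                "plot": r[1],
                "x": float(r[2]),
                "y": float(r[3]),
                "dbh": float(r[4]) if len(r) > 4 else 10.0,
            }
            for r in tree_rows
        ]
    ).set_index("tree_id")
    if species is None:
        species = sorted({s for _, s in nest_records} | {s for _, s in forage_records})
    sp = pd.DataFrame(
        {
            "full_name": species,
            "invasive": [s in invasive for s in species],
            "exclude_from_spatial": [s in excluded for s in species],
        },
        index=pd.Index(species, name="species_code"),
    )
    layers = {}
    for kind, records in (("nest", nest_records), ("forage", forage_records)):
        mat = pd.DataFrame(0, index=trees.index, columns=sp.index, dtype=np.int8)
        for t, s in records:
            mat.loc[t, s] = 1
        layers[kind] = mat
    ds = CommunityDataset(trees=trees, layers=layers, species=sp)
    ds.validate()
    return ds


@pytest.fixture
def toy_dataset() -> CommunityDataset:
    """Three trees on a 3-4-5 layout, two species.

    A nests on T1 and forages on T1 and T2 (one F-N record at T2,
    5 m from its nest); B forages on T3 but nests nowhere.
    """
    return build_dataset(
        tree_rows=[("T1", "p", 0, 0), ("T2", "p", 3, 4), ("T3", "p", 10, 0)],
        nest_records=[("T1", "A")],
        forage_records=[("T1", "A"), ("T2", "A"), ("T3", "B")],
    )


def random_dataset(rng: np.random.Generator, n_trees: int = 20, n_species: int = 10,
                   plot: str = "p") -> CommunityDataset:
    """Unstructured random community for oracle comparisons."""
    trees = [(f"T{i}", plot, rng.uniform(0, 40), rng.uniform(0, 80)) for i in range(n_trees)]
    species = [f"SP{j:02d}" for j in range(n_species)]
    nest, forage = [], []
    for j, s in enumerate(species):
        for i in range(n_trees):
            if rng.random() < 0.15:
                nest.append((f"T{i}", s))
            if rng.random() < 0.25:
                forage.append((f"T{i}", s))
    return build_dataset(trees, nest, forage, species=species)
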