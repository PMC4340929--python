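#!/usr/bin/env python
"""Diversity of nesting vs foraging ant layers, per tree and per plot.

Reads the dataset written by 01_simulate.py (or any dataset in the same
CSV layout via --data), then reports: observed richness and Chao2 per
plot and layer, Mao Tau rarefaction curves, per-tree richness means
with SE (trees as replicates), shared species between plots, and
occupancy summaries.  Tables land in results/diversity/.
"""

import argparse
from pathlib import Path

import pandas as pd

from arborants.data import read_community
from arborants.diversity import (
    RICHNESS_LAYERS,
    _layer_matrix,
    chao2,
    incidence_summary,
    rarefaction_curve,
    richness_table,
    shared_species,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "diversity")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ds = read_community(
        args.data / "trees.csv", args.data / "nest_matrix.csv",
        args.data / "forage_matrix.csv", args.data / "species.csv",
    )
    summaries, estimates, curves = [], [], []
    for plot in ds.plots():
        table = richness_table(ds, plot)
        summaries.append(table)
        print(f"\n{plot}: per-tree species richness (mean over all trees +/- SE)")
        for row in table.itertuples():
            print(f"  {row.layer:>6}: S_obs={row.S_obs:3d}  "
                  f"{row.mean_per_tree:.2f} +/- {row.se_per_tree:.2f} (max {row.max_per_tree})")
        for layer in RICHNESS_LAYERS:
            summ = incidence_summary(_layer_matrix(ds, plot, layer))
            est = chao2(summ)
            estimates.append(
                {"plot": plot, "layer": layer, "S_obs": summ.S_obs, "q1": summ.q1,
                 "q2": summ.q2, "chao2": est.estimate, "sd": est.sd,
                 "variant": est.variant_used}
            )
            curves.append(rarefaction_curve(summ).assign(plot=plot, layer=layer))
        est_all = next(e for e in estimates if e["plot"] == plot and e["layer"] == "all")
        print(f"  Chao2 (all records): {est_all['chao2']:.1f} (SD {est_all['sd']:.1f}) "
              f"vs {est_all['S_obs']} observed")

    pd.concat(summaries, ignore_index=True).to_csv(args.out / "richness_summary.csv", index=False)
    pd.DataFrame(estimates).to_csv(args.out / "richness_estimates.csv", index=False)
    pd.concat(curves, ignore_index=True).to_csv(args.out / "rarefaction.csv", index=False)

    plots = ds.plots()
    if len(plots) == 2:
        n, codes = shared_species(ds, *plots)
        pd.DataFrame({"species_code": codes}).to_csv(args.out / "shared_species.csv", index=False)
        print(f"\nshared species between {plots[0]} and {plots[1]}: {n}")
    print(f"\ntables written to {args.out}")


if __name__ == "__main__":
    main()
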