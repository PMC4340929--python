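"""Optional figure output: cumulative-distance curve and probability profile."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .spatial import NullModelResult

__all__ = ["plot_null_result"]


def plot_null_result(result: NullModelResult, path: str | Path) -> Path:
    """One panel comparing the observed statistic with the null band."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    t = result.table
    if result.statistic == "nearest_distance_curve":
        ax.fill_between(t["grid_m"], t["null_min"], t["null_max"], alpha=0.25,
                        color="grey", label="null min–max")
        ax.fill_between(t["grid_m"], t["env_lo"], t["env_hi"], alpha=0.35,
                        color="steelblue", label="null 2.5–97.5%")
        ax.plot(t["grid_m"], t["observed_cum"], color="firebrick", lw=2, label="observed")
        ax.set_xlabel("distance to nearest nest (m)")
        ax.set_ylabel("cumulative proportion of F-N records")
    else:
        ax.fill_between(t["radius_m"], t["env_lo"], t["env_hi"], alpha=0.35,
                        color="steelblue", label="null 2.5–97.5%")
        ax.plot(t["radius_m"], t["null_mean"], color="grey", ls="--", label="null mean")
        ax.plot(t["radius_m"], t["observed_mean"], color="firebrick", marker="o",
                lw=2, label="observed")
        ax.set_xlabel("maximum distance d (m)")
        ax.set_ylabel("mean nesting probability of F-N species")
    ax.set_title(f"{result.plot}: {result.statistic.replace('_', ' ')}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
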