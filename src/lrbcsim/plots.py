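"""Plot helpers for radial intensity-difference and LRBC-vs-blood curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .reflectance_analysis import ProfileComparison


def plot_profile_comparisons(comparisons: dict[str, ProfileComparison], path,
                             relative: bool = False, r_max: float = 2.0) -> None:
    """Intensity-difference curves versus radial distance, one per label."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, cmp_ in comparisons.items():
        y = cmp_.relative_difference if relative else cmp_.absolute_difference
        mask = cmp_.defined & (cmp_.bin_centers <= r_max) & (cmp_.bin_centers > 0)
        ax.plot(cmp_.bin_centers[mask], y[mask], marker="o", ms=3, label=label)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("radial distance r (mm)")
    ax.set_ylabel("relative intensity difference" if relative
                  else "intensity difference (per incident photon)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lrbc_vs_scale(table: pd.DataFrame, path) -> None:
    """LRBC (um) against % blood content relative to baseline."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(100.0 * table["scale"], table["lrbc_um"],
                yerr=table["stderr_um"], marker="o", capsize=3)
    ax.set_xlabel("blood content (% of baseline)")
    ax.set_ylabel(r"$L_{RBC}$ ($\mu$m)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
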