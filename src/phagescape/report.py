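"""Minimal graphical reports: Z-score heat maps and escape time courses."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import ZScoreMatrix


def zscore_heatmap(matrices: dict[str, ZScoreMatrix], path) -> None:
    """One heat-map row per sample, white (Z=0) to red (max Z in the data)."""
    if not matrices:
        raise ValueError("no Z-score matrices to plot")
    names = list(matrices)
    positions = matrices[names[0]].z.index
    data = np.vstack([matrices[n].z.reindex(positions).to_numpy() for n in names])
    vmax = float(np.nanmax(data))
    if vmax <= 0:
        vmax = 1.0  # all-zero map renders all white
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(positions)), 0.6 * len(names) + 1.5))
    im = ax.imshow(np.clip(data, 0, None), aspect="auto", cmap="Reds", vmin=0, vmax=vmax)
    ax.set_xticks(range(len(positions)))
    ax.set_xticklabels([str(p) for p in positions], rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)))
    ax.set_yticklabels(names, fontsize=8)
    ax.set_xlabel("position relative to PAM")
    fig.colorbar(im, ax=ax, label="Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def timecourse_plot(table: pd.DataFrame, path) -> None:
    """Fraction-mutated vs time line with SD error bars."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    sd = table["sd_fraction_mutated"].fillna(0.0)
    ax.errorbar(
        table["time"], table["mean_fraction_mutated"], yerr=sd,
        marker="o", capsize=3,
    )
    ax.set_xlabel("time")
    ax.set_ylabel("fraction of phage with mutated target")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def kinetics_plot(timecourses: Sequence, fits: Sequence, path) -> None:
    """Fraction cleaved vs time (log x) with fitted first-order curves."""
    from .kinetics import first_order

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for tc, fit in zip(timecourses, fits):
        ax.plot(tc.timepoints, tc.fraction_cleaved, "o", label=tc.replicate_id)
        grid = np.geomspace(tc.timepoints[0], tc.timepoints[-1], 200)
        ax.plot(grid, first_order(grid, fit.k_obs, fit.plateau), "-", alpha=0.7)
    ax.set_xscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fraction cleaved")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
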