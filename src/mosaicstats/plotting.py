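"""Plot helpers for profiles, spectra and the multi-track heatmap."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_rate_profile(profile, ax=None):
    """Case/control rate-per-Mb step plot around feature midpoints."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    f = profile.frame
    centres = (f["bin_low"] + f["bin_high"]) / 2
    ax.step(centres, f["rate_case_per_mb"], where="mid", label="cases")
    ax.step(centres, f["rate_control_per_mb"], where="mid", label="controls")
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_xlabel("distance from TFBS midpoint (bp)")
    ax.set_ylabel("sSNV per Mb per genome")
    ax.legend()
    return ax


def plot_spectrum_96(spectrum: pd.Series, ax=None):
    """Bar plot of the 96-channel substitution spectrum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    colors = np.repeat(
        ["#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63", "#EBC6C4"], 16)
    ax.bar(np.arange(96), spectrum.to_numpy(), color=colors, width=0.8)
    ax.set_xticks(np.arange(8, 96, 16))
    ax.set_xticklabels(["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"])
    ax.set_ylabel("count")
    return ax


def plot_heatmap(grid: pd.DataFrame, ax=None):
    """O/E ratio heatmap over (track, quantile) with FDR stars."""
    import matplotlib.pyplot as plt

    pivot = grid.pivot(index="track", columns="quantile", values="ratio")
    sig = grid.pivot(index="track", columns="quantile", values="significant")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * pivot.shape[1] + 2, 0.6 * pivot.shape[0] + 1.5))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]))
    ax.set_xticklabels(pivot.columns)
    ax.set_yticks(range(pivot.shape[0]))
    ax.set_yticklabels(pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            if sig.iloc[i, j] is True:
                ax.text(j, i, "*", ha="center", va="center", color="w", fontsize=14)
    ax.figure.colorbar(im, ax=ax, label="observed / expected")
    return ax
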