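"""Diagnostic plots for a screen report: the slope histogram and the
p-value-versus-slope scatter used to visualise the empirical cutoffs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .screen import ScreenReport

__all__ = ["plot_slope_histogram", "plot_p_vs_slope"]


def plot_slope_histogram(
    report: ScreenReport, path: str | Path, xlim: float = 0.3, slope_cut: float = 0.05
) -> None:
    slopes = report.results["slope"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.clip(slopes, -xlim, xlim), bins=60, color="0.6")
    for x in (-slope_cut, slope_cut):
        ax.axvline(x, color="tab:blue", lw=1)
    ax.set_xlabel("slope (normalized ratio / cycle)")
    ax.set_ylabel("SNP pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_p_vs_slope(
    report: ScreenReport,
    path: str | Path,
    alpha: float = 0.05,
    slope_cut: float = 0.05,
) -> None:
    df = report.results
    colors = {"candidate": "0.4", "putative": "lightblue", "non_fSNP": "gold"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, col in colors.items():
        sub = df[df["classification"] == cls]
        ax.scatter(sub["slope"], sub["p_value"], s=6, c=col, label=cls, alpha=0.7)
    ax.axhline(alpha, color="k", lw=0.8, ls="--")
    for x in (-slope_cut, slope_cut):
        ax.axvline(x, color="k", lw=0.8, ls="--")
    ax.set_xlabel("slope")
    ax.set_ylabel("p value")
    ax.legend(markerscale=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
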