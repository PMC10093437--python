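"""Plotting: down-sampling scatter with trend lines, rolling-correlation
panels, and the pairwise EC matrix.

Conventions follow the style of the reference figures: overall accuracy in
black, average error consistency in red, LOWESS trend lines over the raw
scatter; points with undefined AEC appear as gaps, never as zeros.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ec_core import PairwiseEC
from .sample_size import DownsamplingPoint, RollingCorrelationResult, TrendCurve

OA_COLOR = "black"
AEC_COLOR = "tab:red"


def plot_downsampling(points: Sequence[DownsamplingPoint],
                      trend: TrendCurve | None = None, ax=None):
    """Scatter of OA and AEC against the down-sampling proportion."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    x = [p.proportion * 100 for p in points]
    ax.scatter(x, [p.oa for p in points], s=14, color=OA_COLOR,
               alpha=0.6, label="OA")
    defined = [p for p in points if p.aec_defined]
    ax.scatter([p.proportion * 100 for p in defined],
               [p.aec for p in defined], s=14, color=AEC_COLOR,
               alpha=0.6, label="AEC")
    if trend is not None:
        ax.plot(trend.x * 100, trend.y_oa, color=OA_COLOR, lw=2)
        ax.plot(trend.x * 100, trend.y_aec, color=AEC_COLOR, lw=2)
    ax.set_xlabel("sample size (%)")
    ax.set_ylabel("metric value")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", frameon=False)
    return ax


def plot_rolling_correlation(results: Sequence[RollingCorrelationResult],
                             metric_name: str = "metric", axes=None):
    """One panel per window size: correlation vs window centre with CI band."""
    results = list(results)
    if axes is None:
        _, axes = plt.subplots(1, len(results),
                               figsize=(4 * len(results), 3.5), squeeze=False)
        axes = axes[0]
    for ax, res in zip(axes, results):
        ok = ~np.isnan(res.correlation)
        ax.plot(res.centers[ok], res.correlation[ok], color="tab:blue", lw=1.5)
        band = ok & ~np.isnan(res.ci_low)
        ax.fill_between(res.centers[band], res.ci_low[band], res.ci_high[band],
                        color="tab:blue", alpha=0.2)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_ylim(-1.05, 1.05)
        ax.set_title(f"window = {res.window_size}")
        ax.set_xlabel("sample size (%)")
    axes[0].set_ylabel(f"corr({metric_name}, sample size %)")
    return axes


def plot_ec_matrix(pec: PairwiseEC, ax=None):
    """Heatmap of the pairwise EC matrix (upper triangle mirrored)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    mat = np.full((pec.n_sets, pec.n_sets), np.nan)
    np.fill_diagonal(mat, 1.0)
    mat[pec.i, pec.j] = pec.values
    mat[pec.j, pec.i] = pec.values
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis")
    plt.colorbar(im, ax=ax, label="error consistency")
    ax.set_xlabel("model index")
    ax.set_ylabel("model index")
    return ax


def save_figure(ax_or_axes, path, dpi: int = 150) -> None:
    ax = ax_or_axes[0] if isinstance(ax_or_axes, (list, np.ndarray)) else ax_or_axes
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
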