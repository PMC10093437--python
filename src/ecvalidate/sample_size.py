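"""Effect-of-sample-size analysis and rolling-window correlations.

The down-sampling experiment asks the practical question "would more data
help?": the dataset is randomly down-sampled (stratified, without
replacement) to a grid of proportions, an EC-enhanced K-Fold run is
performed on each draw, and the resulting (proportion, OA, AEC) points are
smoothed with locally weighted regression (LOWESS).  A trend that is still
rising at proportion 1.0 suggests further samples would improve accuracy
or consistency; a plateau suggests they would not.

Rolling-window correlation quantifies the same trends: the points are
sorted by sample-size percentage and, within each sliding window, the
correlation between percentage and metric is computed together with a
bootstrap percentile confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._seeds import derive_rng, derive_seed
from .adapters import ClassifierAdapter
from .datasets import Dataset
from .engine import RunResult, ValidationConfig, run_internal
from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

#: default grid of down-sampling proportions
DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.2, 1.01, 0.1), 10))
#: default number of random draws per proportion
DEFAULT_DRAWS = 10
#: default (reduced) repetition count per down-sampling point
DEFAULT_POINT_M = 50


@dataclass(frozen=True)
class DownsamplingPoint:
    """One down-sampling draw: a full validation run at a given proportion."""

    proportion: float
    realized_n: int
    draw: int
    oa: float
    oa_sd: float
    aec: float          # NaN when undefined (perfect classifier on the draw)
    aec_sd: float
    n_pairs_undefined: int
    seed: int           # master seed of this point's validation run

    @property
    def aec_defined(self) -> bool:
        return not np.isnan(self.aec)


@dataclass(frozen=True)
class TrendCurve:
    """LOWESS-smoothed OA and AEC against proportion.

    ``y_aec`` is NaN where the smoother had no defined AEC points in
    range (gaps are preserved, never imputed as zeros).
    """

    x: np.ndarray
    y_oa: np.ndarray
    y_aec: np.ndarray
    span: float


@dataclass(frozen=True)
class RollingCorrelationResult:
    """Sliding-window correlations with bootstrap percentile intervals."""

    window_size: int
    centers: np.ndarray       # mean sample-size percentage per window
    correlation: np.ndarray   # NaN for constant windows
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    method: str = "pearson"


def _stratified_subsample(ds: Dataset, n_take: int, seed: int) -> Dataset:
    """Stratified without-replacement subsample of n_take rows."""
    if n_take >= ds.n_samples:
        return ds.subset(np.arange(ds.n_samples))
    try:
        idx, _ = train_test_split(np.arange(ds.n_samples), train_size=n_take,
                                  random_state=seed, stratify=ds.labels)
    except ValueError:
        # classes too small to stratify at this size: plain random draw
        rng = np.random.default_rng(seed)
        idx = rng.choice(ds.n_samples, size=n_take, replace=False)
    return ds.subset(np.sort(idx))


def downsample_experiment(
    ds: Dataset,
    clf: ClassifierAdapter,
    cfg: ValidationConfig | None = None,
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    draws_per_proportion: int = DEFAULT_DRAWS,
) -> list[DownsamplingPoint]:
    """Run an EC-enhanced K-Fold validation on random subsamples.

    For each proportion p, ``draws_per_proportion`` independent stratified
    subsamples of round(p·N) rows are drawn and each receives one full
    internal validation run with ``cfg.m`` repetitions.  Sample ids are
    preserved through subsampling.  Points too small for K folds are
    skipped with a warning.  At proportion 1.0 the draw is the full
    dataset, so the point reproduces ``run_internal`` under the point's
    recorded seed exactly.
    """
    cfg = cfg or ValidationConfig(m=DEFAULT_POINT_M)
    points: list[DownsamplingPoint] = []
    for p_idx, prop in enumerate(proportions):
        if not 0.0 < prop <= 1.0:
            raise InvalidInputError(f"proportion {prop} outside (0, 1]")
        n_take = int(round(prop * ds.n_samples))
        if n_take < 2 * cfg.k:
            logger.warning(
                "skipping proportion %.3g: %d samples cannot support K=%d",
                prop, n_take, cfg.k)
            continue
        n_draws = 1 if prop >= 1.0 else draws_per_proportion
        for draw in range(n_draws):
            draw_seed = derive_seed(cfg.master_seed, 1, p_idx, draw)
            point_seed = derive_seed(cfg.master_seed, 2, p_idx, draw)
            sub = ds if prop >= 1.0 else _stratified_subsample(ds, n_take, draw_seed)
            try:
                result = run_internal(sub, clf, replace(cfg, master_seed=point_seed))
            except InvalidInputError as exc:
                logger.warning("skipping proportion %.3g draw %d: %s",
                               prop, draw, exc)
                continue
            points.append(DownsamplingPoint(
                proportion=float(prop), realized_n=sub.n_samples, draw=draw,
                oa=result.mean_oa, oa_sd=result.sd_oa,
                aec=result.ec_summary.aec, aec_sd=result.ec_summary.sd,
                n_pairs_undefined=result.ec_summary.n_pairs_undefined,
                seed=point_seed))
    return points


def points_to_frame(points: Sequence[DownsamplingPoint]):
    import pandas as pd

    return pd.DataFrame([{
        "proportion": p.proportion, "realized_n": p.realized_n, "draw": p.draw,
        "oa": p.oa, "oa_sd": p.oa_sd, "aec": p.aec, "aec_sd": p.aec_sd,
        "n_pairs_undefined": p.n_pairs_undefined, "seed": p.seed,
    } for p in points])


def _lowess_at(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
               span: float) -> np.ndarray:
    fitted = lowess(y, x, frac=span, return_sorted=False, xvals=grid)
    return np.asarray(fitted, dtype=float)


def fit_trend(points: Sequence[DownsamplingPoint], span: float = 0.6) -> TrendCurve:
    """Locally weighted (LOWESS) trends of OA and AEC against proportion.

    Points with undefined AEC are excluded from the AEC fit only; both
    smoothers are evaluated on the common sorted grid of observed
    proportions.  Requires at least five defined points per response.
    """
    if not 0.0 < span <= 1.0:
        raise InvalidInputError("span must lie in (0, 1]")
    x_all = np.array([p.proportion for p in points], dtype=float)
    if len(x_all) < 5:
        raise InvalidInputError("trend fitting needs at least 5 points")
    oa = np.array([p.oa for p in points], dtype=float)
    aec_pts = [(p.proportion, p.aec) for p in points if p.aec_defined]
    if len(aec_pts) < 5:
        raise InvalidInputError(
            "trend fitting needs at least 5 points with defined AEC")
    grid = np.unique(x_all)
    y_oa = _lowess_at(x_all, oa, grid, span)
    ax = np.array([a for a, _ in aec_pts])
    ay = np.array([b for _, b in aec_pts])
    y_aec = _lowess_at(ax, ay, grid, span)
    return TrendCurve(x=grid, y_oa=y_oa, y_aec=y_aec, span=span)


def _window_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def _rowwise_corr(xs: np.ndarray, ys: np.ndarray, method: str) -> np.ndarray:
    """Correlation of each row pair; NaN for degenerate rows."""
    if method == "spearman":
        xs = stats.rankdata(xs, axis=1)
        ys = stats.rankdata(ys, axis=1)
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def rolling_correlation(
    pairs: Sequence[tuple[float, float]],
    window_size: int,
    n_boot: int = 500,
    seed: int = 0,
    method: Literal["pearson", "spearman"] = "pearson",
    ci_level: float = 0.95,
) -> RollingCorrelationResult:
    """Bootstrapped sliding-window correlation of metric vs percentage.

    Pairs are sorted by percentage; each contiguous window of
    ``window_size`` points yields the correlation between percentage and
    metric plus a percentile bootstrap interval from ``n_boot`` resamples
    of the window's pairs.  Windows (or resamples) with zero variance on
    either axis yield NaN and are excluded from the percentile interval;
    a window whose resamples are all degenerate gets a NaN interval.
    """
    if window_size < 3:
        raise InvalidInputError("window_size must be at least 3")
    arr = np.asarray(sorted(pairs, key=lambda t: t[0]), dtype=float)
    if len(arr) < window_size:
        raise InvalidInputError(
            f"window_size {window_size} exceeds the {len(arr)} available pairs")
    n_windows = len(arr) - window_size + 1
    centers = np.empty(n_windows)
    corr = np.empty(n_windows)
    lo = np.empty(n_windows)
    hi = np.empty(n_windows)
    alpha = (1.0 - ci_level) / 2.0
    for w in range(n_windows):
        x = arr[w:w + window_size, 0]
        y = arr[w:w + window_size, 1]
        centers[w] = x.mean()
        corr[w] = _window_corr(x, y, method)
        if np.isnan(corr[w]) or n_boot <= 0:
            lo[w] = hi[w] = float("nan")
            continue
        rng = derive_rng(seed, 3, w)
        idx = rng.integers(0, window_size, size=(n_boot, window_size))
        boots = _rowwise_corr(x[idx], y[idx], method)
        boots = boots[~np.isnan(boots)]
        if boots.size == 0:
            lo[w] = hi[w] = float("nan")
        else:
            lo[w] = float(np.percentile(boots, 100 * alpha))
            hi[w] = float(np.percentile(boots, 100 * (1 - alpha)))
    return RollingCorrelationResult(window_size=window_size, centers=centers,
                                    correlation=corr, ci_low=lo, ci_high=hi,
                                    n_boot=n_boot, method=method)


def default_window_sizes(n_pairs: int) -> list[int]:
    """Three window sizes near 5%, 10% and 20% of the pair count."""
    sizes = sorted({max(3, int(round(n_pairs * f))) for f in (0.05, 0.10, 0.20)})
    return [s for s in sizes if s <= n_pairs]
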