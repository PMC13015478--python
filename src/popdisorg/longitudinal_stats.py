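"""Trend tests across sessions.

Every per-session metric becomes a (day, value) series; disease progression
is tested by an F-test of an ordinary least-squares line against the
constant-slope (intercept-only) null.  A segmented variant compares the
slopes before and after a treatment onset day, allowing an intercept jump
at onset, and tests slope equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import ParameterError

__all__ = ["MetricSeries", "TrendResult", "SegmentedTrendResult",
           "slope_f_test", "segmented_slope_comparison"]


@dataclass
class MetricSeries:
    """One metric tracked across sessions for one subject."""

    subject_id: str
    metric: str
    days: np.ndarray
    values: np.ndarray
    treatment_onset_day: Optional[float] = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape or self.days.ndim != 1:
            raise ParameterError("days and values must be equal-length 1-D arrays")
        if np.any(np.diff(self.days) <= 0):
            raise ParameterError("days must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.days.size)


@dataclass
class TrendResult:
    slope: float           # metric units per day
    intercept: float
    f_statistic: float
    p_value: float
    df: tuple[int, int]
    n_points: int


@dataclass
class SegmentedTrendResult:
    slope_pre: float
    slope_post: float
    f_statistic: float
    p_value: float
    df: tuple[int, int]
    n_pre: int
    n_post: int


def slope_f_test(series: MetricSeries) -> TrendResult:
    """F-test of a linear trend against the constant (zero-slope) null.

    Fits value ~ day by OLS and compares against the intercept-only model:
    F = ((RSS0 - RSS1) / 1) / (RSS1 / (n - 2)).  A perfectly collinear
    series gives RSS1 = 0, reported as F = inf and p = 0; a constant
    series gives F = 0 and p = 1.
    """
    n = series.n_points
    if n < 3:
        raise ParameterError(f"need >= 3 points for a slope test, got {n}")
    x, y = series.days, series.values
    if np.var(x) == 0:
        raise ParameterError("day variance is zero")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    intercept, slope = fit.params
    rss1 = float(fit.ssr)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df = (1, n - 2)
    if rss1 <= 0:
        f = float("inf") if rss0 > rss1 else 0.0
        p = 0.0 if rss0 > rss1 else 1.0
    else:
        f = (rss0 - rss1) / (rss1 / (n - 2))
        f = max(f, 0.0)
        p = float(stats.f.sf(f, *df))
    return TrendResult(slope=float(slope), intercept=float(intercept),
                       f_statistic=float(f), p_value=p, df=df, n_points=n)


def segmented_slope_comparison(series: MetricSeries,
                               onset_day: Optional[float] = None) -> SegmentedTrendResult:
    """Test whether the trend slope differs before vs after a treatment onset.

    Fits value = a + b*day + c*I(day >= onset) + d*day*I(day >= onset) and
    tests d = 0 by an F comparison against the d-constrained model.  The
    intercept jump c is always allowed, so a sharp level shift at onset
    (with unchanged drift) does not count as a slope change.  Reports the
    two segment slopes b and b + d.
    """
    onset = onset_day if onset_day is not None else series.treatment_onset_day
    if onset is None:
        raise ParameterError("no treatment onset day given")
    x, y = series.days, series.values
    post = (x >= onset).astype(float)
    n_pre, n_post = int((post == 0).sum()), int((post == 1).sum())
    if n_pre < 3 or n_post < 3:
        raise ParameterError(
            f"need >= 3 points on each side of onset, got {n_pre} pre / {n_post} post")
    X_full = sm.add_constant(np.column_stack([x, post, x * post]))
    X_red = sm.add_constant(np.column_stack([x, post]))
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df = (1, int(full.df_resid))
    if full.ssr <= 0:
        f, p = (float("inf"), 0.0) if red.ssr > full.ssr else (0.0, 1.0)
    else:
        f = (red.ssr - full.ssr) / (full.ssr / full.df_resid)
        f = max(float(f), 0.0)
        p = float(stats.f.sf(f, *df))
    b = float(full.params[1])
    d = float(full.params[3])
    return SegmentedTrendResult(slope_pre=b, slope_post=b + d, f_statistic=f,
                                p_value=p, df=df, n_pre=n_pre, n_post=n_post)


def benjamini_hochberg(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """BH-adjusted q-values (optional; trend tests are reported unadjusted
    by default, one p-value per metric)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out
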