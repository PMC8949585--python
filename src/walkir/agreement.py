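"""Method-agreement statistics: Passing-Bablok regression, ICC, paired t.

These compare model-estimated performance against measured performance
pooled over subjects and visits.  Passing-Bablok regression is the
nonparametric method-comparison regression whose slope is the shifted
median of all pairwise slopes; identity (slope 1, intercept 0 inside the
confidence intervals) indicates the two methods agree up to random error.
The intraclass correlation coefficient quantifies absolute agreement
between the two "raters" (measured, estimated); a paired t-test compares
baseline with end-of-treatment performance.

Passing-Bablok and the ICC are implemented from first principles (pairwise
slope enumeration; two-way random-effects ANOVA mean squares) so that every
step is auditable; they are cross-checked in the test suite against
brute-force enumeration and an independent ICC implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, UndefinedStatisticError

__all__ = [
    "PairedSeries",
    "PassingBablokResult",
    "AgreementResult",
    "passing_bablok",
    "icc_agreement",
    "paired_t",
    "evaluate_agreement",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired measured (x) and model-estimated (y) values with pair labels."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < 3:
            raise ValueError("need at least 3 pairs")
        if np.any(np.isnan(x)) or np.any(np.isnan(y)):
            raise ValueError("missing pairs are not allowed")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.labels and len(self.labels) != len(x):
            raise ValueError("labels must align with pairs")


@dataclass(frozen=True)
class PassingBablokResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    linearity_pvalue: float
    n: int
    n_slopes: int


@dataclass(frozen=True)
class AgreementResult:
    """Bundle of the agreement statistics for one outcome."""

    n: int
    pb: PassingBablokResult
    icc: float
    icc_ci: tuple[float, float]
    t_statistic: float | None = None
    t_pvalue: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pb_slope": self.pb.slope,
            "pb_slope_ci_low": self.pb.slope_ci[0],
            "pb_slope_ci_high": self.pb.slope_ci[1],
            "pb_intercept": self.pb.intercept,
            "pb_intercept_ci_low": self.pb.intercept_ci[0],
            "pb_intercept_ci_high": self.pb.intercept_ci[1],
            "pb_linearity_pvalue": self.pb.linearity_pvalue,
            "icc": self.icc,
            "icc_ci_low": self.icc_ci[0],
            "icc_ci_high": self.icc_ci[1],
            "t_statistic": self.t_statistic,
            "t_pvalue": self.t_pvalue,
        }


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All C(n,2) pairwise slopes; x-ties give +/-inf, 0/0 pairs are dropped."""
    n = len(x)
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0) & (dy == 0))
    dx, dy = dx[keep], dy[keep]
    with np.errstate(divide="ignore"):
        return np.where(dx == 0, np.sign(dy) * np.inf, dy / np.where(dx == 0, 1, dx))


def passing_bablok(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> PassingBablokResult:
    """Passing-Bablok regression of y on x.

    Slope: the median of the sorted pairwise slopes, shifted by
    K = #{slopes < -1} with slopes exactly -1 excluded, which makes the
    estimator invariant to swapping the two methods.  Intercept:
    median(y - slope * x).  Confidence intervals use the asymptotic
    rank-based formula; linearity is assessed by a cusum test over the
    residual signs (Kolmogorov-type p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateDataError("need >= 3 pairs of equal length")
    if np.all(x == x[0]):
        raise DegenerateDataError("all x identical: slopes undefined")
    slopes = _pairwise_slopes(x, y)
    slopes = slopes[slopes != -1.0]  # excluded per the original estimator
    if len(slopes) == 0:
        raise DegenerateDataError("no valid pairwise slopes")
    S = np.sort(slopes)
    N = len(S)
    K = int(np.sum(S < -1.0))

    def _at(idx_1based: int) -> float:
        return float(S[min(max(idx_1based - 1, 0), N - 1)])

    if N % 2 == 1:
        slope = _at((N + 1) // 2 + K)
    else:
        slope = 0.5 * (_at(N // 2 + K) + _at(N // 2 + 1 + K))

    n = len(x)
    w = stats.norm.ppf(1 - alpha / 2) * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((N - w) / 2.0))
    m2 = N - m1 + 1
    slope_lo = _at(m1 + K)
    slope_hi = _at(m2 + K)

    intercept = float(np.median(y - slope * x))
    # upper slope -> lower intercept and vice versa
    intercept_ci = (
        float(np.median(y - slope_hi * x)),
        float(np.median(y - slope_lo * x)),
    )
    lin_p = _cusum_linearity_pvalue(x, y, slope, intercept)
    return PassingBablokResult(
        slope=slope,
        intercept=intercept,
        slope_ci=(slope_lo, slope_hi),
        intercept_ci=intercept_ci,
        linearity_pvalue=lin_p,
        n=n,
        n_slopes=N,
    )


def _cusum_linearity_pvalue(
    x: np.ndarray, y: np.ndarray, slope: float, intercept: float
) -> float:
    """Cusum test of linearity over the signs of the residuals.

    Points above/below the fitted line are scored +sqrt(L/l) / -sqrt(l/L)
    (l above, L below), accumulated in order of increasing x; the maximal
    excursion is referred to the Kolmogorov distribution.
    """
    resid = y - (intercept + slope * x)
    above = resid > 0
    below = resid < 0
    l, L = int(above.sum()), int(below.sum())
    if l == 0 or L == 0:
        return 1.0
    scores = np.zeros(len(x))
    scores[above] = np.sqrt(L / l)
    scores[below] = -np.sqrt(l / L)
    order = np.lexsort((y, x))
    cusum = np.cumsum(scores[order])
    h = np.max(np.abs(cusum)) / np.sqrt(l + L)
    return float(stats.kstwobign.sf(h))


def icc_agreement(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of the n x 2 table whose
    rows are pairs (subject-visits) and columns the two methods::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the confidence interval from the F-distribution bounds
    (McGraw & Wong convention).  Raises :class:`UndefinedStatisticError`
    when there is no between-pair variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateDataError("need >= 3 pairs of equal length")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr + mse, 0):
        raise UndefinedStatisticError("no between-pair variance: ICC undefined")
    icc = (msr - mse) / denom

    if mse == 0 and msc == mse:  # exact agreement: CI collapses
        return float(icc), (float(icc), float(icc))

    # Satterthwaite df for the absolute-agreement interval
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), (float(icc), float(icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    lower = min(float(lower), float(icc))
    upper = max(float(upper), float(icc))
    return float(icc), (lower, upper)


def paired_t(pre: Sequence[float], post: Sequence[float]) -> tuple[float, float]:
    """Paired-samples t-test (two-sided) of post vs pre.

    Identical vectors return (0.0, 1.0) by convention; a nonzero constant
    difference (zero spread, infinite t) raises
    :class:`DegenerateDataError`.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post) or len(pre) < 2:
        raise DegenerateDataError("need >= 2 pairs of equal length")
    diff = post - pre
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return 0.0, 1.0
        raise DegenerateDataError("constant nonzero difference: t is unbounded")
    res = stats.ttest_rel(post, pre)
    return float(res.statistic), float(res.pvalue)


def evaluate_agreement(
    pairs: PairedSeries,
    pre: Sequence[float] | None = None,
    post: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> AgreementResult:
    """All agreement statistics for one measured-vs-estimated paired series.

    ``pre``/``post`` optionally add the baseline vs end-of-treatment
    paired t-test (computed on measured values, not on the pairs).
    """
    pb = passing_bablok(pairs.x, pairs.y, alpha=alpha)
    icc, icc_ci = icc_agreement(pairs.x, pairs.y, alpha=alpha)
    t_stat = t_p = None
    if pre is not None and post is not None:
        t_stat, t_p = paired_t(pre, post)
    return AgreementResult(
        n=len(pairs.x), pb=pb, icc=icc, icc_ci=icc_ci, t_statistic=t_stat, t_pvalue=t_p
    )
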