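"""Per-subject calibration of the impulse-response model on clinic visits.

Subjects are measured only at a handful of clinic visits (T0 plus about
four follow-ups), so the fit must be robust with very sparse data.  The
baseline measurement pins p0 (it *is* the starting performance value), and
the remaining four parameters are estimated by minimising the residual sum
of squares between predicted p(t) and measured p(m) at the post-baseline
visits.

For fixed decay constants the model is linear in (k1, k2), so the fit is a
profiled search: a deterministic coarse grid over (tau1, tau2) with the
magnitudes solved per grid point by nonnegative linear least squares,
followed by a local Nelder-Mead refinement of the decay constants.  Grid
ties are broken toward the smallest tau2, then the smallest tau1, keeping
the output deterministic.

Goodness of fit is summarised by R^2 = 1 - RSS/TSS over the fitted visits
and an ANOVA-style F test on the RSS; a fit is flagged *acceptable* when
R^2 exceeds 0.30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import lsq_linear, minimize

from .exceptions import (
    InsufficientDataError,
    UndefinedStatisticError,
    UnidentifiableError,
)
from .model import IRParameters, predict_at_days
from .trimp import TrimpSeries

__all__ = [
    "VisitMeasurement",
    "FitConfig",
    "FitResult",
    "fit_subject",
    "goodness_of_fit",
    "cohort_summary",
    "read_visits",
    "write_visits",
]

VISIT_COLUMNS = ["subject_id", "visit_label", "day_index", "pfwd_m", "six_mwd_m"]

#: Outcome selector values accepted throughout the package.
OUTCOMES = ("pfwd", "6mwd")


@dataclass(frozen=True)
class VisitMeasurement:
    """Measured performance at one dated clinic visit (T0..T4)."""

    visit_label: str
    day_index: int
    pfwd: float
    six_mwd: float

    def __post_init__(self) -> None:
        if self.day_index < 0:
            raise ValueError("day_index must be >= 0")
        if self.visit_label == "T0" and self.day_index != 0:
            raise ValueError("T0 must have day_index 0")
        if self.pfwd < 0 or self.six_mwd < 0:
            raise ValueError("measurements must be >= 0 m")
        if self.pfwd > self.six_mwd:
            raise ValueError(
                f"pain-free distance ({self.pfwd}) cannot exceed total ({self.six_mwd})"
            )

    def value(self, outcome: str) -> float:
        if outcome == "pfwd":
            return self.pfwd
        if outcome == "6mwd":
            return self.six_mwd
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


@dataclass(frozen=True)
class FitConfig:
    """Settings of the grid-then-refine RSS minimisation.

    Decay-constant bounds cover the published cohort means +/- 2 SD;
    ``df_model`` = 2 treats the two magnitudes as the effective model
    degrees of freedom (the taus are profiled), giving residual df = n - 3.
    """

    tau1_bounds: tuple[float, float] = (10.0, 80.0)
    tau2_bounds: tuple[float, float] = (5.0, 60.0)
    grid_step: float = 2.5
    refine: bool = True
    refine_xatol: float = 0.01
    k_max: float = 5.0
    df_model: int = 2
    r2_threshold: float = 0.30


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with RSS, R^2 and the fit's F test."""

    params: IRParameters
    rss: float
    r_squared: float
    f_statistic: float
    f_pvalue: float
    acceptable: bool
    n_obs: int


def _response_basis(w: np.ndarray, days: np.ndarray, tau: float) -> np.ndarray:
    """sum_{i < d} w(i) exp(-(d - i)/tau) for each visit day d."""
    lags = days[:, None] - np.arange(len(w))[None, :]
    kernel = np.where(lags > 0, np.exp(-np.clip(lags, 0, None) / tau), 0.0)
    return kernel @ w


def _profiled_rss(
    w: np.ndarray,
    days: np.ndarray,
    resid: np.ndarray,
    tau1: float,
    tau2: float,
    k_max: float,
) -> tuple[float, float, float]:
    """Best bounded (k1, k2) in [0, k_max] and RSS for fixed decay constants.

    The model is linear in the magnitudes given the decay constants, so
    this is a tiny bounded least-squares problem; the upper bound keeps
    the near-collinear tau1 ~ tau2 direction from producing huge
    mutually-cancelling magnitudes.
    """
    A = _response_basis(w, days, tau1)
    B = _response_basis(w, days, tau2)
    X = np.column_stack([A, -B])
    sol = lsq_linear(X, resid, bounds=(0.0, k_max), method="bvls")
    rss = float(np.sum((X @ sol.x - resid) ** 2))
    return rss, float(sol.x[0]), float(sol.x[1])


def fit_subject(
    trimps: TrimpSeries,
    visits: Sequence[VisitMeasurement],
    outcome: str = "pfwd",
    config: FitConfig | None = None,
) -> FitResult:
    """Calibrate the model for one subject and outcome (PFWD or 6MWD).

    Requires a T0 visit at day 0 (fixing p0) and at least three
    post-baseline visits.  Returns the RSS-minimising parameters together
    with fit statistics over the post-baseline visits.
    """
    config = config or FitConfig()
    t0 = [v for v in visits if v.day_index == 0]
    if not t0:
        raise InsufficientDataError("no baseline (day 0) visit: p0 cannot be fixed")
    p0 = t0[0].value(outcome)
    fit_visits = sorted(
        (v for v in visits if v.day_index > 0), key=lambda v: v.day_index
    )
    if len(fit_visits) < 3:
        raise InsufficientDataError(
            f"need >= 3 post-baseline visits, got {len(fit_visits)}"
        )
    w = trimps.values
    if not np.any(w > 0):
        raise UnidentifiableError("all-zero TRIMP series: parameters unidentifiable")

    days = np.array([v.day_index for v in fit_visits])
    y = np.array([v.value(outcome) for v in fit_visits])
    resid = y - p0

    lo1, hi1 = config.tau1_bounds
    lo2, hi2 = config.tau2_bounds
    grid1 = np.arange(lo1, hi1 + 1e-9, config.grid_step)
    grid2 = np.arange(lo2, hi2 + 1e-9, config.grid_step)

    best: tuple[float, float, float, float, float] | None = None
    for tau2 in grid2:  # tau2-major order implements the tie-break rule
        for tau1 in grid1:
            rss, k1, k2 = _profiled_rss(w, days, resid, tau1, tau2, config.k_max)
            if best is None or rss < best[0]:
                best = (rss, tau1, tau2, k1, k2)
    assert best is not None
    rss, tau1, tau2, k1, k2 = best

    if config.refine:
        def objective(x: np.ndarray) -> float:
            return _profiled_rss(w, days, resid, x[0], x[1], config.k_max)[0]

        res = minimize(
            objective,
            x0=[tau1, tau2],
            method="Nelder-Mead",
            bounds=[config.tau1_bounds, config.tau2_bounds],
            options={"xatol": config.refine_xatol, "fatol": 1e-12, "maxiter": 500},
        )
        r_rss, r_k1, r_k2 = _profiled_rss(w, days, resid, res.x[0], res.x[1], config.k_max)
        if r_rss <= rss:
            rss, tau1, tau2, k1, k2 = r_rss, float(res.x[0]), float(res.x[1]), r_k1, r_k2

    params = IRParameters(p0=p0, k1=k1, k2=k2, tau1=tau1, tau2=tau2)
    predicted = predict_at_days(params, trimps, days)
    try:
        r2, f_stat, f_p = goodness_of_fit(predicted, y, df_model=config.df_model)
    except UndefinedStatisticError:
        r2, f_stat, f_p = float("nan"), float("nan"), float("nan")
    return FitResult(
        params=params,
        rss=float(np.sum((predicted - y) ** 2)),
        r_squared=r2,
        f_statistic=f_stat,
        f_pvalue=f_p,
        acceptable=bool(r2 > config.r2_threshold),
        n_obs=len(fit_visits),
    )


def goodness_of_fit(
    predicted: np.ndarray, measured: np.ndarray, df_model: int = 2
) -> tuple[float, float, float]:
    """R^2, F statistic and p-value for predicted vs measured visits.

    R^2 = 1 - RSS/TSS with TSS about the mean of the measured values;
    F = ((TSS - RSS)/df_model) / (RSS/df_resid) with df_resid = n - df_model - 1.
    A perfect fit (RSS = 0) yields R^2 = 1 with an infinite F (p = 0);
    zero TSS raises :class:`UndefinedStatisticError`.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if len(predicted) != len(measured) or len(measured) < 3:
        raise InsufficientDataError("need >= 3 paired points of equal length")
    rss = float(np.sum((measured - predicted) ** 2))
    tss = float(np.sum((measured - measured.mean()) ** 2))
    if tss == 0:
        raise UndefinedStatisticError("zero total sum of squares: R^2 undefined")
    r2 = 1.0 - rss / tss
    df_resid = len(measured) - df_model - 1
    if df_resid < 1:
        return r2, float("nan"), float("nan")
    if rss == 0:
        return r2, float("inf"), 0.0
    f_stat = ((tss - rss) / df_model) / (rss / df_resid)
    f_p = float(stats.f.sf(f_stat, df_model, df_resid)) if f_stat >= 0 else 1.0
    return r2, float(f_stat), f_p


_PARAM_FIELDS = ("p0", "k1", "k2", "tau1", "tau2")


def cohort_summary(
    fits: Sequence[FitResult], groups: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean +/- SD of each fitted parameter, overall and by subgroup.

    Returns a tidy frame with columns group, n, n_acceptable, parameter,
    mean, sd (population SD convention ``ddof=1``; SD 0 for a single fit).
    """
    if not fits:
        raise InsufficientDataError("no fits to summarise")
    if groups is not None and len(groups) != len(fits):
        raise ValueError("groups must align with fits")
    labels = ["all"] * len(fits) if groups is None else list(groups)
    frame = pd.DataFrame(
        {
            "group": labels,
            "acceptable": [f.acceptable for f in fits],
            "r_squared": [f.r_squared for f in fits],
            **{p: [getattr(f.params, p) for f in fits] for p in _PARAM_FIELDS},
        }
    )
    rows = []
    group_names = ["all"] + (sorted(set(labels)) if groups is not None else [])
    for name in dict.fromkeys(group_names):  # preserve order, drop duplicates
        sub = frame if name == "all" else frame[frame["group"] == name]
        for param in (*_PARAM_FIELDS, "r_squared"):
            vals = sub[param].to_numpy(dtype=float)
            rows.append(
                {
                    "group": name,
                    "n": len(sub),
                    "n_acceptable": int(sub["acceptable"].sum()),
                    "parameter": param,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialect


def write_visits(visits: dict[str, Sequence[VisitMeasurement]], path) -> None:
    rows = [
        {
            "subject_id": sid,
            "visit_label": v.visit_label,
            "day_index": v.day_index,
            "pfwd_m": v.pfwd,
            "six_mwd_m": v.six_mwd,
        }
        for sid, vs in visits.items()
        for v in vs
    ]
    pd.DataFrame(rows, columns=VISIT_COLUMNS).to_csv(path, index=False)


def read_visits(path) -> dict[str, list[VisitMeasurement]]:
    """Read the visits CSV dialect into ``{subject_id: [visits...]}``."""
    from .exceptions import DataFormatError

    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"visits file {path} missing columns {missing}")
    out: dict[str, list[VisitMeasurement]] = {}
    for i, row in df.iterrows():
        try:
            v = VisitMeasurement(
                visit_label=str(row["visit_label"]),
                day_index=int(row["day_index"]),
                pfwd=float(row["pfwd_m"]),
                six_mwd=float(row["six_mwd_m"]),
            )
        except (ValueError, TypeError) as exc:
            raise DataFormatError(f"visits row {i + 2} of {path}: {exc}") from exc
        out.setdefault(str(row["subject_id"]), []).append(v)
    return out
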