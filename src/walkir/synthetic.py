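"""Synthetic TiTo cohort generator.

Emulates the study design end-to-end so the whole pipeline is testable
without any patient data: baseline walking performance drawn from the
published cohort distributions (PFWD 114 +/- 61 m, 6MWD 287 +/- 85 m,
75% men), a 27-week home walking program of two daily 10-min intermittent
sessions whose cadence starts at 60% of the habitual speed and rises 3%
per week up to a per-subject 90-100% cap, session-level adherence of 92%,
"true" impulse-response parameters drawn from the published parameter
distributions, and noisy clinic-visit measurements at weeks
{0, 5, 12, 20, 28} (+/- the stated jitter) generated from the true model.

The generator draws parameters as truncated normals (only marginals are
published). Truncation at zero shifts the realised mean of a
heavily-truncated magnitude (e.g. k1 ~ N(0.03, 0.06) restricted to >= 0
has mean ~0.055); property tests therefore compare empirical means
against the analytic truncated-normal mean.  Because the published
magnitudes have SDs two to three times their means, *independent* draws
would routinely produce subjects whose true pain-free distance collapses
below zero or overtakes their total distance — trajectories no real
claudicant cohort shows.  Draws are therefore jointly rejection-sampled
until the true trajectories satisfy 0 < PFWD(t) < 6MWD(t) through the
follow-up horizon (``enforce_plausibility``; marginal-distribution
checks can switch it off), and decay constants are drawn within the
identifiable range the calibrator searches (cohort mean +/- ~2.5 SD).
The habitual walking speed distribution is not published; the default
N(95, 15) steps/min truncated at 40 is a plausible claudicant cadence,
which is why cohort-level TRIMP magnitudes are checked only
qualitatively.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .calibration import VisitMeasurement, write_visits
from .exceptions import ConfigError
from .model import IRParameters, predict_at_days
from .trimp import (
    SessionPrescription,
    SubjectBaseline,
    TrimpSeries,
    build_trimp_series,
    write_baselines,
    write_diary,
)

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "generate_prescriptions",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Distributions and design constants of the synthetic cohort.

    Two-tuples are (mean, sd) of truncated normal draws. Defaults mirror
    the published cohort tables and program description.
    """

    n_subjects: int = 100
    seed: int = 0
    male_fraction: float = 0.75
    # baseline performance
    six_mwd_baseline: tuple[float, float] = (287.0, 85.0)
    six_mwd_min: float = 50.0
    pfwd_fraction: tuple[float, float] = (0.40, 0.12)  # PFWD as fraction of 6MWD
    pfwd_fraction_bounds: tuple[float, float] = (0.05, 0.90)
    habitual_speed: tuple[float, float] = (95.0, 15.0)
    habitual_speed_min: float = 40.0
    # impulse-response parameter distributions (published cohort means/SDs)
    k1_pfwd: tuple[float, float] = (0.03, 0.06)
    k2_pfwd: tuple[float, float] = (0.03, 0.06)
    tau1_pfwd: tuple[float, float] = (45.0, 13.0)
    tau2_pfwd: tuple[float, float] = (25.0, 10.0)
    k1_6mwd: tuple[float, float] = (0.02, 0.03)
    k2_6mwd: tuple[float, float] = (0.03, 0.03)
    tau1_6mwd: tuple[float, float] = (37.0, 11.0)
    tau2_6mwd: tuple[float, float] = (26.0, 9.0)
    k_min: float = 0.0
    tau1_range: tuple[float, float] = (10.0, 80.0)
    tau2_range: tuple[float, float] = (5.0, 60.0)
    enforce_plausibility: bool = True
    max_redraws: int = 1000
    # program structure
    program_weeks: tuple[float, float] = (27.0, 3.0)
    program_weeks_bounds: tuple[int, int] = (21, 33)
    sessions_per_day: int = 2
    walk_unit_min: float = 1.0
    rest_unit_min: float = 1.0
    repetitions: int = 10
    speed_start_fraction: float = 0.60
    weekly_increment: float = 0.03
    cap_range: tuple[float, float] = (0.90, 1.00)
    adherence: float = 0.92
    # measurement design
    visit_weeks: tuple[int, ...] = (0, 5, 12, 20, 28)
    visit_jitter_weeks: tuple[int, ...] = (0, 1, 2, 2, 3)
    noise_sd: float = 15.0
    start_date: dt.date = dt.date(2018, 1, 1)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 0 <= self.male_fraction <= 1 or not 0 <= self.adherence <= 1:
            raise ConfigError("probabilities must be in [0, 1]")
        for name in ("six_mwd_baseline", "pfwd_fraction", "habitual_speed",
                     "k1_pfwd", "k2_pfwd", "tau1_pfwd", "tau2_pfwd",
                     "k1_6mwd", "k2_6mwd", "tau1_6mwd", "tau2_6mwd",
                     "program_weeks"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ConfigError(f"{name} SD must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(self.visit_weeks) != len(self.visit_jitter_weeks):
            raise ConfigError("visit_weeks and visit_jitter_weeks must align")
        if self.tau1_range[0] <= 0 or self.tau2_range[0] <= 0:
            raise ConfigError("decay-constant ranges must stay positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = dt.date.fromisoformat(d["start_date"])
        for key, value in list(d.items()):
            if isinstance(value, list):
                d[key] = tuple(value)
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad cohort config {path}: {exc}") from exc


@dataclass(frozen=True)
class SyntheticSubject:
    """One generated subject: ground truth plus the observable records."""

    subject_id: str
    sex: str  # "M" | "F"
    baseline: SubjectBaseline
    true_params_pfwd: IRParameters
    true_params_6mwd: IRParameters
    diary: tuple[SessionPrescription, ...]
    visits: tuple[VisitMeasurement, ...]
    program_weeks: int

    def trimp_series(self) -> TrimpSeries:
        end = self.baseline_start() + dt.timedelta(days=self.program_weeks * 7 - 1)
        return build_trimp_series(self.diary, self.baseline,
                                  start=self.baseline_start(), end=end)

    def baseline_start(self) -> dt.date:
        return min(s.date for s in self.diary)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float = np.inf, size=None):
    if sd == 0:
        val = np.clip(mean, low, high)
        return val if size is None else np.full(size, val)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_prescriptions(
    baseline: SubjectBaseline,
    config: CohortConfig,
    weeks: int | None = None,
    cap: float | None = None,
    start_date: dt.date | None = None,
) -> list[SessionPrescription]:
    """The TiTo prescription schedule for one subject (full adherence).

    Week ``w`` (1-based) prescribes a cadence of
    ``round(habitual * min(start_fraction + increment * (w - 1), cap))``
    steps/min — 60% of habitual speed in week 1, +3% per week, capped at
    the subject's 90-100% ceiling — for ``sessions_per_day`` sessions of
    ``repetitions`` walk bouts each, every day.
    """
    weeks = int(weeks if weeks is not None else round(config.program_weeks[0]))
    cap = float(cap if cap is not None else np.mean(config.cap_range))
    start_date = start_date or config.start_date
    sessions = []
    for week in range(1, weeks + 1):
        fraction = min(
            config.speed_start_fraction + config.weekly_increment * (week - 1), cap
        )
        cadence = float(round(baseline.habitual_speed * fraction))
        for day in range(7):
            date = start_date + dt.timedelta(days=(week - 1) * 7 + day)
            for _ in range(config.sessions_per_day):
                sessions.append(
                    SessionPrescription(
                        date=date,
                        cadence=cadence,
                        walk_unit_min=config.walk_unit_min,
                        rest_unit_min=config.rest_unit_min,
                        repetitions=config.repetitions,
                        performed_fraction=1.0,
                    )
                )
    return sessions


def _draw_params(rng: np.random.Generator, config: CohortConfig,
                 outcome: str, p0: float) -> IRParameters:
    k1m, k1s = getattr(config, f"k1_{outcome}")
    k2m, k2s = getattr(config, f"k2_{outcome}")
    t1m, t1s = getattr(config, f"tau1_{outcome}")
    t2m, t2s = getattr(config, f"tau2_{outcome}")
    return IRParameters(
        p0=p0,
        k1=float(_truncnorm(rng, k1m, k1s, config.k_min)),
        k2=float(_truncnorm(rng, k2m, k2s, config.k_min)),
        tau1=float(_truncnorm(rng, t1m, t1s, *config.tau1_range)),
        tau2=float(_truncnorm(rng, t2m, t2s, *config.tau2_range)),
    )


def _draw_plausible_params(
    rng: np.random.Generator,
    config: CohortConfig,
    trimps: TrimpSeries,
    pfwd0: float,
    six0: float,
    horizon: int,
) -> tuple[IRParameters, IRParameters]:
    """Joint draw of PFWD and 6MWD parameters, rejection-sampled so the
    true daily trajectories keep 0 < PFWD(t) < 6MWD(t) up to ``horizon``."""
    from .model import predict_performance  # local import avoids cycle at module load

    last = None
    for _ in range(config.max_redraws if config.enforce_plausibility else 1):
        params_pfwd = _draw_params(rng, config, "pfwd", pfwd0)
        params_6mwd = _draw_params(rng, config, "6mwd", six0)
        last = (params_pfwd, params_6mwd)
        if not config.enforce_plausibility:
            break
        pfwd_t = predict_performance(params_pfwd, trimps, horizon).predicted
        six_t = predict_performance(params_6mwd, trimps, horizon).predicted
        if np.all(pfwd_t > 0) and np.all(pfwd_t < six_t) and np.all(six_t > 0):
            break
    assert last is not None
    return last


def generate_cohort(config: CohortConfig | None = None) -> list[SyntheticSubject]:
    """Draw a full synthetic cohort; reproducible given ``config.seed``.

    Visit measurements are the true-model predictions at the (jittered)
    visit days plus i.i.d. Gaussian noise of SD ``noise_sd`` m, clipped at
    0 and at PFWD <= 6MWD; the baseline visit *is* the baseline test and
    carries no noise. Sessions are independently skipped with probability
    ``1 - adherence`` (skipped sessions stay in the diary with
    performed_fraction 0 and contribute w = 0).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    subjects = []
    for idx in range(config.n_subjects):
        sid = f"S{idx + 1:03d}"
        sex = "M" if rng.random() < config.male_fraction else "F"
        six0 = float(_truncnorm(rng, *config.six_mwd_baseline, config.six_mwd_min))
        frac = float(
            _truncnorm(
                rng,
                *config.pfwd_fraction,
                config.pfwd_fraction_bounds[0],
                config.pfwd_fraction_bounds[1],
            )
        )
        pfwd0 = six0 * frac
        habitual = float(_truncnorm(rng, *config.habitual_speed, config.habitual_speed_min))
        baseline = SubjectBaseline(habitual_speed=habitual, p0_pfwd=pfwd0, p0_6mwd=six0)

        weeks = int(
            np.clip(
                round(float(rng.normal(*config.program_weeks))),
                *config.program_weeks_bounds,
            )
        )
        cap = float(rng.uniform(*config.cap_range))
        diary = generate_prescriptions(baseline, config, weeks=weeks, cap=cap)
        if config.adherence < 1:
            skipped = rng.random(len(diary)) >= config.adherence
            diary = [
                dataclasses.replace(s, performed_fraction=0.0) if skip else s
                for s, skip in zip(diary, skipped)
            ]

        end = config.start_date + dt.timedelta(days=weeks * 7 - 1)
        trimps = build_trimp_series(diary, baseline, start=config.start_date, end=end)

        horizon = max(
            weeks * 7,
            max(config.visit_weeks) * 7 + 7 * max(config.visit_jitter_weeks),
        )
        params_pfwd, params_6mwd = _draw_plausible_params(
            rng, config, trimps, pfwd0, six0, horizon
        )

        visit_days = []
        for week, jitter in zip(config.visit_weeks, config.visit_jitter_weeks):
            day = week * 7
            if jitter > 0:
                day += int(rng.integers(-7 * jitter, 7 * jitter + 1))
            visit_days.append(max(day, 0))
        visit_days[0] = 0
        # enforce strictly increasing schedule
        for i in range(1, len(visit_days)):
            visit_days[i] = max(visit_days[i], visit_days[i - 1] + 7)

        days = np.array(visit_days)
        true_pfwd = predict_at_days(params_pfwd, trimps, days)
        true_6mwd = predict_at_days(params_6mwd, trimps, days)
        visits = []
        for j, day in enumerate(visit_days):
            if j == 0:
                pfwd_m, six_m = pfwd0, six0
            else:
                pfwd_m = max(true_pfwd[j] + rng.normal(0, config.noise_sd), 0.0)
                six_m = max(true_6mwd[j] + rng.normal(0, config.noise_sd), 0.0)
                pfwd_m = min(pfwd_m, six_m)
            visits.append(
                VisitMeasurement(
                    visit_label=f"T{j}",
                    day_index=int(day),
                    pfwd=float(pfwd_m),
                    six_mwd=float(six_m),
                )
            )
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                sex=sex,
                baseline=baseline,
                true_params_pfwd=params_pfwd,
                true_params_6mwd=params_6mwd,
                diary=tuple(diary),
                visits=tuple(visits),
                program_weeks=weeks,
            )
        )
    return subjects


def write_cohort(cohort: list[SyntheticSubject], outdir) -> dict[str, Path]:
    """Emit the diary/baseline/visits CSV dialects (drop-in data source)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "diary": outdir / "diary.csv",
        "baseline": outdir / "baseline.csv",
        "visits": outdir / "visits.csv",
        "truth": outdir / "true_params.csv",
    }
    write_diary({s.subject_id: list(s.diary) for s in cohort}, paths["diary"])
    write_baselines({s.subject_id: s.baseline for s in cohort}, paths["baseline"])
    write_visits({s.subject_id: list(s.visits) for s in cohort}, paths["visits"])
    import pandas as pd

    rows = []
    for s in cohort:
        for outcome, p in (("pfwd", s.true_params_pfwd), ("6mwd", s.true_params_6mwd)):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "sex": s.sex,
                    "outcome": outcome,
                    "p0": p.p0,
                    "k1": p.k1,
                    "k2": p.k2,
                    "tau1": p.tau1,
                    "tau2": p.tau2,
                }
            )
    pd.DataFrame(rows).to_csv(paths["truth"], index=False)
    return paths
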