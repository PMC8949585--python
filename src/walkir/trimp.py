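"""Training-impulse (TRIMP) quantification of intermittent walking sessions.

A test-in/train-out (TiTo) session prescribes intermittent walking at home:
short walk bouts at a metronome-controlled cadence, separated by equal rest
bouts.  Each session's training impulse is the product of three factors:

* **intensity** — prescribed training cadence over the subject's habitual
  walking cadence (both in steps/min), a dimensionless relative load;
* **density** — walking time over total elapsed session time (the final
  walk bout is not followed by a rest, so 10 one-minute walks with
  one-minute rests span 19 minutes);
* **volume** — total number of steps actually performed.

The daily training quantity ``w(t)`` sums the impulses of every session
performed on day ``t`` and is the input signal of the fitness-fatigue
performance model (:mod:`walkir.model`).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataFormatError, InvalidBaselineError, SpanError

__all__ = [
    "SessionPrescription",
    "SubjectBaseline",
    "TrimpSeries",
    "compute_intensity",
    "compute_density",
    "compute_volume",
    "compute_session_trimp",
    "build_trimp_series",
    "read_diary",
    "write_diary",
    "read_baselines",
    "write_baselines",
]

#: Column order of the diary CSV dialect. ``subject_id`` is optional and,
#: when present, comes first.
DIARY_COLUMNS = [
    "date",
    "cadence_spm",
    "walk_min",
    "rest_min",
    "repetitions",
    "performed_fraction",
]

BASELINE_COLUMNS = ["subject_id", "habitual_speed_spm", "pfwd_m", "six_mwd_m"]


@dataclass(frozen=True)
class SessionPrescription:
    """One prescribed walking session: the walk/rest/cadence structure.

    Parameters
    ----------
    date
        Calendar day of the session.
    cadence
        Prescribed training speed in steps/min (metronome cadence).
    walk_unit_min
        Minutes per walk bout.
    rest_unit_min
        Minutes per rest bout between walk bouts.
    repetitions
        Number of prescribed walk bouts.
    performed_fraction
        Fraction in [0, 1] of the prescribed repetitions actually done
        (diary adherence); 0 marks a skipped session.
    """

    date: dt.date
    cadence: float
    walk_unit_min: float = 1.0
    rest_unit_min: float = 1.0
    repetitions: int = 10
    performed_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError(f"cadence must be > 0, got {self.cadence}")
        if self.walk_unit_min <= 0:
            raise ValueError(f"walk_unit_min must be > 0, got {self.walk_unit_min}")
        if self.rest_unit_min < 0:
            raise ValueError(f"rest_unit_min must be >= 0, got {self.rest_unit_min}")
        if self.repetitions < 1:
            raise ValueError(f"repetitions must be >= 1, got {self.repetitions}")
        if not 0.0 <= self.performed_fraction <= 1.0:
            raise ValueError(
                f"performed_fraction must be in [0, 1], got {self.performed_fraction}"
            )


@dataclass(frozen=True)
class SubjectBaseline:
    """Baseline 6-min walking test result for one subject.

    ``habitual_speed`` is the step cadence counted during the first minute
    of the baseline test; ``p0_pfwd``/``p0_6mwd`` are the pain-free and
    total distances (m), the starting performance values p(0).
    """

    habitual_speed: float
    p0_pfwd: float
    p0_6mwd: float

    def __post_init__(self) -> None:
        if self.habitual_speed <= 0:
            raise InvalidBaselineError(
                f"habitual walking speed must be > 0 steps/min, got {self.habitual_speed}"
            )
        if self.p0_pfwd < 0 or self.p0_6mwd < 0:
            raise InvalidBaselineError("baseline distances must be >= 0 m")
        if self.p0_pfwd > self.p0_6mwd:
            raise InvalidBaselineError(
                f"pain-free distance ({self.p0_pfwd} m) cannot exceed "
                f"total distance ({self.p0_6mwd} m)"
            )


@dataclass(frozen=True)
class TrimpSeries:
    """Daily training quantity w(t): one value per calendar day (0 on rest days)."""

    start_date: dt.date
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("TRIMP series must be one-dimensional")
        if np.any(values < 0):
            raise ValueError("TRIMP values must be >= 0")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def day_index(self, date: dt.date) -> int:
        return (date - self.start_date).days

    def to_frame(self) -> pd.DataFrame:
        days = np.arange(len(self.values))
        dates = [self.start_date + dt.timedelta(days=int(d)) for d in days]
        return pd.DataFrame({"day": days, "date": dates, "trimp": self.values})


def compute_intensity(session: SessionPrescription, baseline: SubjectBaseline) -> float:
    """Relative intensity: training cadence over habitual cadence.

    Both cadences are in steps/min, so the ratio is dimensionless; e.g. a
    60 steps/min prescription for a subject walking habitually at
    100 steps/min gives 0.60.
    """
    if baseline.habitual_speed <= 0:  # defensive; the dataclass already rejects this
        raise InvalidBaselineError("habitual walking speed must be > 0")
    return session.cadence / baseline.habitual_speed


def compute_density(session: SessionPrescription) -> float:
    """Session density: walking minutes over total elapsed minutes.

    The final walk bout has no trailing rest, so the elapsed time of ``r``
    bouts is ``r * walk + (r - 1) * rest`` minutes (10 x 1-min walks with
    1-min rests -> 10/19). Always in (0, 1].
    """
    walk = session.walk_unit_min * session.repetitions
    total = walk + session.rest_unit_min * (session.repetitions - 1)
    return walk / total


def compute_volume(session: SessionPrescription) -> float:
    """Total steps performed: cadence x minutes per bout x bouts done."""
    return (
        session.cadence
        * session.walk_unit_min
        * session.repetitions
        * session.performed_fraction
    )


def compute_session_trimp(
    session: SessionPrescription,
    baseline: SubjectBaseline,
    rounded: bool = False,
) -> float:
    """Session TRIMP = intensity x density x volume (arbitrary units).

    With ``rounded=True`` the intensity and density are rounded to two
    decimals before multiplying and the product is rounded to the nearest
    integer a.u. — the presentation convention of the published worked
    example (0.60 x 0.53 x 600 = 191 a.u.). The default keeps full
    floating precision (the same session gives 3600/19 ~= 189.47 a.u.).
    """
    intensity = compute_intensity(session, baseline)
    density = compute_density(session)
    volume = compute_volume(session)
    if rounded:
        return float(round(round(intensity, 2) * round(density, 2) * volume))
    return intensity * density * volume


def build_trimp_series(
    sessions: Iterable[SessionPrescription],
    baseline: SubjectBaseline,
    start: dt.date | None = None,
    end: dt.date | None = None,
) -> TrimpSeries:
    """Aggregate session TRIMPs into the daily series w(t).

    Each day's value is the sum of the TRIMPs of all sessions on that day
    (two sessions per day under the standard prescription); days without a
    session get 0. ``start``/``end`` (inclusive) default to the first/last
    session date; a session outside an explicit span raises
    :class:`~walkir.exceptions.SpanError`.
    """
    sessions = list(sessions)
    if not sessions and (start is None or end is None):
        raise SpanError("an empty session list needs an explicit start and end date")
    if start is None:
        start = min(s.date for s in sessions)
    if end is None:
        end = max(s.date for s in sessions)
    if end < start:
        raise SpanError(f"end date {end} precedes start date {start}")
    n_days = (end - start).days + 1
    values = np.zeros(n_days)
    for s in sessions:
        idx = (s.date - start).days
        if not 0 <= idx < n_days:
            raise SpanError(f"session on {s.date} outside span {start}..{end}")
        values[idx] += compute_session_trimp(s, baseline)
    return TrimpSeries(start_date=start, values=values)


# ---------------------------------------------------------------------------
# CSV dialects


def write_diary(
    diaries: Mapping[str, Sequence[SessionPrescription]], path
) -> None:
    """Write diaries for one or more subjects to the diary CSV dialect."""
    rows = []
    for subject_id, sessions in diaries.items():
        for s in sessions:
            rows.append(
                {
                    "subject_id": subject_id,
                    "date": s.date.isoformat(),
                    "cadence_spm": s.cadence,
                    "walk_min": s.walk_unit_min,
                    "rest_min": s.rest_unit_min,
                    "repetitions": s.repetitions,
                    "performed_fraction": s.performed_fraction,
                }
            )
    pd.DataFrame(rows, columns=["subject_id", *DIARY_COLUMNS]).to_csv(path, index=False)


def read_diary(path) -> dict[str, list[SessionPrescription]]:
    """Read a diary CSV; returns ``{subject_id: [sessions...]}``.

    A file without a ``subject_id`` column is treated as a single subject
    keyed ``""``. Malformed rows raise :class:`DataFormatError` naming the
    row number.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"diary file {path} missing columns {missing}")
    if "subject_id" not in df.columns:
        df["subject_id"] = ""
    out: dict[str, list[SessionPrescription]] = {}
    for i, row in df.iterrows():
        try:
            session = SessionPrescription(
                date=dt.date.fromisoformat(str(row["date"])),
                cadence=float(row["cadence_spm"]),
                walk_unit_min=float(row["walk_min"]),
                rest_unit_min=float(row["rest_min"]),
                repetitions=int(row["repetitions"]),
                performed_fraction=float(row["performed_fraction"]),
            )
        except (ValueError, TypeError) as exc:
            raise DataFormatError(f"diary row {i + 2} of {path}: {exc}") from exc
        out.setdefault(str(row["subject_id"]), []).append(session)
    return out


def write_baselines(baselines: Mapping[str, SubjectBaseline], path) -> None:
    rows = [
        {
            "subject_id": sid,
            "habitual_speed_spm": b.habitual_speed,
            "pfwd_m": b.p0_pfwd,
            "six_mwd_m": b.p0_6mwd,
        }
        for sid, b in baselines.items()
    ]
    pd.DataFrame(rows, columns=BASELINE_COLUMNS).to_csv(path, index=False)


def read_baselines(path) -> dict[str, SubjectBaseline]:
    """Read the baseline CSV dialect into ``{subject_id: SubjectBaseline}``."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in BASELINE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"baseline file {path} missing columns {missing}")
    out: dict[str, SubjectBaseline] = {}
    for i, row in df.iterrows():
        try:
            out[str(row["subject_id"])] = SubjectBaseline(
                habitual_speed=float(row["habitual_speed_spm"]),
                p0_pfwd=float(row["pfwd_m"]),
                p0_6mwd=float(row["six_mwd_m"]),
            )
        except (ValueError, TypeError, InvalidBaselineError) as exc:
            raise DataFormatError(f"baseline row {i + 2} of {path}: {exc}") from exc
    return out
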