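"""End-to-end pipeline: diary -> TRIMP -> fit -> agreement -> report.

Orchestrates the per-subject workflow over a cohort read from the CSV
dialects (diary, baseline, visits) or generated synthetically, and writes
the run artifacts: per-subject fit reports, cohort parameter summaries,
actual-vs-estimated visit summaries, agreement reports, per-subject
trajectory CSVs and a machine-readable run manifest.  Same config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _version
from .agreement import AgreementResult, PairedSeries, evaluate_agreement
from .calibration import (
    FitConfig,
    FitResult,
    VisitMeasurement,
    cohort_summary,
    fit_subject,
    read_visits,
)
from .exceptions import ConfigError, DataFormatError, InsufficientDataError
from .model import predict_at_days, predict_performance
from .synthetic import CohortConfig, SyntheticSubject, generate_cohort
from .trimp import TrimpSeries, build_trimp_series, read_baselines, read_diary

logger = logging.getLogger("walkir")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "compare_subgroups",
    "load_reference_visit_summary",
    "visit_deltas",
]


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one data source (files xor synthetic)."""

    diary_path: str | None = None
    baseline_path: str | None = None
    visits_path: str | None = None
    synthetic: CohortConfig | None = None
    outcomes: tuple[str, ...] = ("pfwd", "6mwd")
    fit: FitConfig = field(default_factory=FitConfig)
    output_dir: str = "walkir_run"
    seed: int | None = None
    exclude_unacceptable_from_agreement: bool = False
    write_trajectories: bool = True

    def __post_init__(self) -> None:
        have_files = any([self.diary_path, self.baseline_path, self.visits_path])
        if have_files and self.synthetic is not None:
            raise ConfigError("choose files or a synthetic cohort, not both")
        if have_files and not all(
            [self.diary_path, self.baseline_path, self.visits_path]
        ):
            raise ConfigError("file input needs diary, baseline and visits paths")
        if not have_files and self.synthetic is None:
            raise ConfigError("no data source configured")
        if self.synthetic is not None and self.seed is None:
            raise ConfigError("a seed is required for synthetic runs")
        for outcome in self.outcomes:
            if outcome not in ("pfwd", "6mwd"):
                raise ConfigError(f"unknown outcome {outcome!r}")


@dataclass
class PipelineResult:
    """In-memory artifacts of one run."""

    fits: dict[str, dict[str, FitResult]]  # outcome -> subject_id -> fit
    agreement: dict[str, AgreementResult]  # outcome -> statistics
    summaries: dict[str, pd.DataFrame]  # outcome -> cohort parameter summary
    visit_table: pd.DataFrame  # actual vs estimated per visit label
    manifest: dict
    output_dir: Path


def _config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration (the output location is excluded
    so reruns into different directories share a manifest hash)."""
    payload = {
        k: repr(v)
        for k, v in dataclasses.asdict(config).items()
        if k != "output_dir"
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_subjects(
    config: RunConfig,
) -> tuple[dict[str, TrimpSeries], dict[str, list[VisitMeasurement]], dict[str, str]]:
    """Returns per-subject TRIMP series, visits and group (sex) labels."""
    if config.synthetic is not None:
        cohort_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        trimps = {s.subject_id: s.trimp_series() for s in cohort}
        visits = {s.subject_id: list(s.visits) for s in cohort}
        sexes = {s.subject_id: s.sex for s in cohort}
        return trimps, visits, sexes

    diaries = read_diary(config.diary_path)
    baselines = read_baselines(config.baseline_path)
    visits = read_visits(config.visits_path)
    trimps = {}
    for sid, sessions in diaries.items():
        if sid not in baselines:
            logger.warning("subject %s has a diary but no baseline; skipped", sid)
            continue
        trimps[sid] = build_trimp_series(sessions, baselines[sid])
    return trimps, visits, {}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run TRIMP quantification, calibration and agreement for a cohort.

    Subjects without a usable baseline visit are skipped with a warning.
    Raises :class:`InsufficientDataError` when no subject can be processed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    trimps, visits, sexes = _load_subjects(config)

    fits: dict[str, dict[str, FitResult]] = {o: {} for o in config.outcomes}
    predictions: list[dict] = []
    for sid in sorted(trimps):
        if sid not in visits:
            logger.warning("subject %s has no visits; skipped", sid)
            continue
        svisits = visits[sid]
        for outcome in config.outcomes:
            try:
                fit = fit_subject(trimps[sid], svisits, outcome, config.fit)
            except InsufficientDataError as exc:
                logger.warning("subject %s (%s): %s; skipped", sid, outcome, exc)
                continue
            fits[outcome][sid] = fit
            days = np.array([v.day_index for v in svisits if v.day_index > 0])
            labels = [v.visit_label for v in svisits if v.day_index > 0]
            pred = predict_at_days(fit.params, trimps[sid], days)
            for lab, day, p, v in zip(
                labels, days, pred, (v for v in svisits if v.day_index > 0)
            ):
                predictions.append(
                    {
                        "subject_id": sid,
                        "outcome": outcome,
                        "visit_label": lab,
                        "day_index": int(day),
                        "measured_m": v.value(outcome),
                        "estimated_m": float(p),
                        "acceptable": fit.acceptable,
                    }
                )
            if config.write_trajectories:
                traj_dir = outdir / "trajectories"
                traj_dir.mkdir(exist_ok=True)
                horizon = max(int(days.max()), len(trimps[sid]))
                traj = predict_performance(fit.params, trimps[sid], horizon)
                traj.to_frame(trimps[sid]).to_csv(
                    traj_dir / f"{sid}_{outcome}.csv", index=False
                )

    if not any(fits[o] for o in config.outcomes):
        raise InsufficientDataError("no subject could be fitted")

    pred_df = pd.DataFrame(predictions)
    pred_df.to_csv(outdir / "predictions.csv", index=False)

    agreement: dict[str, AgreementResult] = {}
    summaries: dict[str, pd.DataFrame] = {}
    visit_rows = []
    for outcome in config.outcomes:
        if not fits[outcome]:
            continue
        sub = pred_df[pred_df["outcome"] == outcome]
        if config.exclude_unacceptable_from_agreement:
            sub = sub[sub["acceptable"]]
        if len(sub) >= 3 and sub["measured_m"].nunique() > 1:
            sids = sorted(fits[outcome])
            t0 = {
                sid: next(v.value(outcome) for v in visits[sid] if v.day_index == 0)
                for sid in sids
            }
            last = {
                sid: max(visits[sid], key=lambda v: v.day_index).value(outcome)
                for sid in sids
            }
            pairs = PairedSeries(
                x=sub["measured_m"].to_numpy(),
                y=sub["estimated_m"].to_numpy(),
                labels=tuple(sub["subject_id"] + ":" + sub["visit_label"]),
            )
            agreement[outcome] = evaluate_agreement(
                pairs,
                pre=[t0[s] for s in sids],
                post=[last[s] for s in sids],
            )
        labels = sorted(fits[outcome])
        summaries[outcome] = cohort_summary(
            [fits[outcome][sid] for sid in labels],
            groups=[sexes.get(sid, "all") for sid in labels] if sexes else None,
        )
        summaries[outcome].to_csv(outdir / f"fit_summary_{outcome}.csv", index=False)
        fit_rows = [
            {
                "subject_id": sid,
                "p0": f.params.p0,
                "k1": f.params.k1,
                "k2": f.params.k2,
                "tau1": f.params.tau1,
                "tau2": f.params.tau2,
                "rss": f.rss,
                "r_squared": f.r_squared,
                "f_statistic": f.f_statistic,
                "f_pvalue": f.f_pvalue,
                "acceptable": f.acceptable,
                "n_obs": f.n_obs,
            }
            for sid, f in sorted(fits[outcome].items())
        ]
        pd.DataFrame(fit_rows).to_csv(outdir / f"fits_{outcome}.csv", index=False)

        # actual vs estimated summary per visit label (reference-table layout)
        for lab in sorted(sub["visit_label"].unique()):
            at = sub[sub["visit_label"] == lab]
            visit_rows.append(
                {
                    "outcome": outcome,
                    "visit": lab,
                    "n": len(at),
                    "actual_mean_m": at["measured_m"].mean(),
                    "actual_sd_m": at["measured_m"].std(ddof=1),
                    "estimated_mean_m": at["estimated_m"].mean(),
                    "estimated_sd_m": at["estimated_m"].std(ddof=1),
                }
            )

    visit_table = pd.DataFrame(visit_rows)
    visit_table.to_csv(outdir / "visit_summary.csv", index=False)
    agreement_dict = {o: a.to_dict() for o, a in agreement.items()}
    (outdir / "agreement.json").write_text(json.dumps(agreement_dict, indent=2))
    pd.DataFrame(
        [{"outcome": o, **d} for o, d in agreement_dict.items()]
    ).to_csv(outdir / "agreement.csv", index=False)

    manifest = {
        "walkir_version": _version,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_subjects": len(trimps),
        "n_fitted": {o: len(fits[o]) for o in config.outcomes},
        "outcomes": list(config.outcomes),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        fits=fits,
        agreement=agreement,
        summaries=summaries,
        visit_table=visit_table,
        manifest=manifest,
        output_dir=outdir,
    )


def compare_subgroups(fits_by_group: dict[str, list[FitResult]]) -> pd.DataFrame:
    """Per-parameter subgroup comparison (Welch two-sample t-tests).

    Requires at least two groups with >= 2 fits each; with more than two
    groups every pair is compared. Returns a tidy frame with group means,
    SDs and the Welch t and p per parameter and group pair.
    """
    groups = sorted(fits_by_group)
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups to compare")
    for g in groups:
        if len(fits_by_group[g]) < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 fits")
    params = ("p0", "k1", "k2", "tau1", "tau2", "r_squared")

    def values(g: str, p: str) -> np.ndarray:
        fits = fits_by_group[g]
        if p == "r_squared":
            return np.array([f.r_squared for f in fits])
        return np.array([getattr(f.params, p) for f in fits])

    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            for p in params:
                va, vb = values(ga, p), values(gb, p)
                if np.std(va, ddof=1) == 0 and np.std(vb, ddof=1) == 0:
                    t, pv = (0.0, 1.0) if va.mean() == vb.mean() else (np.inf, 0.0)
                else:
                    t, pv = stats.ttest_ind(va, vb, equal_var=False)
                rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "parameter": p,
                        "mean_a": va.mean(),
                        "sd_a": np.std(va, ddof=1),
                        "n_a": len(va),
                        "mean_b": vb.mean(),
                        "sd_b": np.std(vb, ddof=1),
                        "n_b": len(vb),
                        "t_statistic": float(t),
                        "p_value": float(pv),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published reference summary (cohort means at visits T0-T4)


def load_reference_visit_summary() -> pd.DataFrame:
    """Published cohort summary: actual and model-estimated PFWD/6MWD
    means +/- SD (m) at visits T0-T4 for the home-based walking program
    study cohort (n = 100)."""
    with resources.files("walkir.data").joinpath("cohort_visit_summary.csv").open() as fh:
        return pd.read_csv(fh)


def visit_deltas(
    summary: pd.DataFrame, series: str = "actual"
) -> dict[str, float]:
    """T4 - T0 change in mean performance (m) per outcome.

    ``series`` selects the actual or the model-estimated values; the
    estimated series has no T0 entry, in which case the actual T0 is the
    reference (the baseline is shared by construction).
    """
    out = {}
    for outcome, grp in summary.groupby("outcome"):
        sel = grp[grp["series"] == series].set_index("visit")["mean_m"]
        t0_src = sel if "T0" in sel.index else grp[
            grp["series"] == "actual"
        ].set_index("visit")["mean_m"]
        out[outcome] = float(sel["T4"] - t0_src["T0"])
    return out
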