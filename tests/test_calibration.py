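import datetime as dt

import numpy as np
import pytest
from scipy import stats

from walkir import (
    FitConfig,
    FitResult,
    InsufficientDataError,
    IRParameters,
    TrimpSeries,
    UndefinedStatisticError,
    UnidentifiableError,
    VisitMeasurement,
    cohort_summary,
    fit_subject,
    goodness_of_fit,
    predict_at_days,
    read_visits,
    write_visits,
)
from walkir.calibration import _profiled_rss

VISIT_DAYS = np.array([0, 35, 84, 140, 196])


def visits_from_values(days, values, offset=200.0):
    """Visit records carrying ``values`` in the PFWD slot (6MWD = PFWD + offset)."""
    return [
        VisitMeasurement(
            visit_label=f"T{i}",
            day_index=int(d),
            pfwd=float(v),
            six_mwd=float(v) + offset,
        )
        for i, (d, v) in enumerate(zip(days, values))
    ]


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 4.0, 8.0])
        r2, f, p = goodness_of_fit(y, y)
        assert r2 == 1.0 and np.isinf(f) and p == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        r2, _, _ = goodness_of_fit(np.full(4, y.mean()), y)
        assert r2 == pytest.approx(0.0)

    def test_four_point_hand_computation(self):
        # hand arithmetic: RSS = 1+4+1+4 = 10; TSS about mean 25 of
        # (10,20,30,40) = 225+25+25+225 = 500; R2 = 1 - 10/500 = 0.98
        measured = np.array([10.0, 20.0, 30.0, 40.0])
        predicted = np.array([11.0, 18.0, 31.0, 42.0])
        r2, f, p = goodness_of_fit(predicted, measured, df_model=2)
        assert r2 == pytest.approx(1 - 10 / 500)
        f_hand = ((500 - 10) / 2) / (10 / 1)  # df_resid = 4 - 3 = 1
        assert f == pytest.approx(f_hand)
        assert p == pytest.approx(float(stats.f.sf(f_hand, 2, 1)))

    def test_zero_total_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            goodness_of_fit(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))


class TestFitSubject:
    def test_noiseless_parameter_recovery(self, tito_trimps, published_mean_params_pfwd):
        true = published_mean_params_pfwd
        values = predict_at_days(true, tito_trimps, VISIT_DAYS)
        fit = fit_subject(tito_trimps, visits_from_values(VISIT_DAYS, values), "pfwd")
        assert fit.params.tau1 == pytest.approx(true.tau1, abs=2.0)
        assert fit.params.tau2 == pytest.approx(true.tau2, abs=2.0)
        assert fit.params.k1 == pytest.approx(true.k1, rel=0.05)
        assert fit.params.k2 == pytest.approx(true.k2, rel=0.05)
        recovered = predict_at_days(fit.params, tito_trimps, VISIT_DAYS)
        assert np.max(np.abs(recovered - values)) < 0.1

    def test_fitted_optimum_beats_every_grid_point(self, tito_trimps, rng):
        # optimizer sanity: RSS at the returned parameters <= grid RSS
        true = IRParameters(p0=114, k1=0.035, k2=0.02, tau1=50, tau2=20)
        values = predict_at_days(true, tito_trimps, VISIT_DAYS)
        values[1:] += rng.normal(0, 10, size=4)
        values = np.clip(values, 0, None)
        config = FitConfig()
        fit = fit_subject(
            tito_trimps, visits_from_values(VISIT_DAYS, values), "pfwd", config
        )
        w = tito_trimps.values
        resid = values[1:] - values[0]
        days = VISIT_DAYS[1:]
        for tau1 in np.arange(*config.tau1_bounds, config.grid_step):
            for tau2 in np.arange(*config.tau2_bounds, config.grid_step):
                grid_rss, _, _ = _profiled_rss(w, days, resid, tau1, tau2, config.k_max)
                assert fit.rss <= grid_rss + 1e-9

    def test_null_response_fits_with_zero_rss(self, tito_trimps):
        # constant measurements: the model explains them with k ~ 0
        values = np.full(5, 114.0)
        fit = fit_subject(tito_trimps, visits_from_values(VISIT_DAYS, values), "pfwd")
        assert fit.rss <= 1e-10
        assert np.isnan(fit.r_squared)  # zero TSS: R^2 undefined
        assert not fit.acceptable

    def test_acceptability_flag_follows_threshold(self, tito_trimps, rng):
        true = IRParameters(p0=114, k1=0.03, k2=0.03, tau1=45, tau2=25)
        values = predict_at_days(true, tito_trimps, VISIT_DAYS)
        fit = fit_subject(tito_trimps, visits_from_values(VISIT_DAYS, values), "pfwd")
        assert fit.acceptable == (fit.r_squared > 0.30)
        assert fit.acceptable

    def test_too_few_visits_rejected(self, tito_trimps):
        visits = visits_from_values([0, 35, 84], [114, 150, 180])
        with pytest.raises(InsufficientDataError):
            fit_subject(tito_trimps, visits, "pfwd")

    def test_missing_baseline_rejected(self, tito_trimps):
        # no day-0 record at all
        visits = [
            VisitMeasurement(
                visit_label=f"T{i + 1}", day_index=d, pfwd=v, six_mwd=v + 200
            )
            for i, (d, v) in enumerate(
                zip([35, 84, 140, 196], [150.0, 180.0, 200.0, 210.0])
            )
        ]
        with pytest.raises(InsufficientDataError):
            fit_subject(tito_trimps, visits, "pfwd")

    def test_all_zero_trimps_unidentifiable(self):
        trimps = TrimpSeries(start_date=dt.date(2018, 1, 1), values=np.zeros(200))
        visits = visits_from_values(VISIT_DAYS, [114, 150, 180, 200, 210])
        with pytest.raises(UnidentifiableError):
            fit_subject(trimps, visits, "pfwd")

    def test_deterministic_given_config(self, tito_trimps, rng):
        true = IRParameters(p0=114, k1=0.03, k2=0.03, tau1=45, tau2=25)
        values = predict_at_days(true, tito_trimps, VISIT_DAYS)
        values[1:] += rng.normal(0, 15, size=4)
        visits = visits_from_values(VISIT_DAYS, np.clip(values, 0, None))
        fit1 = fit_subject(tito_trimps, visits, "pfwd")
        fit2 = fit_subject(tito_trimps, visits, "pfwd")
        assert fit1 == fit2


class TestCohortSummary:
    def _fit(self, tau1=45.0, r2=0.8) -> FitResult:
        return FitResult(
            params=IRParameters(p0=114, k1=0.03, k2=0.03, tau1=tau1, tau2=25),
            rss=10.0,
            r_squared=r2,
            f_statistic=5.0,
            f_pvalue=0.05,
            acceptable=r2 > 0.30,
            n_obs=4,
        )

    def test_single_fit_mean_is_fit_sd_zero(self):
        table = cohort_summary([self._fit()])
        row = table[(table["group"] == "all") & (table["parameter"] == "tau1")]
        assert row["mean"].item() == 45.0 and row["sd"].item() == 0.0
        assert row["n_acceptable"].item() == 1

    def test_identical_subgroups_summarise_identically(self):
        fits = [self._fit(tau1=40), self._fit(tau1=50)] * 2
        groups = ["M", "M", "F", "F"]
        table = cohort_summary(fits, groups=groups)
        men = table[table["group"] == "M"].set_index("parameter")["mean"]
        women = table[table["group"] == "F"].set_index("parameter")["mean"]
        assert (men == women).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(InsufficientDataError):
            cohort_summary([])


def test_visits_csv_round_trip(tmp_path):
    visits = {
        "S1": visits_from_values(VISIT_DAYS, [114, 150, 180, 200, 210]),
        "S2": visits_from_values(VISIT_DAYS, [90, 120, 140, 150, 160]),
    }
    write_visits(visits, tmp_path / "visits.csv")
    assert read_visits(tmp_path / "visits.csv") == visits
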