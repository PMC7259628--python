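"""Segmented log-linear fitting: exactness, oracles, invariances, pooling."""

import math

import numpy as np
import pytest

from tumorkinetics.errors import (
    EmptyCohortError,
    IdentifiabilityError,
    ZeroSldError,
)
from tumorkinetics.segmented import (
    design_matrix,
    doubling_time,
    fit_cohort,
    fit_patient,
    halving_time,
)

from conftest import make_series, segmented_sld


def random_eligible_series(rng, n_pre=2, n_post=3, sigma=0.1, pid="P1"):
    t_pre = np.sort(rng.uniform(-12, -0.2, n_pre))
    t_post = np.sort(rng.uniform(0.3, 14, n_post))
    t = np.concatenate([t_pre, t_post])
    y0 = rng.lognormal(4.0, 0.4)
    rg, rs = rng.uniform(-0.5, 0.5, 2)
    sld = segmented_sld(t, y0, rg, rs) * np.exp(rng.normal(0, sigma, t.size))
    return make_series(list(zip(t, sld)), pid=pid), (y0, rg, rs)


def rss_of(series, y0, rg, rs):
    logy = np.log(series.slds())
    X = design_matrix(series.times())
    return float(np.sum((logy - X @ [math.log(y0), rg, rs]) ** 2))


class TestFitPatient:
    def test_flat_series_gives_zero_rates(self, flat_series):
        fit = fit_patient(flat_series)
        assert fit.rg_hat == pytest.approx(0, abs=1e-12)
        assert fit.rs_hat == pytest.approx(0, abs=1e-12)
        assert fit.y0_hat == pytest.approx(100.0)
        assert fit.d_hat == pytest.approx(0, abs=1e-12)
        assert fit.saturated and fit.sigma_hat == 0.0

    def test_three_points_interpolated_exactly(self):
        y0, rg, rs = 50.0, 0.1, 0.095
        t = [-2.0, -0.5, 2.0]
        series = make_series([(ti, float(segmented_sld(ti, y0, rg, rs))) for ti in t])
        fit = fit_patient(series)
        assert fit.y0_hat == pytest.approx(y0, rel=1e-9)
        assert fit.rg_hat == pytest.approx(rg, rel=1e-9)
        assert fit.rs_hat == pytest.approx(rs, rel=1e-9)
        assert fit.saturated and math.isnan(fit.se_rg)

    def test_d_hat_is_exact_difference(self, rng):
        series, _ = random_eligible_series(rng)
        fit = fit_patient(series)
        assert fit.d_hat == fit.rs_hat - fit.rg_hat

    def test_beats_dense_grid_oracle(self, rng):
        """OLS solution is the least-squares minimizer: no grid point does better."""
        for _ in range(20):
            series, _ = random_eligible_series(
                rng, n_pre=rng.integers(2, 4), n_post=rng.integers(1, 5)
            )
            fit = fit_patient(series)
            best = rss_of(series, fit.y0_hat, fit.rg_hat, fit.rs_hat)
            for ly0 in np.linspace(math.log(fit.y0_hat) - 0.4, math.log(fit.y0_hat) + 0.4, 21):
                grid_rg = fit.rg_hat + np.linspace(-0.3, 0.3, 21)
                grid_rs = fit.rs_hat + np.linspace(-0.3, 0.3, 21)
                for rg in grid_rg:
                    for rs in grid_rs:
                        assert best <= rss_of(series, math.exp(ly0), rg, rs) + 1e-9

    def test_multiplicative_scale_invariance(self, rng):
        series, _ = random_eligible_series(rng)
        c = 3.7
        scaled = make_series([(s.t, s.sld * c) for s in series.scans])
        f1, f2 = fit_patient(series), fit_patient(scaled)
        assert f2.y0_hat == pytest.approx(f1.y0_hat * c, rel=1e-9)
        assert f2.rg_hat == pytest.approx(f1.rg_hat, abs=1e-12)
        assert f2.rs_hat == pytest.approx(f1.rs_hat, abs=1e-12)

    def test_time_unit_equivariance(self, rng):
        """Refitting with t in weeks rescales rates by months-per-week exactly."""
        series, _ = random_eligible_series(rng)
        k = 52.1786 / 12  # weeks per month
        weekly = make_series([(s.t * k, s.sld) for s in series.scans])
        f_m, f_w = fit_patient(series), fit_patient(weekly)
        assert f_w.rg_hat == pytest.approx(f_m.rg_hat / k, rel=1e-9)
        assert f_w.rs_hat == pytest.approx(f_m.rs_hat / k, rel=1e-9)
        assert f_w.y0_hat == pytest.approx(f_m.y0_hat, rel=1e-9)

    def test_matches_statsmodels_ols(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        series, _ = random_eligible_series(rng, n_pre=3, n_post=4)
        fit = fit_patient(series)
        X = design_matrix(series.times())
        res = sm.OLS(np.log(series.slds()), X).fit()
        assert fit.rg_hat == pytest.approx(res.params[1], rel=1e-10)
        assert fit.rs_hat == pytest.approx(res.params[2], rel=1e-10)
        assert fit.se_rg == pytest.approx(res.bse[1], rel=1e-8)
        assert fit.se_rs == pytest.approx(res.bse[2], rel=1e-8)
        assert fit.sigma_hat == pytest.approx(np.sqrt(res.mse_resid), rel=1e-10)

    def test_zero_sld_replaced_by_default_and_error_on_request(self):
        series = make_series([(-2, 50), (-0.4, 30), (1.4, 0.0)])
        fit = fit_patient(series)  # 0 -> 2.5 mm before log
        expected = fit_patient(make_series([(-2, 50), (-0.4, 30), (1.4, 2.5)]))
        assert fit.rs_hat == pytest.approx(expected.rs_hat)
        with pytest.raises(ZeroSldError):
            fit_patient(series, zero_sld="error")

    def test_ineligible_series_rejected(self):
        with pytest.raises(ValueError, match="not eligible"):
            fit_patient(make_series([(-0.4, 50), (1.4, 60)]))

    def test_rank_deficient_design_rejected(self):
        # Both pre-treatment scans essentially at t = 0 leave r_g free: the
        # pre-treatment column of the design is (numerically) null.
        series = make_series([(-1e-18, 50.0), (0.0, 50.0), (1.4, 55.0)])
        with pytest.raises(IdentifiabilityError):
            fit_patient(series)


class TestFitCohort:
    def test_pooled_sigma_not_estimable_for_saturated_cohort(self):
        cohort = [
            make_series([(-2, 50), (-0.4, 52), (1.4, 55)], pid=f"P{i}")
            for i in range(3)
        ]
        result = fit_cohort(cohort)
        assert result.pooled_sigma is None

    def test_single_patient_pooled_equals_own_sigma(self, rng):
        series, _ = random_eligible_series(rng, n_pre=2, n_post=3)
        result = fit_cohort([series])
        assert result.pooled_sigma == pytest.approx(result.fits[0].sigma_hat)

    def test_pooled_sigma_combines_rss_over_dof(self, rng):
        cohort = [
            random_eligible_series(rng, n_pre=3, n_post=4, pid=f"P{i}")[0]
            for i in range(5)
        ]
        result = fit_cohort(cohort)
        rss = sum(f.rss for f in result.fits)
        dof = sum(f.dof for f in result.fits)
        assert result.pooled_sigma == pytest.approx(math.sqrt(rss / dof))

    def test_failures_reported_not_fatal(self, rng):
        good, _ = random_eligible_series(rng, pid="good")
        bad = make_series([(-1e-18, 50.0), (0.0, 50.0), (1.4, 55.0)], pid="bad")
        result = fit_cohort([good, bad])
        assert [f.patient_id for f in result.fits] == ["good"]
        assert result.failures[0][0] == "bad"

    def test_empty_cohort_raises(self):
        with pytest.raises(EmptyCohortError):
            fit_cohort([])


class TestDoublingHalving:
    def test_identity_rate_doubles_in_one_month(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_zero_rate_is_undefined_not_exception(self):
        assert math.isnan(doubling_time(0.0))
        assert math.isnan(halving_time(0.0))

    def test_shrinking_tumor_has_halving_not_doubling_time(self):
        r = -math.log(2)
        assert math.isnan(doubling_time(r))
        assert halving_time(r) == pytest.approx(1.0)
        assert halving_time(-0.1) > 0

    def test_slow_growth_cross_check(self):
        # ln(2)/0.05134 month^-1: a ~13.5-month doubling time
        assert doubling_time(0.05134) == pytest.approx(13.50, abs=0.01)
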