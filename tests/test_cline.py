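"""Broken-stick, horizontal and logistic cline fits and the clinality LRT."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, chi2

from clinescan.cline import (
    BrokenStickCline,
    BrokenStickParams,
    ClineFit,
    ClineFitError,
    HorizontalCline,
    LogisticCline,
    broken_stick_predict,
    fit_broken_stick,
    fit_horizontal,
    lrt_clinal,
)


PARAMS = BrokenStickParams(38.0, 0.1, 42.0, 0.9)


class TestBrokenStickModel:
    def test_linear_segment_midpoint(self):
        assert broken_stick_predict(PARAMS, 40.0) == pytest.approx(0.5)

    def test_southern_plateau(self):
        assert broken_stick_predict(PARAMS, 30.0) == pytest.approx(0.1)
        assert broken_stick_predict(PARAMS, 50.0) == pytest.approx(0.9)

    def test_derived_midpoint_and_slope(self):
        assert PARAMS.midpoint == pytest.approx(40.0)
        assert PARAMS.slope == pytest.approx(0.2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BrokenStickParams(42.0, 0.1, 38.0, 0.9)
        with pytest.raises(ValueError):
            BrokenStickParams(38.0, -0.1, 42.0, 0.9)


class TestHorizontalFit:
    def test_pooled_frequency(self):
        fit = fit_horizontal([35.0, 40.0], [8, 2], [10, 10])
        assert fit.params[0] == pytest.approx(0.5)

    def test_loglik_is_sum_of_binomial_logpmf(self):
        lats = [33.0, 37.0, 41.0]
        x, n = [3, 7, 5], [10, 12, 11]
        fit = fit_horizontal(lats, x, n)
        p = sum(x) / sum(n)
        oracle = sum(binom.logpmf(xi, ni, p) for xi, ni in zip(x, n))
        assert fit.loglik == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_fixed_sites(self):
        fit = fit_horizontal([35.0, 40.0], [10, 10], [10, 10])
        assert fit.params[0] in (0.0, 1.0)
        assert abs(fit.loglik) < 0.01  # clamped at the boundary


class TestBrokenStickFit:
    def test_parameter_recovery_noise_free(self):
        lats = np.linspace(31, 47, 20)
        n = np.full(20, 10_000.0)
        x = np.round(broken_stick_predict(PARAMS, lats) * n)
        fit = fit_broken_stick(lats, x, n)
        p = fit.params
        assert p.lat_south_break == pytest.approx(38.0, abs=0.1)
        assert p.lat_north_break == pytest.approx(42.0, abs=0.1)
        assert p.p_south == pytest.approx(0.1, abs=0.01)
        assert p.p_north == pytest.approx(0.9, abs=0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nesting_over_horizontal(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 15))
        lats = np.sort(rng.uniform(30, 45, m))
        n = np.full(m, 30.0)
        x = rng.binomial(30, rng.uniform(0.05, 0.95), m).astype(float)
        for objective in ("binomial", "gaussian"):
            bs = fit_broken_stick(lats, x, n, objective=objective)
            h = fit_horizontal(lats, x, n, objective=objective)
            assert bs.loglik >= h.loglik - 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_reflection_symmetry_exact(self, seed):
        rng = np.random.default_rng(seed)
        lats = np.sort(rng.uniform(30, 45, 12))
        n = np.full(12, 40.0)
        x = rng.binomial(40, np.clip(0.1 + 0.05 * (lats - 30), 0, 1)).astype(float)
        a = BrokenStickCline().fit(lats, x, n)
        b = BrokenStickCline().fit(lats, n - x, n)
        assert a.loglik_ == b.loglik_
        assert a.midpoint_ == b.midpoint_
        assert a.slope_ == -b.slope_
        ha = HorizontalCline().fit(lats, x, n)
        hb = HorizontalCline().fit(lats, n - x, n)
        assert lrt_clinal(a.fit_, ha.fit_) == lrt_clinal(b.fit_, hb.fit_)

    def test_median_recovery_on_synthetic_clines(self, recovery_fits):
        ds, truth, fits = recovery_fits
        mid_err = np.abs([f.midpoint_ for f in fits] - truth["midpoint"].to_numpy())
        slope_rel_err = np.abs(
            (np.abs([f.slope_ for f in fits]) - np.abs(truth["slope_true"]))
            / truth["slope_true"].to_numpy()
        )
        assert np.median(mid_err) < 0.5
        assert np.median(slope_rel_err) < 0.2

    def test_truth_fit_midpoint_correlation(self, recovery_fits):
        ds, truth, fits = recovery_fits
        r = np.corrcoef([f.midpoint_ for f in fits], truth["midpoint"])[0, 1]
        assert r > 0.95

    def test_too_few_sites_rejected(self):
        with pytest.raises(ClineFitError):
            fit_broken_stick([30, 35, 40, 45], [1, 2, 3, 4], [10, 10, 10, 10])

    def test_too_few_distinct_latitudes_rejected(self):
        lats = [30.0, 30.0, 40.0, 40.0, 40.0]
        with pytest.raises(ClineFitError):
            fit_broken_stick(lats, [1, 2, 3, 4, 5], [10] * 5)

    def test_step_like_cline_flagged(self):
        # sites straddle the jump at nearly identical latitudes, so the
        # optimal break separation collapses onto the 0.01-degree floor
        lats = np.array([30, 33, 36, 39, 39.999, 40.001, 41, 42, 43, 44, 45.0])
        n = np.full(len(lats), 200.0)
        x = np.where(lats < 40, 2.0, 198.0)
        fit = fit_broken_stick(lats, x, n)
        assert "step_like" in fit.flags


class TestClinalityLrt:
    def test_equal_fits_give_unit_p(self):
        h = ClineFit("horizontal", (0.5,), -10.0, n_sites=10)
        b = ClineFit("broken_stick", None, -10.0, n_sites=10)
        stat, df, p = lrt_clinal(b, h)
        assert stat == 0.0 and df == 3 and p == 1.0

    def test_chi_square_critical_value(self):
        h = ClineFit("horizontal", (0.5,), 0.0, n_sites=10)
        b = ClineFit("broken_stick", None, 7.815 / 2, n_sites=10)
        _, _, p = lrt_clinal(b, h)
        assert p == pytest.approx(chi2.sf(7.815, 3), abs=1e-12)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_strong_cline_decisive(self):
        rng = np.random.default_rng(0)
        lats = np.linspace(30, 45, 20)
        p_true = broken_stick_predict(BrokenStickParams(38.0, 0.1, 42.0, 0.9), lats)
        x = rng.binomial(40, p_true).astype(float)
        n = np.full(20, 40.0)
        bs = fit_broken_stick(lats, x, n)
        h = fit_horizontal(lats, x, n)
        _, _, p = lrt_clinal(bs, h)
        assert p < 1e-6

    def test_inconsistent_loglik_raises(self):
        h = ClineFit("horizontal", (0.5,), -5.0, n_sites=10)
        b = ClineFit("broken_stick", None, -6.0, n_sites=10)
        with pytest.raises(ClineFitError):
            lrt_clinal(b, h)

    def test_mixed_objectives_rejected(self):
        h = ClineFit("horizontal", (0.5,), -5.0, objective="binomial", n_sites=10)
        b = ClineFit("broken_stick", None, -4.0, objective="gaussian", n_sites=10)
        with pytest.raises(ValueError):
            lrt_clinal(b, h)

    def test_type_one_error_on_flat_loci(self):
        # boundary non-regularity makes the nominal chi-square(3) reference
        # approximate; the rejection rate should stay near alpha
        rng = np.random.default_rng(42)
        lats = np.linspace(30, 45, 20)
        n = np.full(20, 40.0)
        rejections = 0
        n_rep = 150
        for _ in range(n_rep):
            p0 = rng.uniform(0.2, 0.8)
            x = rng.binomial(40, p0, 20).astype(float)
            bs = fit_broken_stick(lats, x, n)
            h = fit_horizontal(lats, x, n)
            _, _, p = lrt_clinal(bs, h)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.12


class TestLogisticFit:
    def test_agrees_with_broken_stick_on_steep_cline(self):
        rng = np.random.default_rng(9)
        lats = np.linspace(30, 45, 25)
        p_true = 0.05 + 0.9 / (1 + np.exp(-3 * (lats - 40.0)))
        x = rng.binomial(60, p_true).astype(float)
        n = np.full(25, 60.0)
        lg = LogisticCline().fit(lats, x, n)
        bs = BrokenStickCline().fit(lats, x, n)
        assert lg.converged_
        assert lg.midpoint_ == pytest.approx(bs.midpoint_, abs=0.5)

    def test_flat_data_flagged_not_raised(self):
        rng = np.random.default_rng(10)
        lats = np.linspace(30, 45, 15)
        x = rng.binomial(40, 0.5, 15).astype(float)
        lg = LogisticCline().fit(lats, x, np.full(15, 40.0))
        assert not lg.converged_ or "boundary" in lg.flags_ or lg.loglik_ > -1e9

    def test_nests_horizontal(self):
        rng = np.random.default_rng(11)
        lats = np.linspace(30, 45, 12)
        x = rng.binomial(40, 0.4, 12).astype(float)
        n = np.full(12, 40.0)
        lg = LogisticCline().fit(lats, x, n)
        h = HorizontalCline().fit(lats, x, n)
        assert lg.loglik_ >= h.loglik_ - 1e-9


class TestSklearnInterface:
    def test_get_set_params_roundtrip(self):
        est = BrokenStickCline(objective="gaussian", n_quantiles=7)
        params = est.get_params()
        est2 = BrokenStickCline().set_params(**params)
        assert est2.get_params() == params

    def test_predict_matches_model(self):
        lats = np.linspace(31, 47, 20)
        n = np.full(20, 1000.0)
        x = np.round(broken_stick_predict(PARAMS, lats) * n)
        est = BrokenStickCline().fit(lats, x, n)
        np.testing.assert_allclose(
            est.predict(lats), broken_stick_predict(est.params_, lats)
        )
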