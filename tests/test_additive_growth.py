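import numpy as np
import pytest

import fermcurve as fc
from fermcurve.curve_models import FitError
from fermcurve.screen_data import ScreenDataError

# truths whose branches have saturated by the tipping point, the regime in
# which the plateau construction is exact
GROWTH = fc.CurveParams(1e9, 1e8, 8)
DECLINE = fc.CurveParams(1e9, 5e7, 60)
TX = 48.0


class TestTippingPoint:
    def test_unique_maximum(self, series_factory):
        s = series_factory([0, 10, 20, 30], [0, 5, 9, 7])
        assert fc.find_tipping_point(s) == (20, 9)

    def test_monotone_series_peaks_at_last_time(self, series_factory):
        s = series_factory([0, 10, 20, 30], [1, 2, 3, 4])
        assert fc.find_tipping_point(s) == (30, 4)

    def test_tie_broken_to_earliest(self, series_factory):
        s = series_factory([0, 10, 20], [1, 3, 3])
        assert fc.find_tipping_point(s) == (10, 3)

    def test_empty_series_rejected(self, series_factory):
        with pytest.raises(ScreenDataError, match="empty"):
            fc.find_tipping_point(series_factory([], []))


class TestPlateauAndMirror:
    def test_plateau_substitutes_after_tx(self, series_factory):
        s = series_factory([0, 10, 20], [0, 9, 4])
        out = fc.plateau_after(s, 10)
        np.testing.assert_array_equal(out.values, [0, 9, 9])
        np.testing.assert_array_equal(out.times, s.times)

    def test_plateau_at_last_time_is_identity(self, series_factory):
        s = series_factory([0, 10, 20], [0, 5, 9])
        out = fc.plateau_after(s, 20)
        np.testing.assert_array_equal(out.values, s.values)

    def test_plateau_idempotent(self, series_factory):
        s = series_factory([0, 10, 20, 30], [0, 9, 4, 2])
        once = fc.plateau_after(s, 10)
        twice = fc.plateau_after(once, 10)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_mirror_reflects_and_pads(self, series_factory):
        s = series_factory([0, 100, 205], [8, 8, 0])
        out = fc.mirror_decline(s, 0, 205)
        np.testing.assert_array_equal(out.times, [0, 105, 205])
        np.testing.assert_array_equal(out.values, [0, 8, 8])

    def test_mirror_involution_on_times(self, series_factory):
        s = series_factory([0, 30, 100, 205], [2, 9, 5, 1])
        once = fc.mirror_decline(s, 30, 205)
        twice = fc.mirror_decline(once, 205 - 30, 205)
        np.testing.assert_array_equal(twice.times, s.times)

    def test_flat_series_stays_flat(self, series_factory):
        s = series_factory([0, 50, 205], [3, 3, 3])
        out = fc.mirror_decline(s, 50, 205)
        np.testing.assert_array_equal(out.values, [3, 3, 3])

    def test_tx_must_be_sampled(self, series_factory):
        s = series_factory([0, 10, 20], [1, 2, 3])
        with pytest.raises(ScreenDataError, match="not a sampled time"):
            fc.plateau_after(s, 15)
        with pytest.raises(ScreenDataError, match="not a sampled time"):
            fc.mirror_decline(s, 15, 205)


@pytest.fixture(scope="module")
def noiseless_fit():
    s = fc.simulate_growth_curve(GROWTH, DECLINE, tx=TX)
    return fc.fit_additive(s)


class TestAdditiveFit:
    def test_seven_parameters_recovered(self, noiseless_fit):
        p = noiseless_fit.named_params()
        assert len(p) == 7
        assert p["tx"] == TX
        for name, true in [("MaxCFU", GROWTH.A), ("GroRate", GROWTH.mu),
                           ("Lag", GROWTH.lam), ("DeclineMaxCFU", DECLINE.A),
                           ("DeclineRate", DECLINE.mu),
                           ("DeclineLag", DECLINE.lam)]:
            assert p[name] == pytest.approx(true, rel=1e-4), name

    def test_branch_model_identities_recovered(self):
        s = fc.simulate_growth_curve(
            GROWTH, fc.CurveParams(1e9, 5e7, 40), tx=55.0,
            growth_model="gompertz", decline_model="gompertz")
        fit = fc.fit_additive(s)
        assert fit.growth.model == "gompertz"
        assert fit.decline.model == "gompertz"

    def test_noisy_growth_params_within_15_percent(self):
        s = fc.simulate_growth_curve(GROWTH, DECLINE, tx=TX,
                                     noise_sd=0.02, seed=5)
        fit = fc.fit_additive(s)
        assert fit.growth.params.A == pytest.approx(GROWTH.A, rel=0.15)
        assert fit.growth.params.mu == pytest.approx(GROWTH.mu, rel=0.15)

    def test_monotone_series_decline_not_estimable(self, schedule):
        s = fc.simulate_metabolite_curve(fc.CurveParams(1e9, 5e7, 30),
                                         "logistic", schedule,
                                         candidate_id="c", analyte="cfu")
        fit = fc.fit_additive(s)
        assert fit.growth is not None
        assert fit.decline is None
        assert "decline-not-estimable" in fit.flags

    def test_bounded_by_max_capacity(self, noiseless_fit):
        t = np.linspace(0, 205, 500)
        y = fc.evaluate_additive(noiseless_fit, t)
        cap = max(noiseless_fit.growth.params.A,
                  noiseless_fit.decline.params.A)
        assert np.all(y <= cap * (1 + 1e-9))


class TestEvaluateAdditive:
    @pytest.fixture
    def fit(self, noiseless_fit):
        return noiseless_fit

    def test_prelag_near_zero(self, fit):
        # growth branch well before its lag: < 1% of capacity
        assert fc.evaluate_additive(fit, 0.0) < 0.01 * GROWTH.A

    def test_fully_declined_at_end(self, fit):
        # decline branch at mirrored time 0, well before its lag
        assert fc.evaluate_additive(fit, 205.0) < 1e-3 * DECLINE.A

    def test_piecewise_branches(self, fit):
        t_lo, t_hi = TX - 1e-6, TX + 1e-6
        g = fc.logistic_value(fit.growth.params, t_lo)
        d = fc.logistic_value(fit.decline.params, 205 - t_hi)
        assert fc.evaluate_additive(fit, t_lo) == pytest.approx(g, rel=1e-12)
        assert fc.evaluate_additive(fit, t_hi) == pytest.approx(d, rel=1e-12)

    def test_mean_exactly_at_tx(self, fit):
        g = fc.logistic_value(fit.growth.params, TX)
        d = fc.logistic_value(fit.decline.params, 205 - TX)
        assert fc.evaluate_additive(fit, TX) == \
            pytest.approx(0.5 * (g + d), rel=1e-12)

    def test_requires_both_branches(self, schedule):
        s = fc.simulate_metabolite_curve(fc.CurveParams(1e9, 5e7, 30),
                                         "logistic", schedule,
                                         candidate_id="c", analyte="cfu")
        fit = fc.fit_additive(s)
        with pytest.raises(FitError):
            fc.evaluate_additive(fit, 10.0)


class TestSustainability:
    def _fit_with_decline_lag(self, lam):
        s = fc.simulate_growth_curve(GROWTH,
                                     fc.CurveParams(1e9, 5e7, lam), tx=TX)
        return fc.fit_additive(s)

    def test_positive_decline_lag(self):
        fit = self._fit_with_decline_lag(55.0)
        assert fc.sustainability(fit) == pytest.approx(150.0, abs=1e-2)

    def test_negative_decline_lag_flagged_beyond_window(self):
        fit = self._fit_with_decline_lag(-5.0)
        with pytest.warns(UserWarning, match="not fully declined"):
            value = fc.sustainability(fit)
        assert value == pytest.approx(210.0, abs=0.5)
        assert value > fit.t_end
        assert "not fully declined within observation window" in fit.flags

    def test_missing_decline_branch_rejected(self, schedule):
        s = fc.simulate_metabolite_curve(fc.CurveParams(1e9, 5e7, 30),
                                         "logistic", schedule,
                                         candidate_id="c", analyte="cfu")
        fit = fc.fit_additive(s)
        with pytest.raises(FitError, match="decline branch"):
            fc.sustainability(fit)
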