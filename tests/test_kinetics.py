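"""LED death-kinetics fits, protein decay, Hill/sigmoid fits, onset coupling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from pdarkit.kinetics import (
    LEDFit,
    fit_exp2_decay,
    fit_hill4_eu,
    fit_led,
    fit_led_table,
    fit_sigmoid4,
    led_auc,
    led_eval,
    lf50_from_led,
    onset_coupling,
)


class TestLedEval:
    def test_onset_value_and_asymptote(self):
        assert led_eval(10.0, 0.02, 0.82, 0.1, 10.0) == pytest.approx(0.02)
        assert led_eval(1e6, 0.02, 0.82, 0.1, 10.0) == pytest.approx(0.82)

    def test_half_rise_point(self):
        t = 10 + math.log(2) / 0.1
        assert led_eval(t, 0.02, 0.82, 0.1, 10.0) == pytest.approx(0.42)

    def test_constant_at_baseline_before_onset(self):
        t = np.linspace(0, 10, 50)
        np.testing.assert_allclose(led_eval(t, 0.05, 0.9, 0.2, 10.0), 0.05)

    @settings(max_examples=100, deadline=None)
    @given(
        lf0=st.floats(0, 0.3),
        rise=st.floats(0, 0.7),
        dr=st.floats(0.01, 5),
        do=st.floats(0, 48),
    )
    def test_monotone_nondecreasing_and_continuous(self, lf0, rise, dr, do):
        t = np.linspace(0, 96, 400)
        y = led_eval(t, lf0, lf0 + rise, dr, do)
        assert np.all(np.diff(y) >= -1e-12)
        # continuity at onset
        assert abs(led_eval(do - 1e-9, lf0, lf0 + rise, dr, do)
                   - led_eval(do + 1e-9, lf0, lf0 + rise, dr, do)) < 1e-6


class TestFitLed:
    t = np.arange(0.0, 73.0, 2.0)

    def test_noiseless_round_trip(self):
        lf = led_eval(self.t, 0.02, 0.8, 0.1, 12.0)
        fit = fit_led(self.t, lf)
        assert fit.converged
        for got, want in zip((fit.lf0, fit.lfp, fit.dr, fit.do), (0.02, 0.8, 0.1, 12.0)):
            assert got == pytest.approx(want, abs=1e-6)

    def test_flat_series_yields_flat_fit(self):
        fit = fit_led(self.t, np.full_like(self.t, 0.03))
        assert fit.converged
        assert fit.lf0 == pytest.approx(0.03, abs=1e-3)
        assert fit.lfp == pytest.approx(0.03, abs=1e-3)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.default_rng(42)
        truth = (0.02, 0.8, 0.1, 12.0)
        lf = np.clip(led_eval(self.t, *truth) + rng.normal(0, 0.01, len(self.t)), 0, 1)
        fit = fit_led(self.t, lf)
        assert fit.lfp == pytest.approx(truth[1], rel=0.05)
        assert fit.dr == pytest.approx(truth[2], rel=0.05)
        assert fit.do == pytest.approx(truth[3], rel=0.05)

    def test_parameter_order_invariant(self):
        """Converged fits respect 0 <= LF0 <= LFP <= 1, DR > 0, DO >= 0."""
        rng = np.random.default_rng(3)
        lf = np.clip(led_eval(self.t, 0.05, 0.6, 0.3, 30.0)
                     + rng.normal(0, 0.02, len(self.t)), 0, 1)
        fit = fit_led(self.t, lf)
        assert 0 <= fit.lf0 <= fit.lfp <= 1
        assert fit.dr > 0 and fit.do >= 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_led([0, 1, 2, 3, 4], [0, 0, 0, 0, 0])


class TestLf50:
    def test_step_limit_equals_onset(self):
        fit = LEDFit(lf0=0.0, lfp=0.8, dr=1e4, do=10.0)
        assert lf50_from_led(fit) == pytest.approx(10.0, abs=1e-3)

    def test_closed_form_half_rise(self):
        fit = LEDFit(lf0=0.0, lfp=0.8, dr=0.1, do=10.0)
        # at a long horizon the max is ~LFP and LF50 ~ DO + ln2/DR
        got = lf50_from_led(fit, horizon=2000.0)
        assert got == pytest.approx(10 + math.log(2) / 0.1, abs=0.01)

    def test_flat_fit_is_missing(self):
        fit = LEDFit(lf0=0.05, lfp=0.05, dr=0.1, do=10.0)
        assert np.isnan(lf50_from_led(fit))

    def test_lf50_not_before_onset_when_baseline_low(self):
        fit = LEDFit(lf0=0.01, lfp=0.9, dr=0.2, do=15.0)
        assert lf50_from_led(fit) >= fit.do


class TestLedAuc:
    def test_flat_rectangle(self):
        fit = LEDFit(lf0=0.5, lfp=0.5, dr=0.1, do=0.0)
        assert led_auc(fit, 10.0) == pytest.approx(5.0)

    def test_step_limit(self):
        fit = LEDFit(lf0=0.0, lfp=1.0, dr=1e8, do=10.0)
        assert led_auc(fit, 20.0) == pytest.approx(10.0, abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(
        lf0=st.floats(0, 0.3),
        rise=st.floats(0, 0.7),
        dr=st.floats(0.01, 5),
        do=st.floats(0, 60),
        T=st.floats(1, 96),
    )
    def test_analytic_matches_quadrature(self, lf0, rise, dr, do, T):
        fit = LEDFit(lf0=lf0, lfp=lf0 + rise, dr=dr, do=do)
        numeric = quad(lambda x: led_eval(x, fit.lf0, fit.lfp, fit.dr, fit.do),
                       0, T, points=[min(do, T)], limit=200)[0]
        assert led_auc(fit, T) == pytest.approx(numeric, abs=1e-6)


class TestExp2Decay:
    t = np.arange(0.0, 49.0, 2.0)

    def test_single_exponential_half_life(self):
        lam = math.log(2) / 10.0
        fit = fit_exp2_decay(self.t, np.exp(-lam * self.t))
        assert fit.t_half == pytest.approx(10.0, abs=1e-3)

    def test_constant_signal_never_decays(self):
        fit = fit_exp2_decay(self.t, np.ones_like(self.t))
        assert np.isinf(fit.t_half)

    def test_symmetric_split_equals_single_exponential(self):
        lam = math.log(2) / 8.0
        y = 0.5 * np.exp(-lam * self.t) + 0.5 * np.exp(-lam * self.t)
        fit = fit_exp2_decay(self.t, y)
        assert fit.t_half == pytest.approx(8.0, abs=1e-3)

    def test_rates_are_nonpositive(self):
        rng = np.random.default_rng(5)
        y = np.exp(-0.1 * self.t) * rng.lognormal(0, 0.02, len(self.t))
        fit = fit_exp2_decay(self.t, y / y.max())
        assert fit.b <= 0 and fit.d <= 0

    def test_half_life_beyond_window_is_extrapolated(self):
        lam = math.log(2) / 100.0  # half-life 100 h, window 48 h
        fit = fit_exp2_decay(self.t, np.exp(-lam * self.t))
        assert fit.t_half == pytest.approx(100.0, rel=0.05)


class TestHill4:
    t = np.arange(0.0, 25.0, 1.0)

    def _logistic(self, mid, slope=4.0, floor=0.0, ceil=1.0):
        frac = np.where(self.t > 0, 1 / (1 + (mid / np.maximum(self.t, 1e-9)) ** slope), 0.0)
        return floor + (ceil - floor) * frac

    def test_symmetric_round_trip(self):
        fit = fit_hill4_eu(self.t, self._logistic(8.0))
        assert fit.midpoint == pytest.approx(8.0, abs=1e-3)
        assert fit.t_half_eu == pytest.approx(8.0, abs=1e-3)

    def test_low_ceiling_never_crosses_half(self):
        fit = fit_hill4_eu(self.t, self._logistic(8.0, ceil=0.4))
        assert np.isnan(fit.t_half_eu)

    def test_floor_not_above_ceiling(self):
        rng = np.random.default_rng(11)
        y = np.clip(self._logistic(6.0) + rng.normal(0, 0.03, len(self.t)), 0, 1)
        fit = fit_hill4_eu(self.t, y)
        assert fit.floor <= fit.ceiling


class TestSigmoid4:
    doses = np.geomspace(1e-3, 100, 9)

    def _curve(self, bottom=0.0, top=1.0, ec50=1.0, slope=1.0):
        x = np.log10(self.doses)
        return bottom + (top - bottom) / (1 + 10 ** (slope * (np.log10(ec50) - x)))

    def test_noiseless_round_trip(self):
        fit = fit_sigmoid4(self.doses, self._curve())
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(1.0, abs=1e-6)
        assert fit.ec50 == pytest.approx(1.0, abs=1e-6)
        assert fit.hill_slope == pytest.approx(1.0, abs=1e-6)

    def test_midpoint_identity(self):
        fit = fit_sigmoid4(self.doses, self._curve(bottom=0.1, top=0.9, ec50=3.0))
        assert fit(fit.ec50) == pytest.approx((fit.top + fit.bottom) / 2, abs=1e-9)

    def test_flat_response_flagged(self):
        fit = fit_sigmoid4(self.doses, np.full_like(self.doses, 0.5))
        assert not fit.converged


class TestOnsetCoupling:
    def test_exact_shifted_identity(self):
        x = np.array([2.0, 5.0, 10.0, 20.0])
        res = onset_coupling(x, x + 11.0)
        assert res.slope == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)
        assert res.lag_constant == pytest.approx(11.0)

    def test_permuted_pairs_decorrelate(self):
        rng = np.random.default_rng(99)
        x = np.linspace(2, 30, 40)
        y = rng.permutation(x + 11.0)
        res = onset_coupling(x, y)
        assert abs(res.r) < 0.35

    def test_duplicate_abscissa_does_not_crash(self):
        res = onset_coupling([5.0, 5.0, 9.0], [10.0, 12.0, 20.0])
        assert np.isfinite(res.slope)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            onset_coupling([1.0, 2.0], [2.0, 3.0])


def test_fit_led_table_one_row_per_condition(panel_config):
    from pdarkit.simulate import simulate_panel

    df = simulate_panel(panel_config, genotypes=("WT",))
    fits = fit_led_table(df)
    assert len(fits) == df["condition_id"].nunique()
    assert fits["converged"].all()
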