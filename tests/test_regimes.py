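import math

import numpy as np
import pytest
from scipy.optimize import brentq

from pulsedhill import (
    HillParameters,
    SquareWaveSignal,
    classify_regime,
    delay_boundary,
    delay_factor,
    fast_boundary_KA,
    graded_boundary_KA,
    graded_clocking,
    integrate_numeric,
    mean_pulsed_binding,
    regime_boundaries_vs_KA,
    rise_time_pulsed,
    rise_time_sustained,
    sustained_binding,
)


def _params(n, k1, K_A):
    return HillParameters.from_dissociation_constant(n, k1, K_A)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "k2, expected",
        [(10.0, "slow_d"), (0.001, "fast_f"), (0.238, "competitive_e")],
    )
    def test_labels_from_x(self, k2, expected):
        p = HillParameters(2, 0.01, k2)
        sig = SquareWaveSignal(10.0, 6.0, 0.3)
        assert classify_regime(p, sig).regime == expected

    def test_sustained_is_distinct_status(self, default_params):
        rep = classify_regime(default_params, SquareWaveSignal(10.0, 6.0, 1.0))
        assert rep.regime == "sustained"
        assert math.isnan(rep.x)
        assert rep.fast_boundary_K_A is None

    def test_rescaling_invariance(self, default_params, default_signal):
        """Jointly scaling the rates and inverting the period preserves
        the (dimensionless) regime label."""
        rep = classify_regime(default_params, default_signal)
        for c in (0.01, 100.0):
            scaled = HillParameters(
                default_params.n, c * default_params.k1, c * default_params.k2
            )
            sig = SquareWaveSignal(
                default_signal.amplitude,
                default_signal.period / c,
                default_signal.duty_cycle,
            )
            assert classify_regime(scaled, sig).regime == rep.regime

    def test_graded_implies_fast(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            p = _params(2, 10 ** rng.uniform(-4, -2), 10 ** rng.uniform(0, 1.8))
            sig = SquareWaveSignal(
                10 ** rng.uniform(0.7, 1.9), 10 ** rng.uniform(-2.5, 1), rng.uniform(0.05, 0.95)
            )
            rep = classify_regime(p, sig)
            if rep.graded_g:
                assert rep.regime == "fast_f"

    def test_threshold_must_exceed_one(self, default_params, default_signal):
        with pytest.raises(ValueError):
            classify_regime(default_params, default_signal, threshold=1.0)


class TestRiseTimes:
    def test_sustained_direct_value(self):
        p = _params(2, 0.01, 32.0)
        assert rise_time_sustained(p, 40.0) == pytest.approx(0.0381, abs=2e-4)

    def test_sustained_zero_amplitude(self, default_params):
        assert rise_time_sustained(default_params, 0.0) == pytest.approx(
            1 / default_params.k2
        )

    def test_sustained_numeric_crossing(self, default_params):
        """Time for the sustained trajectory to reach (1 - 1/e) of its
        asymptote equals the closed-form rise time."""
        sig = SquareWaveSignal(10.0, 6.0, 1.0)
        tau = rise_time_sustained(default_params, 10.0)
        traj = integrate_numeric(default_params, sig, 5 * tau, dt_out=tau / 400)
        target = (1 - 1 / math.e) * sustained_binding(default_params, 10.0)
        crossing = traj.times[np.searchsorted(traj.probabilities, target)]
        assert crossing == pytest.approx(tau, rel=0.01)

    def test_pulsed_reduces_to_sustained_at_gamma_one(self, default_params):
        sig = SquareWaveSignal(10.0, 6.0, 1.0)
        assert rise_time_pulsed(default_params, sig).time == pytest.approx(
            rise_time_sustained(default_params, 10.0)
        )

    def test_pulsed_direct_value(self):
        p = _params(2, 0.01, 8.0)
        sig = SquareWaveSignal(40.0, 0.1, 0.3)
        res = rise_time_pulsed(p, sig)
        assert res.time == pytest.approx(0.1488, abs=2e-4)
        assert res.valid

    def test_pulsed_negative_outside_validity(self):
        p = _params(2, 0.01, 1.0)
        sig = SquareWaveSignal(40.0, 10.0, 0.1)
        res = rise_time_pulsed(p, sig)
        assert res.time < 0
        assert not res.valid

    def test_pulsed_numeric_crossing_in_fast_regime(self):
        """(1 - 1/e) rise of the pulse-averaged trajectory matches the
        fast-pulsing formula when x << 1 and delay holds."""
        p = _params(2, 0.01, 8.0)
        sig = SquareWaveSignal(40.0, 0.01, 0.3)
        assert p.k2 * 0.7 * 0.01 < 0.01
        res = rise_time_pulsed(p, sig)
        traj = integrate_numeric(p, sig, 60 * sig.period, dt_out=sig.period / 40)
        # period-averaged trajectory
        n_per = int(round(traj.times[-1] / sig.period))
        means, centers = [], []
        for i in range(n_per):
            m = (traj.times >= i * sig.period) & (traj.times <= (i + 1) * sig.period)
            means.append(np.trapezoid(traj.probabilities[m], traj.times[m]) / sig.period)
            centers.append((i + 0.5) * sig.period)
        means, centers = np.asarray(means), np.asarray(centers)
        target = (1 - 1 / math.e) * mean_pulsed_binding(p, sig)
        crossing = np.interp(target, means, centers)
        assert crossing == pytest.approx(res.time, rel=0.10)


class TestDelayBoundary:
    def test_no_boundary_when_braced_nonpositive(self):
        # k1 T A^n gamma >= 2 leaves no real K_A: binding is never delayed
        p = _params(2, 0.01, 8.0)
        sig = SquareWaveSignal(40.0, 6.0, 0.3)
        assert 0.01 * 6.0 * 1600 * 0.3 >= 2
        assert delay_boundary(p, sig) is None

    def test_boundary_equals_rise_time_root(self):
        """The closed form is the K_A at which tau_pulsed = tau_sus."""
        sig = SquareWaveSignal(40.0, 0.1, 0.3)
        b = delay_boundary(_params(2, 0.01, 8.0), sig)

        def gap(K):
            p = _params(2, 0.01, K)
            return rise_time_pulsed(p, sig).time - rise_time_sustained(p, 40.0)

        root = brentq(gap, 1.0, 1e3, rtol=1e-14)
        assert b == pytest.approx(root, rel=1e-6)
        # below the boundary pulsing delays binding, above it does not
        assert gap(0.5 * b) > 0 > gap(2 * b)

    def test_monotone_decreasing_in_duty_cycle(self):
        p = _params(2, 0.01, 8.0)
        bounds = [
            delay_boundary(p, SquareWaveSignal(40.0, 0.0625, g)) for g in (0.1, 0.3, 0.8)
        ]
        assert all(b is not None for b in bounds)
        assert bounds[0] > bounds[1] > bounds[2]


class TestDelayFactor:
    def test_sustained_is_unity(self, default_params):
        assert delay_factor(default_params, SquareWaveSignal(10.0, 6.0, 1.0)) == 1.0

    def test_small_duty_cycle_limit(self):
        p = _params(2, 0.01, 10.0)
        sig = SquareWaveSignal(10.0, 6.0, 1e-9)
        assert delay_factor(p, sig) == pytest.approx(2.0, rel=1e-6)

    def test_direct_value(self):
        # (A^n + K_A^n) / (A^n gamma + K_A^n) = (1600 + 64) / (480 + 64)
        p = _params(2, 0.01, 8.0)
        sig = SquareWaveSignal(40.0, 6.0, 0.3)
        assert delay_factor(p, sig) == pytest.approx(1664 / 544, rel=1e-12)


class TestGradedClocking:
    def _graded_setup(self):
        return _params(2, 0.01, 1.0), SquareWaveSignal(40.0, 0.01, 0.1)

    def test_satisfied_and_linear(self):
        p, sig = self._graded_setup()
        res = graded_clocking(p, sig, i_max=50)
        assert res.satisfied
        assert res.linear_window >= 3
        assert res.linearity_error <= 0.10

    def test_per_pulse_increments_nearly_constant(self):
        p, sig = self._graded_setup()
        res = graded_clocking(p, sig, i_max=50)
        inc = np.diff(res.per_pulse_levels[: res.linear_window])
        assert np.all(inc > 0)
        assert np.max(np.abs(inc / inc[0] - 1)) <= 0.10

    def test_first_pulse_small_relative_to_mean(self):
        p, sig = self._graded_setup()
        res = graded_clocking(p, sig, i_max=10)
        assert res.per_pulse_levels[0] / mean_pulsed_binding(p, sig) <= 0.2

    def test_slow_pulsing_not_satisfied(self):
        p = _params(2, 0.01, 32.0)
        sig = SquareWaveSignal(10.0, 6.0, 0.3)
        assert not graded_clocking(p, sig).satisfied

    def test_requires_enough_pulses(self, default_params, default_signal):
        with pytest.raises(ValueError):
            graded_clocking(default_params, default_signal, i_max=2)


class TestAsymptoticTrackingInvariants:
    def test_slow_regime_tracks_signal(self):
        """Deep in regime d the cycle saturates each pulse and empties
        each gap."""
        from pulsedhill import asymptotic_cycle

        g, T = 0.3, 6.0
        k2 = 100.0 / ((1 - g) * T)
        p = HillParameters(2, k2 / 8.0**2, k2)
        sig = SquareWaveSignal(16.0, T, g)
        cyc = asymptotic_cycle(p, sig, 1000)
        p_sus = sustained_binding(p, 16.0)
        on_end = cyc.probabilities[cyc.times < sig.pulse_on][-1]
        off_end = cyc.probabilities[-1]
        assert on_end >= 0.95 * p_sus
        assert off_end <= 0.05 * p_sus

    def test_fast_regime_small_ripple(self):
        from pulsedhill import asymptotic_cycle

        g, T = 0.3, 6.0
        k2 = 0.01 / ((1 - g) * T)
        p = HillParameters(2, k2 / 8.0**2, k2)
        sig = SquareWaveSignal(16.0, T, g)
        cyc = asymptotic_cycle(p, sig, 1000)
        ripple = (cyc.probabilities.max() - cyc.probabilities.min()) / cyc.probabilities.mean()
        assert ripple <= 0.05


class TestBoundariesTable:
    def test_fast_boundary_closed_form(self):
        assert fast_boundary_KA(2, 0.01, 0.3, 6.0) == pytest.approx(4.88, abs=0.01)

    def test_boundary_ordering(self):
        """Graded clocking is a stricter condition than fast pulsing."""
        rng = np.random.default_rng(37)
        for _ in range(200):
            n = rng.choice([2, 4])
            k1 = 10 ** rng.uniform(-4, -2)
            A = 10 ** rng.uniform(0.7, 1.9)
            g = rng.uniform(0.05, 0.95)
            T = 10 ** rng.uniform(-2.5, 1)
            fast = fast_boundary_KA(n, k1, g, T)
            graded = graded_boundary_KA(n, k1, A, g, T)
            if graded is not None:
                assert graded <= fast

    def test_sustained_has_no_boundaries(self):
        df, bounds = regime_boundaries_vs_KA(
            2, 0.01, 40.0, 1.0, 6.0, np.logspace(0, np.log10(64), 16)
        )
        assert all(v is None for v in bounds.values())
        assert set(df["regime"]) == {"sustained"}

    def test_table_membership_consistent_with_boundaries(self):
        grid = np.logspace(0, np.log10(64), 64)
        df, bounds = regime_boundaries_vs_KA(2, 0.01, 40.0, 0.3, 6.0, grid)
        assert bounds["fast"] == pytest.approx(4.88, abs=0.01)
        # below the fast boundary / threshold the label is fast_f
        fast_rows = df[df["K_A_nM"] <= bounds["fast"] / 10 ** (1 / 2)]
        assert set(fast_rows["regime"]) <= {"fast_f"}
        slow_rows = df[df["K_A_nM"] >= bounds["fast"] * 10 ** (1 / 2) * 1.01]
        assert set(slow_rows["regime"]) <= {"slow_d"}
        assert df["is_fast_boundary"].sum() == 1
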