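"""Unit and property tests for the fuel-driven reaction-cycle ODE system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropcycle import (
    CycleState,
    ExperimentConfig,
    RateConstants,
    TimeCourse,
    depletion_time,
    integrate,
    peak_anhydride,
    threshold_times,
)
from dropcycle.reaction_cycle import CONSERVATION_RTOL, derivatives

conc = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)
rate = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)


def euler_oracle(config, k, t_end, n_out=10, dt=1e-3):
    """Fixed-step explicit Euler integration, independent of the solver path."""
    y = np.array([config.F0, config.P0, 0.0, 0.0, 0.0])
    t_out = np.linspace(0, t_end, n_out + 1)[1:]
    out, next_i = [], 0
    n_steps = int(round(t_end / dt))
    for i in range(1, n_steps + 1):
        F, P, I, A, W = y
        act = k.k1 * F * P
        y = y + dt * np.array(
            [
                -k.k0 * F - act,
                -act + k.k3 * I + k.k4 * A,
                act - (k.k2 + k.k3) * I,
                k.k2 * I - k.k4 * A,
                k.k0 * F + (k.k2 + k.k3) * I,
            ]
        )
        while next_i < len(t_out) and i * dt >= t_out[next_i] - dt / 2:
            out.append(y.copy())
            next_i += 1
    return t_out, np.array(out).T


def assert_close_01pct(y, y_ref):
    """Agreement within 0.1%, floored at 0.1% of each species' range so that
    values decayed through many decades are judged on the species scale."""
    scale = np.max(np.abs(y_ref), axis=1, keepdims=True)
    tol = np.maximum(1e-3 * np.abs(y_ref), 1e-3 * scale)
    assert np.all(np.abs(y - y_ref) <= tol)


def make_course(t, A, A_total=25.0, F=None, provenance=None):
    """Hand-built TimeCourse with consistent conservation bookkeeping."""
    t = np.asarray(t, float)
    A = np.asarray(A, float)
    F = np.zeros_like(t) if F is None else np.asarray(F, float)
    P = A_total - A
    I = np.zeros_like(t)
    W = F[0] - F  # keeps F + I + W constant
    return TimeCourse(t, np.vstack([F, P, I, A, W]), provenance or {})


class TestDerivatives:
    def test_all_zero_state(self):
        k = RateConstants(0.1, 0.01, 0.5, 0.3, 0.1)
        assert np.all(derivatives(CycleState(0, 0, 0, 0, 0, 0), k) == 0)

    def test_pure_deactivation_limb(self):
        """Only anhydride present: hydrolysis back to precursor at k4*A."""
        k = RateConstants(0.3, 0.02, 1.0, 2.0, 0.1)
        d = derivatives(CycleState(t=0, F=0, P=0, I=0, A=2.0, W=0), k)
        assert d == pytest.approx([0.0, 0.2, 0.0, -0.2, 0.0])

    def test_hand_evaluated_rate_laws(self):
        # independent hand evaluation: act = 0.002*10*20 = 0.4
        k = RateConstants(0.01, 0.002, 0.5, 0.2, 0.1)
        d = derivatives(CycleState(t=0, F=10, P=20, I=1, A=0.5, W=0), k)
        assert d == pytest.approx([-0.5, -0.15, -0.3, 0.45, 0.8])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            CycleState(t=0, F=-1, P=0, I=0, A=0, W=0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(F=conc, P=conc, I=conc, A=conc, k=st.tuples(rate, rate, rate, rate, rate))
    def test_conservation_of_derivative_sums(self, F, P, I, A, k):
        """Peptide (dP+dI+dA) and carbodiimide (dF+dI+dW) sums vanish."""
        d = derivatives(CycleState(t=0, F=F, P=P, I=I, A=A, W=0), RateConstants(*k))
        scale = max(np.max(np.abs(d)), 1.0)
        assert abs(d[1] + d[2] + d[3]) <= 1e-12 * scale
        assert abs(d[0] + d[2] + d[4]) <= 1e-12 * scale


class TestIntegrate:
    def test_no_fuel_is_inert(self, k_default):
        tc = integrate(ExperimentConfig(F0=0.0), k_default, 10.0)
        assert np.all(tc.A == 0)
        assert np.all(tc.P == pytest.approx(23.0))

    @pytest.mark.parametrize("F0", [7.5, 25.0, 60.0])
    def test_conservation_invariants(self, F0, k_default):
        tc = integrate(ExperimentConfig(F0=F0), k_default, 60.0)
        assert np.max(np.abs(tc.P + tc.I + tc.A - 23.0)) / 23.0 < CONSERVATION_RTOL
        assert np.max(np.abs(tc.F + tc.I + tc.W - F0)) / F0 < CONSERVATION_RTOL

    def test_euler_oracle_agreement(self):
        """Adaptive solution matches fixed-step Euler (dt=1e-3 min) to 0.1%
        on a 10-point grid over random parameter draws."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            # rates O(1)/min keep the first-order oracle's own truncation
            # error well below the 0.1% comparison band at dt = 1e-3
            k = RateConstants(*rng.uniform([0.01, 0.001, 0.1, 0.1, 0.02], [0.3, 0.02, 0.8, 0.8, 0.3]))
            cfg = ExperimentConfig(F0=rng.uniform(5, 60))
            t_end = 10.0
            t_out, y_ref = euler_oracle(cfg, k, t_end)
            tc = integrate(cfg, k, t_end, output_step=1.0)
            y = np.vstack([tc.F, tc.P, tc.I, tc.A, tc.W])[:, 1:]
            assert_close_01pct(y, y_ref)

    def test_closed_form_limit_no_activation(self, k_default):
        """With k1 = 0 fuel decays as exp(-k0 t) and no anhydride ever forms."""
        k = k_default.replace(k1=0.0)
        tc = integrate(ExperimentConfig(F0=25.0), k, 20.0)
        assert np.max(np.abs(tc.A)) < 1e-9
        expected = 25.0 * np.exp(-k.k0 * tc.t)
        assert np.allclose(tc.F, expected, rtol=1e-6, atol=1e-9)

    def test_monotone_fuel_and_waste(self, tc25):
        assert np.all(np.diff(tc25.F) <= 1e-9)
        assert np.all(np.diff(tc25.W) >= -1e-9)

    def test_peak_monotone_in_fuel(self, k_default):
        peaks = [
            peak_anhydride(integrate(ExperimentConfig(F0=f), k_default, 30.0))[1]
            for f in (5.0, 10.0, 20.0, 40.0)
        ]
        assert np.all(np.diff(peaks) > 0)

    def test_invalid_inputs(self, k_default):
        with pytest.raises(ValueError):
            integrate(ExperimentConfig(F0=25.0), k_default, t_end=-1.0)
        with pytest.raises(ValueError):
            RateConstants(-0.1, 0.01, 0.5, 0.3, 0.1)


class TestObservables:
    def test_flat_zero_trace_peak(self):
        tc = make_course([0, 1, 2], [0, 0, 0])
        assert peak_anhydride(tc) == (0.0, 0.0)

    def test_closed_form_pulse_peak(self):
        """Two-exponential pulse: dense-scan oracle locates the maximum."""
        a, b, beta = 0.08, 0.9, 5.0
        pulse = lambda t: beta * (np.exp(-a * t) - np.exp(-b * t))
        t_dense = np.linspace(0, 60, 600001)
        i = np.argmax(pulse(t_dense))
        t_grid = np.arange(0, 60.001, 0.01)
        t_peak, A_peak = peak_anhydride(make_course(t_grid, pulse(t_grid)))
        assert t_peak == pytest.approx(t_dense[i], abs=0.01)
        assert A_peak == pytest.approx(pulse(t_dense[i]), rel=1e-4)

    def test_threshold_never_exceeded(self):
        tc = make_course([0, 1, 2], [0.1, 0.2, 0.1])
        assert threshold_times(tc, 0.9) == (None, None)

    def test_triangular_trace_interpolated_crossings(self):
        """Piecewise-linear rise/fall: crossings computed in closed form."""
        t = np.arange(0, 20.5, 0.5)
        A = np.where(t <= 10, 0.2 * t, 2.0 - 0.2 * (t - 10))
        t_on, t_off = threshold_times(make_course(t, A), 0.9)
        assert t_on == pytest.approx(4.5, abs=1e-9)
        assert t_off == pytest.approx(15.5, abs=1e-9)

    def test_depletion_no_fuel(self, k_default):
        tc = integrate(ExperimentConfig(F0=0.0), k_default, 5.0)
        assert depletion_time(tc, 0.1) == 0.0

    def test_depletion_closed_form_exponential(self):
        """Monotone exponential fuel decay: crossing at ln(C0/limit)/rate."""
        r, C0, limit = 0.3, 20.0, 0.1
        t = np.arange(0, 40.05, 0.05)
        tc = make_course(t, np.zeros_like(t), F=C0 * np.exp(-r * t))
        expected = np.log(C0 / limit) / r
        assert depletion_time(tc, limit) == pytest.approx(expected, abs=0.05)

    def test_depletion_unreached_flagged(self):
        t = np.arange(0, 5.5, 0.5)
        tc = make_course(t, np.zeros_like(t), F=np.full_like(t, 5.0))
        assert depletion_time(tc, 0.1) is None


class TestTimeCourse:
    def test_csv_round_trip(self, tc25, tmp_path):
        path = tmp_path / "tc.csv"
        tc25.to_csv(path)
        back = TimeCourse.from_csv(path)
        assert np.allclose(back.A, tc25.A, rtol=1e-8)
        assert back.provenance["rate_constants"] == tc25.provenance["rate_constants"]

    def test_rejects_nonmonotone_times(self):
        with pytest.raises(ValueError):
            make_course([0, 1, 1], [0, 0, 0])

    def test_rejects_conservation_violation(self):
        t = np.array([0.0, 1.0])
        y = np.vstack([[10, 10], [23, 20], [0, 0], [0, 0], [0, 0]])  # peptide lost
        from dropcycle.reaction_cycle import IntegrationError

        with pytest.raises(IntegrationError):
            TimeCourse(t, y)

    def test_state_interpolation(self, tc25):
        st1 = tc25.state_at(2.0)
        assert st1.t == 2.0
        assert st1.A == pytest.approx(float(np.interp(2.0, tc25.t, tc25.A)))
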