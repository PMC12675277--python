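"""Closed-form accumulation model against trivial identities and the RK4 oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckflux import (
    DivergenceError,
    KineticParams,
    ValidationError,
    eval_accumulation,
    eval_accumulation_with_treatment,
    integrate_accumulation_rk4,
    steady_state,
    visualization_curve,
)
from conftest import random_param_sets

C0, F = 2.0, 0.05


class TestEvalAccumulation:
    def test_t_zero_gives_adsorption_offset(self):
        p = KineticParams(I=0.01, E=0.003, K=0.12)
        assert eval_accumulation(0.0, p, C0, F) == pytest.approx(0.12 * C0)

    def test_no_influx_no_adsorption_is_zero(self):
        p = KineticParams(I=0.0, E=0.005, K=0.0)
        assert np.all(eval_accumulation([0.0, 100.0, 900.0], p, C0, F) == 0.0)

    def test_matches_rk4_oracle_at_reference_point(self):
        """I=0.01, E=0.005, K=0, f=0.05, c0=2, t=300 s -> ~2.938 nM."""
        p = KineticParams(I=0.01, E=0.005, K=0.0)
        oracle = integrate_accumulation_rk4([300.0], p, C0, F, dt=0.01)[0]
        value = eval_accumulation(300.0, p, C0, F)
        assert value == pytest.approx(oracle, abs=1e-8 * C0)
        assert value == pytest.approx(2.938, abs=1e-3)

    def test_degenerate_rate_limit(self):
        """f*I + E = 0 with I = E = 0: linear-growth limit I*c0*t (here 0) + K*c0."""
        p = KineticParams(I=0.0, E=0.0, K=0.05)
        out = eval_accumulation([0.0, 500.0], p, C0, F)
        assert np.allclose(out, 0.05 * C0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t": -1.0, "c0": C0, "f": F},
            {"t": 10.0, "c0": 0.0, "f": F},
            {"t": 10.0, "c0": C0, "f": -0.1},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        p = KineticParams(I=0.01, E=0.005, K=0.0)
        with pytest.raises(ValidationError):
            eval_accumulation(kwargs["t"], p, kwargs["c0"], kwargs["f"])

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            KineticParams(I=-0.01, E=0.005, K=0.0)

    def test_fk_above_one_rejected(self):
        p = KineticParams(I=0.01, E=0.005, K=25.0)
        with pytest.raises(ValidationError):
            eval_accumulation(10.0, p, C0, 0.05)


class TestOracleEquivalence:
    def test_closed_form_matches_rk4_over_random_parameters(self):
        """Analytic solution vs mass-balance ODE integration, 25 random draws."""
        I, E, K, f = random_param_sets(25, seed=42)
        t_grid = np.linspace(0.0, 900.0, 7)
        for i in range(25):
            p = KineticParams(I=I[i], E=E[i], K=K[i])
            closed = eval_accumulation(t_grid, p, C0, f[i])
            oracle = integrate_accumulation_rk4(t_grid, p, C0, f[i], dt=0.01)
            assert np.max(np.abs(closed - oracle)) < 1e-8 * C0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        I=st.floats(1e-4, 1e-1),
        E=st.floats(1e-4, 1e-1),
        K=st.floats(0.0, 0.3),
        f=st.floats(1e-3, 0.2),
    )
    def test_monotone_in_time_and_linear_in_c0(self, I, E, K, f):
        p = KineticParams(I=I, E=E, K=K)
        t = np.linspace(0.0, 1800.0, 50)
        c = eval_accumulation(t, p, C0, f)
        assert np.all(np.diff(c) >= -1e-12)
        alpha = 3.7
        scaled = eval_accumulation(t, p, alpha * C0, f)
        assert np.allclose(scaled, alpha * c, rtol=1e-12)


class TestTreatmentModel:
    P = KineticParams(I=0.02, E=0.004, K=0.02, I_prime=0.002)

    def test_identical_influx_degenerates_to_plain_model(self):
        p = KineticParams(I=0.02, E=0.004, K=0.02, I_prime=0.02)
        t = np.linspace(0.0, 900.0, 31)
        treated = eval_accumulation_with_treatment(t, p, 420.0, C0, F)
        plain = eval_accumulation(t, p, C0, F)
        assert np.allclose(treated, plain, rtol=1e-12)

    def test_continuity_at_treatment_time(self):
        tp = 420.0
        at_tp = eval_accumulation_with_treatment(tp, self.P, tp, C0, F)
        just_after = eval_accumulation_with_treatment(np.nextafter(tp, 1e9), self.P, tp, C0, F)
        assert at_tp == pytest.approx(eval_accumulation(tp, self.P, C0, F), rel=1e-12)
        assert just_after == pytest.approx(at_tp, rel=1e-9)

    def test_matches_piecewise_rk4_oracle(self):
        t = np.array([60.0, 300.0, 420.0, 600.0, 900.0])
        closed = eval_accumulation_with_treatment(t, self.P, 420.0, C0, F)
        oracle = integrate_accumulation_rk4(t, self.P, C0, F, t_prime=420.0, dt=0.01)
        assert np.max(np.abs(closed - oracle)) < 1e-8 * C0

    def test_converges_to_post_treatment_steady_state(self):
        late = eval_accumulation_with_treatment(1e7, self.P, 420.0, C0, F)
        post = KineticParams(I=self.P.I_prime, E=self.P.E, K=self.P.K)
        assert late == pytest.approx(steady_state(post, C0, F), rel=1e-9)

    def test_missing_I_prime_is_configuration_error(self):
        from ckflux import ConfigurationError

        with pytest.raises(ConfigurationError):
            eval_accumulation_with_treatment(100.0, KineticParams(0.01, 0.005), 50.0, C0, F)


class TestSteadyState:
    def test_adsorption_only_plateau(self):
        assert steady_state(KineticParams(I=0.0, E=0.004, K=0.05), C0, F) == pytest.approx(0.1)

    def test_equilibrative_limit(self):
        p = KineticParams(I=0.01, E=0.01, K=0.0)
        assert steady_state(p, C0, 1e-9) == pytest.approx(C0, rel=1e-6)

    def test_matches_long_time_evaluation(self):
        p = KineticParams(I=0.01, E=0.005, K=0.0)
        ss = steady_state(p, C0, F)
        assert ss == pytest.approx(3.636, abs=1e-3)
        assert ss == pytest.approx(eval_accumulation(1e6, p, C0, F), rel=1e-10)

    def test_unbounded_accumulation_raises(self):
        with pytest.raises(DivergenceError):
            steady_state(KineticParams(I=0.01, E=0.0, K=0.0), C0, 0.0)


class TestVisualizationCurve:
    def test_adsorption_factor_ignored(self):
        t = np.linspace(0.0, 900.0, 10)
        with_K = visualization_curve(KineticParams(0.01, 0.005, K=0.3), F, t)
        without_K = visualization_curve(KineticParams(0.01, 0.005, K=0.0), F, t)
        assert np.array_equal(with_K, without_K)

    def test_zero_grid(self):
        assert visualization_curve(KineticParams(0.01, 0.005, K=0.2), F, [0.0]) == [0.0]
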