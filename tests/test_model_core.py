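"""Core model: auxiliary functions, QSS reductions, and the full right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftdyn import ModelParameters, ParameterError, full_rhs, graft_function, hill, percent, suppress
from graftdyn.model import STATE_VARS, baseline_state, qss_ir, qss_t0


class TestHill:
    @pytest.mark.parametrize(
        "x, x_half, expected",
        [(0.0, 0.06, 0.0), (0.06, 0.06, 0.5), (0.12, 0.06, 64.0 / 65.0)],
    )
    def test_values(self, x, x_half, expected):
        assert hill(x, x_half) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, 100), st.floats(1e-3, 10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_saturating(self, x, x_half):
        v = hill(x, x_half)
        assert 0.0 <= v <= 1.0
        assert hill(x + 1.0, x_half) >= v  # increasing (up to float saturation)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill(-0.1, 0.06)
        with pytest.raises(ValueError):
            hill(0.1, 0.0)


class TestSuppress:
    @pytest.mark.parametrize(
        "x, y, scale, expected",
        [(1.0, 0.0, 0.28, 1.0), (1.0, 0.28, 0.28, 0.5),
         (2.0, 0.125, 0.28, 2.0 / (1.0 + (0.125 / 0.28) ** 2))],
    )
    def test_values(self, x, y, scale, expected):
        assert suppress(x, y, scale) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_never_amplifies(self, x, y):
        assert suppress(x, y, 0.28) <= x + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            suppress(-1.0, 0.0, 0.28)
        with pytest.raises(ValueError):
            suppress(1.0, -1.0, 0.28)


class TestGraftFunction:
    def test_undamaged_graft_is_full_function(self, params):
        assert graft_function(0.0, params) == 1.0

    @pytest.mark.parametrize("d_g, pct", [(1.9, 20.0), (1.8, 24.0)])
    def test_printed_damage_function_pairs(self, params, d_g, pct):
        # pins the e^(-D_G/x_gdg) exponent convention of the curve
        assert percent(graft_function(d_g, params)) == pct

    def test_monotone_decreasing_to_zero(self, params):
        d = np.linspace(0, 8, 500)
        g = graft_function(d, params)
        assert np.all(np.diff(g) < 0)
        assert graft_function(30.0, params) < 1e-10


class TestQuasiSteadyState:
    def test_resting_innate_baseline(self, params):
        assert qss_ir(baseline_state(params), params) == pytest.approx(2.0 / 3.0)

    def test_resting_innate_depleted_by_activation(self, params):
        lo = qss_ir(np.array([0, 1.0, 0, 0.125, 0, 0]), params)
        assert lo < qss_ir(baseline_state(params), params)
        assert qss_ir(np.array([0, 1e9, 0, 0.125, 0, 0]), params) < 1e-6

    def test_t0_baseline(self, params):
        assert qss_t0(baseline_state(params), params) == pytest.approx(20.0)

    def test_t0_independent_of_ta_without_innate_drive(self, params):
        # with I = 0 and alpha = 0 the (1 + T_A) factors cancel exactly
        for t_a in (0.0, 0.5, 7.0):
            state = np.array([0, 1.0, 0.3, 0.6, 0.2, t_a])
            assert qss_t0(state, params) == pytest.approx(20.0)

    def test_t0_decreasing_in_innate(self, params):
        states = [np.array([i, 0, 0, 0.125, 0, 0]) for i in (0.0, 0.5, 1.0)]
        vals = [qss_t0(s, params) for s in states]
        assert vals[0] > vals[1] > vals[2]


class TestFullRhs:
    def test_baseline_is_exact_equilibrium(self, params):
        assert np.all(full_rhs(0.0, baseline_state(params), params) == 0.0)

    def test_pure_repair_when_innate_quiet(self, params):
        rates = full_rhs(0.0, np.array([0, 3.0, 0, 0.125, 0, 0]), params)
        assert rates[1] == pytest.approx(-0.06)  # mu_d * D, no damage production

    def test_innate_gain_is_saturating(self, params, rng):
        for _ in range(50):
            y = rng.uniform(0, 3, size=6)
            di = full_rhs(0.0, y, params)[0]
            assert di < params.s_ir - params.mu_i * y[0]

    def test_nonnegative_orthant_forward_invariant(self, params, rng):
        for _ in range(50):
            y = rng.uniform(0, 3, size=6)
            for k in range(6):
                z = y.copy()
                z[k] = 0.0
                assert full_rhs(0.0, z, params)[k] >= 0.0

    def test_anti_inflammatory_level_weakly_reduces_inflammation(self, params, rng):
        for _ in range(25):
            y = rng.uniform(0, 3, size=6)
            lo, hi = y.copy(), y.copy()
            lo[3], hi[3] = 0.1, 1.0
            r_lo, r_hi = full_rhs(0.0, lo, params), full_rhs(0.0, hi, params)
            for k in (0, 1, 2):  # dI, dD, dD_G
                assert r_hi[k] <= r_lo[k] + 1e-12

    def test_syngeneic_graft_ignores_allo_rates(self, params, rng):
        bumped = params.replace(k_tpig=0.9, k_tpt0g=0.9, k_tat0g=0.9, k_dgtp=9.0)
        for _ in range(25):
            y = rng.uniform(0, 3, size=6)
            np.testing.assert_array_equal(full_rhs(0.0, y, params), full_rhs(0.0, y, bumped))

    def test_graft_absent_freezes_graft_damage(self, params):
        y = np.array([0.2, 1.0, 1.5, 0.3, 0.4, 0.1])
        rates = full_rhs(0.0, y, params.replace(alpha=0.5), graft_present=False)
        assert rates[2] == 0.0

    def test_rejects_non_finite_state(self, params):
        with pytest.raises(ValueError):
            full_rhs(0.0, np.array([np.nan, 0, 0, 0, 0, 0]), params)


class TestParameters:
    def test_defaults_are_positive_and_alpha_zero(self, params):
        assert params.alpha == 0.0
        assert params.baseline_a == pytest.approx(0.125)
        assert params.cap_i == pytest.approx(1.6)
        assert params.cap_d == pytest.approx(17.5)

    @pytest.mark.parametrize("bad", [{"mu_i": -1.0}, {"mu_i": 0.0}, {"alpha": 1.5}, {"nope": 1.0}])
    def test_validation(self, bad):
        with pytest.raises(ParameterError):
            ModelParameters().replace(**bad)

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_file_round_trip(self, tmp_path, suffix):
        p = ModelParameters(alpha=0.4).replace(mu_i=0.06)
        path = tmp_path / f"params{suffix}"
        p.to_file(path)
        assert ModelParameters.from_file(path) == p

    def test_state_variable_order(self):
        assert STATE_VARS == ("I", "D", "D_G", "A", "T_P", "T_A")
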