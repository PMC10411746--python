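"""Equilibria, Jacobian, local stability, Lyapunov certification."""

import math

import numpy as np
import pytest

from twopredprey import (
    ModelParameters,
    find_equilibria,
    global_stability_conditions,
    jacobian,
    local_stability,
    lyapunov,
    lyapunov_derivative,
    lyapunov_derivative_numeric,
    rhs,
    sample_parameters,
    local_stability_conditions,
)
from conftest import equilibrium


class TestFindEquilibria:
    def test_case1_axial_points(self, case1):
        assert equilibrium(case1, "P1").coords == pytest.approx((0, 1, 1))
        assert equilibrium(case1, "P4").coords == pytest.approx((3, 0, 0))
        assert equilibrium(case1, "P1").admissible
        assert equilibrium(case1, "P4").admissible

    def test_case2_predatorII_point_inadmissible(self, case2):
        p2 = equilibrium(case2, "P2")
        assert p2.coords[2] == pytest.approx((0.1 - 0.95) / 0.1)  # -8.5
        assert not p2.admissible

    def test_degenerate_point_coincides_with_trivial(self):
        params = ModelParameters(0.5, 0.2, 0.1, 0, 0, 0, 0,
                                 0.3, 0.3, 0.1, 0.2, 0.2, 0.1)
        assert equilibrium(params, "P1").coords == pytest.approx((0, 0, 0))

    def test_zero_denominator_points_omitted(self):
        params = ModelParameters(0.5, 0.2, 0.1, 0, 0, 0, 0,
                                 0.3, 0.2, 0.0, 0.3, 0.2, 0.1)
        tags = {p.tag for p in find_equilibria(params)}
        assert "P1" not in tags and "P3" not in tags
        assert "P2" in tags and "P4" in tags

    def test_no_coexistence_point(self, case1):
        assert all(p.tag in {"trivial", "P1", "P2", "P3", "P4"}
                   for p in find_equilibria(case1))


class TestJacobian:
    def test_diagonal_at_origin(self, case1):
        jac = jacobian((0, 0, 0), case1)
        assert np.allclose(jac, np.diag([0.3, 0.1, 0.1]))

    def test_prey_only_point_case1(self, case1):
        jac = jacobian((3, 0, 0), case1)
        assert np.diag(jac) == pytest.approx((-0.3, 0.4, 0.4))
        # rows 2 and 3 have zero off-diagonals when Y = Z = 0
        assert jac[1, 0] == jac[1, 2] == jac[2, 0] == jac[2, 1] == 0.0

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(42)
        eps = 1e-6
        for trial in range(100):
            params = sample_parameters(trial, "none")
            state = rng.uniform(0.1, 4.0, size=3)
            jac = jacobian(state, params)
            fd = np.empty((3, 3))
            for j in range(3):
                hi, lo = state.copy(), state.copy()
                hi[j] += eps
                lo[j] -= eps
                fd[:, j] = (rhs(hi, params) - rhs(lo, params)) / (2 * eps)
            assert np.max(np.abs(jac - fd)) < 1e-6, trial


class TestLocalStability:
    def test_prey_only_point_unstable_for_case1(self, case1):
        report = local_stability(equilibrium(case1, "P4"), case1)
        assert not report.locally_stable_numeric
        assert report.verdict == "unstable"
        assert max(report.eigenvalues.real) == pytest.approx(0.4)

    def test_inadmissible_point_rejected(self, case2):
        with pytest.raises(ValueError, match="not admissible"):
            local_stability(equilibrium(case2, "P2"), case2)

    def test_marginal_eigenvalue_is_not_stable(self):
        # beta1 = beta2 puts P4 at the origin with a zero eigenvalue
        params = ModelParameters(0.3, 0.3, 0.1, 0, 0, 0, 0,
                                 0.1, 0.2, 0.1, 0.1, 0.2, 0.1)
        report = local_stability(equilibrium(params, "P4"), params)
        assert not report.locally_stable_numeric  # strict inequality contract
        assert report.verdict == "inconclusive"

    def test_pair_point_condition_left_indeterminate(self, case1):
        assert local_stability_conditions("P1", case1) is None
        report = local_stability(equilibrium(case1, "P1"), case1)
        assert report.local_conditions_hold is None

    @pytest.mark.parametrize("constraints,tag", [
        ("local-stability-P2", "P2"),
        ("local-stability-P3", "P3"),
        ("local-stability-P4", "P4"),
    ])
    def test_conditions_imply_negative_eigenvalues(self, constraints, tag):
        """One-way implication: wherever the closed-form local-stability
        inequalities hold, every Jacobian eigenvalue real part is negative."""
        for seed in range(25):
            params = sample_parameters(seed, constraints)
            point = equilibrium(params, tag)
            assert point.admissible
            report = local_stability(point, params, tol=1e-9)
            assert report.local_conditions_hold, (constraints, seed)
            assert report.locally_stable_numeric, (constraints, seed)


class TestLyapunov:
    def test_zero_at_reference_point(self, case1):
        p1 = equilibrium(case1, "P1")
        assert lyapunov(p1.coords, p1) == 0.0

    def test_value_at_doubled_predators(self, case1):
        # two identical summands 2 - 1 - ln 2 around P1 = (0, 1, 1)
        p1 = equilibrium(case1, "P1")
        assert lyapunov((0, 2, 2), p1) == pytest.approx(2 * (1 - math.log(2)))

    def test_nonnegative_around_each_admissible_point(self, case1):
        rng = np.random.default_rng(3)
        for point in find_equilibria(case1):
            if not point.admissible:
                continue
            for state in rng.uniform(0.01, 5.0, size=(1000, 3)):
                assert lyapunov(state, point) >= 0.0

    def test_zero_state_at_positive_reference_diverges(self, case1):
        with pytest.raises(ValueError, match="diverges"):
            lyapunov((0.0, 0.0, 1.0), equilibrium(case1, "P1"))


class TestLyapunovDerivative:
    def test_zero_at_reference_point(self, case1):
        for tag in ("P1", "P2", "P3", "P4"):
            point = equilibrium(case1, tag)
            assert lyapunov_derivative(point.coords, point, case1) \
                == pytest.approx(0.0, abs=1e-15)

    def test_closed_forms_match_chain_rule(self, case1):
        """The per-point closed forms must agree with grad(V) . F."""
        rng = np.random.default_rng(11)
        states = rng.uniform(0.05, 3.0, size=(500, 3))
        for tag in ("P1", "P2", "P3", "P4"):
            point = equilibrium(case1, tag)
            closed = lyapunov_derivative(states, point, case1)
            numeric = lyapunov_derivative_numeric(states, point, case1)
            assert np.allclose(closed, numeric, rtol=1e-9, atol=1e-12), tag

    def test_trivial_point_has_no_closed_form(self, case1):
        trivial = equilibrium(case1, "trivial")
        with pytest.raises(ValueError, match="chain rule"):
            lyapunov_derivative((1, 1, 1), trivial, case1)
        # the numeric route still works there
        val = lyapunov_derivative_numeric((1, 1, 1), trivial, case1)
        assert math.isfinite(float(val))


class TestGlobalStabilityConditions:
    def test_case1_premises_fail_for_P1(self, case1):
        ok, detail = global_stability_conditions("P1", case1)
        assert not ok
        assert not detail["beta1_le_beta2"]  # 0.5 > 0.2

    def test_constructed_P1_premises_certify_descent(self):
        params = ModelParameters(0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1,
                                 0.3, 0.2, 0.1, 0.3, 0.2, 0.1)
        ok, _ = global_stability_conditions("P1", params)
        assert ok
        point = equilibrium(params, "P1")
        rng = np.random.default_rng(5)
        states = rng.uniform(1e-4, 3.0, size=(1000, 3))
        assert np.max(lyapunov_derivative(states, point, params)) <= 1e-12

    def test_decoupled_prey_only_premises(self):
        params = ModelParameters(0.5, 0.2, 0.1, 0, 0, 0, 0,
                                 0.1, 0.3, 0.1, 0.1, 0.3, 0.1)
        ok, _ = global_stability_conditions("P4", params)
        assert ok

    @pytest.mark.parametrize("constraints,tag", [
        ("global-stability-P1", "P1"),
        ("global-stability-P2", "P2"),
        ("global-stability-P3", "P3"),
        ("global-stability-P4", "P4"),
    ])
    def test_premises_imply_nonpositive_descent(self, constraints, tag):
        rng = np.random.default_rng(17)
        for seed in range(25):
            params = sample_parameters(seed, constraints)
            ok, _ = global_stability_conditions(tag, params)
            assert ok, (constraints, seed)
            point = equilibrium(params, tag)
            assert point.admissible
            states = rng.uniform(1e-6, 2.0, size=(500, 3))
            assert np.max(lyapunov_derivative(states, point, params)) <= 1e-12
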