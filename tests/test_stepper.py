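"""Tests for right-hand-side assembly, per-step solvers, and time marching."""

import numpy as np
import pytest

import oracles
from fcable.discretization import caputo_l1_weights, scheme_coefficients
from fcable.problems import ManufacturedSpec, SpatialFactor, example1, example2, make_manufactured
from fcable.stepper import (
    GridSpec,
    SolutionHistory,
    SolverConfig,
    StepFailure,
    StepSystem,
    assemble_rhs,
    march,
    solve_step,
)


def zero_problem(gamma=0.5):
    spec = ManufacturedSpec(gamma=gamma, p=1.0,
                            x_factor=SpatialFactor.poly([0.0]),
                            y_factor=SpatialFactor.poly([0.0]))
    return make_manufactured(spec, name="zero")


class TestGridSpec:
    def test_spacing_and_axes(self):
        g = GridSpec(m=4, n=8)
        assert g.h == pytest.approx(0.25)
        assert g.tau == pytest.approx(0.125)
        np.testing.assert_allclose(g.xs, np.linspace(0, 1, 5))

    @pytest.mark.parametrize("kwargs", [
        dict(m=1, n=4), dict(m=4, n=0), dict(m=4, n=4, q2=-1.0),
        dict(m=4, n=4, T=0.0), dict(m=4, n=4, q2=2.0),  # last: h_x != h_y
    ])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)


class TestAssembleRhs:
    def test_zero_history_and_forcing(self):
        grid = GridSpec(m=4, n=4)
        coeffs = scheme_coefficients(0.5, grid.tau, grid.h)
        weights = caputo_l1_weights(0.5, 4)
        history = SolutionHistory(grid=grid, levels=[np.zeros((5, 5))])
        rhs = assemble_rhs(history, weights, coeffs, np.zeros((5, 5)))
        np.testing.assert_array_equal(rhs, 0.0)

    def test_constant_initial_level(self):
        grid = GridSpec(m=4, n=4)
        coeffs = scheme_coefficients(0.5, grid.tau, grid.h)
        weights = caputo_l1_weights(0.5, 4)
        history = SolutionHistory(grid=grid, levels=[np.full((5, 5), 2.0)])
        rhs = assemble_rhs(history, weights, coeffs, np.zeros((5, 5)))
        np.testing.assert_allclose(rhs, grid.h**2 * 2.0, rtol=1e-14)

    @pytest.mark.parametrize("gamma", [0.3, 0.5])
    def test_matches_bruteforce_stencil_sum_with_history(self, gamma):
        rng = np.random.default_rng(23)
        grid = GridSpec(m=4, n=8)
        coeffs = scheme_coefficients(gamma, grid.tau, grid.h)
        weights = caputo_l1_weights(gamma, 8)
        levels = [rng.normal(scale=0.1, size=(5, 5)) for _ in range(3)]  # k = 2
        forcing = rng.normal(scale=0.1, size=(5, 5))
        rhs = assemble_rhs(SolutionHistory(grid=grid, levels=levels),
                           weights, coeffs, forcing)
        b = oracles.l1_weights(gamma, 8)
        for i in range(1, 4):
            for j in range(1, 4):
                expected = oracles.step_rhs(levels, b, coeffs.g0, grid.h, forcing, i, j)
                assert rhs[i - 1, j - 1] == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_short_weight_vector_rejected(self):
        grid = GridSpec(m=4, n=4)
        coeffs = scheme_coefficients(0.5, grid.tau, grid.h)
        weights = caputo_l1_weights(0.5, 1)
        levels = [np.zeros((5, 5))] * 4  # k = 3 needs b_0..b_3
        with pytest.raises(ValueError, match="weights"):
            assemble_rhs(SolutionHistory(grid=grid, levels=levels),
                         weights, coeffs, np.zeros((5, 5)))


class TestSolveStep:
    def test_single_interior_node_is_scalar_division(self):
        coeffs = scheme_coefficients(0.5, 0.25, 0.5)
        system = StepSystem(coeffs=coeffs, rhs=np.array([[3.14]]),
                            boundary=np.zeros((3, 3)))
        w, _, _ = solve_step(system, SolverConfig())
        assert w[1, 1] == pytest.approx(3.14 / coeffs.a0, rel=1e-12)

    def test_constant_field_reproduced_through_coefficient_identity(self):
        c = 1.7
        coeffs = scheme_coefficients(0.3, 0.2, 0.2)
        rhs = np.full((4, 4), (coeffs.a0 - 4 * coeffs.a1 - 4 * coeffs.a2) * c)
        system = StepSystem(coeffs=coeffs, rhs=rhs, boundary=np.full((6, 6), c))
        for method in ("point_iterative", "direct"):
            w, _, _ = solve_step(system, SolverConfig(method=method))
            np.testing.assert_allclose(w, c, rtol=1e-10)

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9])
    def test_gauss_seidel_agrees_with_direct(self, gamma):
        rng = np.random.default_rng(5)
        coeffs = scheme_coefficients(gamma, 0.125, 0.125)
        assert coeffs.a1 > 0 and coeffs.a2 > 0  # diagonally dominant regime
        system = StepSystem(coeffs=coeffs, rhs=rng.normal(size=(7, 7)),
                            boundary=rng.normal(size=(9, 9)))
        w_gs, iters, res = solve_step(system, SolverConfig(tolerance=1e-12))
        w_dir, _, _ = solve_step(system, SolverConfig(method="direct"))
        assert np.max(np.abs(w_gs - w_dir)) < 1e-10
        assert iters >= 1 and res <= 1e-12

    def test_nonconvergence_is_flagged(self):
        coeffs = scheme_coefficients(0.5, 0.25, 0.25)
        system = StepSystem(coeffs=coeffs, rhs=np.ones((3, 3)),
                            boundary=np.zeros((5, 5)))
        with pytest.raises(StepFailure):
            solve_step(system, SolverConfig(max_iterations=1, tolerance=1e-14))

    def test_nonfinite_rhs_rejected(self):
        coeffs = scheme_coefficients(0.5, 0.25, 0.25)
        with pytest.raises(ValueError, match="finite"):
            StepSystem(coeffs=coeffs, rhs=np.array([[np.inf]]),
                       boundary=np.zeros((3, 3)))


class TestMarch:
    def test_zero_problem_stays_zero(self):
        prob = zero_problem()
        history, report = march(prob, GridSpec(m=4, n=4))
        for level in history.levels:
            np.testing.assert_array_equal(level, 0.0)
        assert report.all_converged

    def test_initial_level_is_sampled_initial_condition(self):
        prob = example2(0.5)
        grid = GridSpec(m=4, n=2)
        history, _ = march(prob, grid)
        X, Y = grid.mesh()
        np.testing.assert_allclose(history[0], prob.initial(X, Y) * np.ones_like(X))

    def test_boundary_carried_at_every_level(self):
        prob = example2(0.5)
        grid = GridSpec(m=4, n=3)
        history, _ = march(prob, grid)
        X, Y = grid.mesh()
        for k in range(1, 4):
            exact = prob.exact(X, Y, k * grid.tau)
            np.testing.assert_allclose(history[k][0, :], exact[0, :], rtol=1e-13)
            np.testing.assert_allclose(history[k][:, -1], exact[:, -1], rtol=1e-13)

    def test_single_step_equals_hand_assembled_system(self):
        # with n = 1 there is no memory sum; the step is one linear solve
        prob = example1(0.5)
        grid = GridSpec(m=4, n=1)
        history, _ = march(prob, grid, SolverConfig(method="direct"))
        levels = oracles.march_dense(prob, m=4, n=1)
        assert np.max(np.abs(history.final() - levels[-1])) < 1e-12

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("factory", [example1, example2])
    def test_march_matches_dense_bruteforce_oracle(self, factory, gamma):
        prob = factory(gamma)
        history, _ = march(prob, GridSpec(m=6, n=6),
                           SolverConfig(tolerance=1e-13))
        levels = oracles.march_dense(prob, m=6, n=6)
        for ours, ref in zip(history.levels, levels):
            assert np.max(np.abs(ours - ref)) < 1e-10

    def test_determinism_bit_identical(self):
        prob = example2(0.3)
        runs = [march(prob, GridSpec(m=5, n=5))[0] for _ in range(2)]
        for a, b in zip(runs[0].levels, runs[1].levels):
            np.testing.assert_array_equal(a, b)

    def test_grid_problem_mismatch_rejected(self):
        prob = example1(0.5)
        with pytest.raises(ValueError, match="disagree"):
            march(prob, GridSpec(m=4, n=4, T=2.0))

    def test_failure_carries_step_index(self):
        prob = example1(0.5)
        with pytest.raises(StepFailure) as excinfo:
            march(prob, GridSpec(m=6, n=2),
                  SolverConfig(max_iterations=2, tolerance=1e-14))
        assert excinfo.value.step == 0

    def test_cubic_spatial_solution_with_linear_time_is_exact(self):
        # per-axis cubics are in the compact operator's kernel of exactness and
        # the L1 weights reproduce a linear-in-time profile exactly
        spec = ManufacturedSpec(
            gamma=0.5, p=1.0,
            x_factor=SpatialFactor.poly([0.5, 1.0, -2.0, 1.0]),
            y_factor=SpatialFactor.poly([1.0, 0.5, 0.25, -0.75]),
        )
        prob = make_manufactured(spec)
        grid = GridSpec(m=4, n=6)
        history, _ = march(prob, grid, SolverConfig(tolerance=1e-14))
        X, Y = grid.mesh()
        exact = prob.exact(X, Y, 1.0)
        assert np.max(np.abs(history.final() - exact)) < 1e-12

    @pytest.mark.parametrize("gamma", [0.5])
    def test_cubic_spatial_quadratic_time_shows_pure_temporal_decay(self, gamma):
        # spatial error vanishes for per-axis cubics, so refinement in tau at
        # fixed m must contract the error at rate about 2 - gamma
        spec = ManufacturedSpec(
            gamma=gamma, p=2.0,
            x_factor=SpatialFactor.poly([0.5, 1.0, -2.0, 1.0]),
            y_factor=SpatialFactor.poly([1.0, 0.5, 0.25, -0.75]),
        )
        prob = make_manufactured(spec)
        errors = []
        for n in (10, 20, 40):
            grid = GridSpec(m=4, n=n)
            history, _ = march(prob, grid, SolverConfig(method="direct"))
            X, Y = grid.mesh()
            err = np.abs(history.final() - prob.exact(X, Y, 1.0))[1:-1, 1:-1]
            errors.append(err.max())
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(np.abs(orders - (2.0 - gamma)) <= 0.25)
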