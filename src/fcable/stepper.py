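"""Implicit time marching for the compact L1 scheme.

Each step solves the 9-point implicit system

    a0*w[i,j] - a1*(edge neighbours) - a2*(corner neighbours) = rhs[i,j]

on the interior of a uniform vertex-centered grid, where the right-hand
side carries the compact average of the previous level, the full fractional
memory sum over all stored levels, and the compact-averaged forcing:

    rhs = h^2*A(w^k) - h^2*sum_{r=1}^{k} b_r*(A(w^{k+1-r}) - A(w^{k-r}))
          + g0*h^2*A(g^{k+1}).

Two solvers are provided per step: lexicographic point Gauss-Seidel with a
warm start from the previous level (the system is strictly diagonally
dominant whenever a1, a2 >= 0, since a0 - 4a1 - 4a2 = h^2(1 + mu0*g0) > 0),
and a sparse direct factorization used as an oracle and fallback.  The full
solution history is stored: the fractional memory term is evaluated exactly,
with no truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.signal import lfilter

from .discretization import (
    CaputoWeights,
    SchemeCoefficients,
    caputo_l1_weights,
    compact_average,
    scheme_coefficients,
)
from .problems import CableProblem

__all__ = [
    "GridSpec",
    "SolverConfig",
    "SolutionHistory",
    "StepSystem",
    "SolveReport",
    "StepFailure",
    "assemble_rhs",
    "solve_step",
    "march",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform vertex-centered space-time grid on a square domain.

    ``m`` subintervals per axis give nodes x_i = q1 + i*h, i = 0..m (boundary
    included); ``n`` time steps of size tau = T/n.  Equal spacing in x and y
    is required.
    """

    m: int
    n: int
    q1: float = 0.0
    q2: float = 1.0
    q3: float = 0.0
    q4: float = 1.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2 (at least one interior node), got {self.m}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.q2 <= self.q1 or self.q4 <= self.q3:
            raise ValueError("domain bounds must satisfy q2 > q1 and q4 > q3")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        hx = (self.q2 - self.q1) / self.m
        hy = (self.q4 - self.q3) / self.m
        if abs(hx - hy) > 1e-12 * max(hx, hy):
            raise ValueError(f"grid must be square: h_x={hx} differs from h_y={hy}")

    @property
    def h(self) -> float:
        return (self.q2 - self.q1) / self.m

    @property
    def tau(self) -> float:
        return self.T / self.n

    @property
    def xs(self) -> np.ndarray:
        return np.linspace(self.q1, self.q2, self.m + 1)

    @property
    def ys(self) -> np.ndarray:
        return np.linspace(self.q3, self.q4, self.m + 1)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs, self.ys, indexing="ij")

    @classmethod
    def for_problem(cls, problem: CableProblem, m: int, n: int) -> "GridSpec":
        return cls(m=m, n=n, q1=problem.q1, q2=problem.q2,
                   q3=problem.q3, q4=problem.q4, T=problem.T)


@dataclass(frozen=True)
class SolverConfig:
    """Per-step linear-solver settings.

    ``point_iterative`` runs lexicographic Gauss-Seidel sweeps, stopping when
    the max-norm of successive-iterate differences drops to ``tolerance``;
    ``direct`` uses a sparse LU factorization.
    """

    method: str = "point_iterative"
    tolerance: float = 1e-10
    max_iterations: int = 10_000
    initial_guess: str = "previous_level"

    def __post_init__(self) -> None:
        if self.method not in ("point_iterative", "direct"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.initial_guess not in ("previous_level", "zeros"):
            raise ValueError(f"unknown initial_guess {self.initial_guess!r}")


@dataclass
class SolutionHistory:
    """All stored time levels w^0..w^k on the full nodal grid."""

    grid: GridSpec
    levels: List[np.ndarray] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.levels) - 1

    def __getitem__(self, k: int) -> np.ndarray:
        return self.levels[k]

    def __len__(self) -> int:
        return len(self.levels)

    def final(self) -> np.ndarray:
        return self.levels[-1]


@dataclass(frozen=True)
class StepSystem:
    """One implicit step: coefficients, interior right-hand side and the new
    level's Dirichlet boundary values (a full nodal array whose interior is
    ignored)."""

    coeffs: SchemeCoefficients
    rhs: np.ndarray
    boundary: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.rhs)):
            raise ValueError("right-hand side contains non-finite entries")


@dataclass
class SolveReport:
    """Per-step iteration counts and final residuals of a marched run."""

    config: SolverConfig
    iterations_per_step: List[int] = field(default_factory=list)
    final_residuals: List[float] = field(default_factory=list)
    converged: List[bool] = field(default_factory=list)

    @property
    def total_iterations(self) -> int:
        return int(sum(self.iterations_per_step))

    @property
    def max_iterations_per_step(self) -> int:
        return int(max(self.iterations_per_step, default=0))

    @property
    def all_converged(self) -> bool:
        return all(self.converged)


class StepFailure(RuntimeError):
    """Raised when a per-step solve fails to converge or is singular."""

    def __init__(self, message: str, step: Optional[int] = None,
                 residual: Optional[float] = None):
        super().__init__(message)
        self.step = step
        self.residual = residual


def assemble_rhs(
    history: SolutionHistory | List[np.ndarray],
    weights: CaputoWeights,
    coeffs: SchemeCoefficients,
    forcing_field: np.ndarray,
) -> np.ndarray:
    """Right-hand side of the implicit system for the step k -> k+1.

    ``history`` holds the full nodal levels w^0..w^k (boundary included, so
    compact averages next to the boundary pick up the known Dirichlet values
    of each level); ``forcing_field`` is g sampled on the full nodal grid at
    t_{k+1}.  Returns the interior array

        h^2*A(w^k) - h^2*sum_{r=1}^{k} b_r*(A(w^{k+1-r}) - A(w^{k-r}))
        + g0*h^2*A(g^{k+1}).
    """
    levels = history.levels if isinstance(history, SolutionHistory) else list(history)
    k = len(levels) - 1
    if k < 0:
        raise ValueError("history must hold at least the initial level")
    if len(weights) < k + 1:
        raise ValueError(
            f"need L1 weights b_0..b_{k}, got only {len(weights)} values"
        )
    h2 = coeffs.h * coeffs.h
    averaged = [compact_average(w) for w in levels]
    rhs = h2 * averaged[k]
    for r in range(1, k + 1):
        rhs -= h2 * weights[r] * (averaged[k + 1 - r] - averaged[k - r])
    rhs += coeffs.g0 * h2 * compact_average(forcing_field)
    return rhs


class _StencilOperator:
    """The interior 9-point operator a0*I - a1*E - a2*C for one coefficient set.

    Caches the sparse LU factorization so a marched run factorizes once.
    """

    def __init__(self, coeffs: SchemeCoefficients, m: int):
        self.coeffs = coeffs
        self.m = m
        self._lu = None

    def _factorize(self):
        if self._lu is None:
            c, mi = self.coeffs, self.m - 1
            if mi == 1:
                shift = sp.csr_matrix((1, 1))
            else:
                ones = np.ones(mi - 1)
                shift = sp.diags([ones, ones], [-1, 1], format="csr")
            eye = sp.identity(mi, format="csr")
            mat = (
                c.a0 * sp.kron(eye, eye)
                - c.a1 * (sp.kron(shift, eye) + sp.kron(eye, shift))
                - c.a2 * sp.kron(shift, shift)
            ).tocsc()
            self._lu = spla.splu(mat)
        return self._lu

    def boundary_contribution(self, boundary: np.ndarray) -> np.ndarray:
        """Neighbour terms that fall on the boundary, moved to the RHS."""
        c = self.coeffs
        wb = np.array(boundary, dtype=float)
        wb[1:-1, 1:-1] = 0.0
        edges = wb[2:, 1:-1] + wb[:-2, 1:-1] + wb[1:-1, 2:] + wb[1:-1, :-2]
        corners = wb[2:, 2:] + wb[:-2, 2:] + wb[2:, :-2] + wb[:-2, :-2]
        return c.a1 * edges + c.a2 * corners

    def solve_direct(self, rhs: np.ndarray, boundary: np.ndarray) -> np.ndarray:
        mi = self.m - 1
        lu = self._factorize()
        rhs_eff = rhs + self.boundary_contribution(boundary)
        sol = lu.solve(rhs_eff.ravel()).reshape(mi, mi)
        if not np.all(np.isfinite(sol)):
            raise StepFailure("direct solve produced non-finite values (singular system?)")
        full = np.array(boundary, dtype=float)
        full[1:-1, 1:-1] = sol
        return full

    def gauss_seidel(
        self, rhs: np.ndarray, boundary: np.ndarray, guess: np.ndarray,
        tolerance: float, max_iterations: int,
    ) -> tuple[np.ndarray, int, float]:
        """Lexicographic point Gauss-Seidel on the full nodal array.

        Within one sweep, row i is updated after rows < i; inside a row the
        update at j uses the already-updated value at j-1, i.e. the new
        values satisfy the first-order recurrence

            a0*w[i,j] - a1*w[i,j-1] = (known terms at j),

        which is evaluated exactly (same iterates as a scalar loop) with a
        linear filter along the row.
        """
        c = self.coeffs
        w = np.array(guess, dtype=float)
        w[0, :], w[-1, :] = boundary[0, :], boundary[-1, :]
        w[:, 0], w[:, -1] = boundary[:, 0], boundary[:, -1]
        diff = np.inf
        iterations = 0
        for iterations in range(1, max_iterations + 1):
            diff = 0.0
            for i in range(1, self.m):
                # terms independent of the in-row recurrence: old j+1 value,
                # new row i-1, old row i+1, and the corner neighbours
                known = (
                    rhs[i - 1, :]
                    + c.a1 * (w[i - 1, 1:-1] + w[i + 1, 1:-1] + w[i, 2:])
                    + c.a2 * (w[i - 1, 2:] + w[i - 1, :-2] + w[i + 1, 2:] + w[i + 1, :-2])
                )
                known[0] += c.a1 * w[i, 0]  # boundary seed of the recurrence
                new_row = lfilter([1.0 / c.a0], [1.0, -c.a1 / c.a0], known)
                diff = max(diff, float(np.max(np.abs(new_row - w[i, 1:-1]))))
                w[i, 1:-1] = new_row
            if diff <= tolerance:
                break
        return w, iterations, diff


def solve_step(
    system: StepSystem,
    config: SolverConfig,
    guess: Optional[np.ndarray] = None,
    operator: Optional[_StencilOperator] = None,
) -> tuple[np.ndarray, int, float]:
    """Solve one implicit step; returns (full nodal field, iterations, residual).

    For the direct method the residual is reported as 0 and iterations as 1.
    Non-convergence of the iterative method raises :class:`StepFailure`
    carrying the last successive-difference norm.
    """
    m = system.boundary.shape[0] - 1
    if system.rhs.shape != (m - 1, m - 1):
        raise ValueError(
            f"rhs shape {system.rhs.shape} inconsistent with boundary shape "
            f"{system.boundary.shape}"
        )
    op = operator if operator is not None else _StencilOperator(system.coeffs, m)
    if config.method == "direct":
        return op.solve_direct(system.rhs, system.boundary), 1, 0.0
    if guess is None or config.initial_guess == "zeros":
        guess = np.zeros_like(system.boundary)
    w, iterations, diff = op.gauss_seidel(
        system.rhs, system.boundary, guess, config.tolerance, config.max_iterations
    )
    if diff > config.tolerance:
        raise StepFailure(
            f"Gauss-Seidel did not reach tolerance {config.tolerance:g} in "
            f"{config.max_iterations} sweeps (last difference {diff:.3e})",
            residual=diff,
        )
    return w, iterations, diff


def march(
    problem: CableProblem,
    grid: GridSpec,
    config: SolverConfig = SolverConfig(),
) -> tuple[SolutionHistory, SolveReport]:
    """March the implicit scheme from t=0 to t=T.

    Level 0 is the initial condition sampled on the grid; every later level
    carries the problem's Dirichlet data on the boundary ring and the scheme
    solution in the interior.  The full history enters each step's memory
    term.
    """
    for got, want, label in [
        (grid.q1, problem.q1, "q1"), (grid.q2, problem.q2, "q2"),
        (grid.q3, problem.q3, "q3"), (grid.q4, problem.q4, "q4"),
        (grid.T, problem.T, "T"),
    ]:
        if abs(got - want) > 1e-12 * max(1.0, abs(want)):
            raise ValueError(f"grid and problem disagree on {label}: {got} vs {want}")

    X, Y = grid.mesh()
    coeffs = scheme_coefficients(problem.gamma, grid.tau, grid.h, problem.mu0)
    weights = caputo_l1_weights(problem.gamma, grid.n)
    op = _StencilOperator(coeffs, grid.m)

    level0 = np.asarray(problem.initial(X, Y), dtype=float) * np.ones_like(X)
    history = SolutionHistory(grid=grid, levels=[level0])
    report = SolveReport(config=config)

    for k in range(grid.n):
        t_next = (k + 1) * grid.tau
        forcing = np.asarray(problem.forcing(X, Y, t_next), dtype=float) * np.ones_like(X)
        rhs = assemble_rhs(history, weights, coeffs, forcing)
        boundary = np.asarray(problem.boundary(X, Y, t_next), dtype=float) * np.ones_like(X)
        system = StepSystem(coeffs=coeffs, rhs=rhs, boundary=boundary)
        try:
            w, iterations, residual = solve_step(
                system, config, guess=history[k], operator=op
            )
        except StepFailure as exc:
            exc.step = k
            report.iterations_per_step.append(config.max_iterations)
            report.final_residuals.append(exc.residual if exc.residual is not None else np.nan)
            report.converged.append(False)
            raise
        history.levels.append(w)
        report.iterations_per_step.append(iterations)
        report.final_residuals.append(residual)
        report.converged.append(True)
    return history, report
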