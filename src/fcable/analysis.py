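"""Error metrics, convergence-order estimators, refinement studies, and the
von Neumann amplification-factor stability scan.

Error metrics follow the benchmark convention of the finite-difference
literature on fractional diffusion: the maximum (M_E) and mean (A_E)
absolute nodal error over interior nodes at the final time.

Two empirical order estimators are provided, matching the refinement
pairings customary for a scheme with error O(tau^(2-gamma) + h^4):

* temporal: order = log2(ME(2*tau, h) / ME(tau, h)) at fixed h,
* spatial:  order = log2(ME(16*tau, 2h) / ME(tau, h)) — the time step is
  refined 16-fold alongside each spatial halving so that a fourth-order
  spatial error contraction maps to an order estimate of about 4 when the
  spatial term dominates.

The stability scan evaluates the first-step Fourier amplification factor

    F(phi1*h, phi2*h) = (h^2/36) * (25 + 5*m0 + m1) / (a0 - 2*a1*m0 - 4*a2*m1)

with m0 = cos(phi1*h) + cos(phi2*h), m1 = cos(phi1*h)*cos(phi2*h), over a
uniform grid of mode angles in [0, pi]^2.  At phi = 0 the factor reduces to
1/(1 + mu0*g0) < 1, which is also its maximum whenever a1, a2 > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .discretization import scheme_coefficients
from .problems import CableProblem
from .stepper import GridSpec, SolutionHistory, SolveReport, SolverConfig, march

__all__ = [
    "ErrorReport",
    "RefinementStudy",
    "AmplificationSpectrum",
    "error_report",
    "order_temporal",
    "order_spatial",
    "amplification_factor",
    "stability_scan",
    "refinement_study",
]


@dataclass(frozen=True)
class ErrorReport:
    """Maximum and average absolute interior nodal error at the final time."""

    M_E: float
    A_E: float
    gamma: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.A_E <= self.M_E or math.isclose(self.A_E, self.M_E)):
            raise ValueError(f"A_E={self.A_E} exceeds M_E={self.M_E}")


@dataclass
class RefinementStudy:
    """Ordered run records of a refinement experiment plus derived orders."""

    mode: str
    rows: List[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path, float_format: Optional[str] = "%.6g") -> None:
        self.to_dataframe().to_csv(path, index=False, float_format=float_format)


@dataclass(frozen=True)
class AmplificationSpectrum:
    """First-step amplification factor sampled on a [0, pi]^2 mode grid."""

    gamma: float
    tau: float
    h: float
    mu0: float
    phis: np.ndarray
    factors: np.ndarray

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.factors)))

    @property
    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(np.abs(self.factors)), self.factors.shape)
        return float(self.phis[i]), float(self.phis[j])


def error_report(numerical: SolutionHistory, problem: CableProblem) -> ErrorReport:
    """Compare the final marched level against the problem's exact solution."""
    if problem.exact is None:
        raise ValueError("error_report requires a problem with an exact solution")
    grid = numerical.grid
    X, Y = grid.mesh()
    exact = np.asarray(problem.exact(X, Y, grid.T), dtype=float)
    err = np.abs(exact - numerical.final())[1:-1, 1:-1]
    return ErrorReport(
        M_E=float(err.max()), A_E=float(err.mean()),
        gamma=problem.gamma, m=grid.m, n=grid.n,
    )


def _log2_ratio(err_coarse: float, err_fine: float) -> float:
    if err_coarse <= 0 or err_fine <= 0:
        raise ValueError(
            f"order estimates need positive errors, got ({err_coarse}, {err_fine})"
        )
    return math.log2(err_coarse / err_fine)


def order_temporal(err_coarse: float, err_fine: float) -> float:
    """log2 error ratio between runs at (2*tau, h) and (tau, h)."""
    return _log2_ratio(err_coarse, err_fine)


def order_spatial(err_coarse: float, err_fine: float) -> float:
    """log2 error ratio between runs at (16*tau, 2h) and (tau, h)."""
    return _log2_ratio(err_coarse, err_fine)


def amplification_factor(
    gamma: float, tau: float, h: float, mu0: float, phi1h: float, phi2h: float
) -> float:
    """First-step Fourier growth factor of the scheme at mode angles (phi1*h, phi2*h)."""
    c = scheme_coefficients(gamma, tau, h, mu0)
    m0 = math.cos(phi1h) + math.cos(phi2h)
    m1 = math.cos(phi1h) * math.cos(phi2h)
    denom = c.a0 - 2.0 * c.a1 * m0 - 4.0 * c.a2 * m1
    if abs(denom) < 1e-300:
        raise ZeroDivisionError(
            f"amplification denominator vanishes at (gamma={gamma}, tau={tau}, "
            f"h={h}, mu0={mu0}, phi1h={phi1h}, phi2h={phi2h})"
        )
    return (h * h / 36.0) * (25.0 + 5.0 * m0 + m1) / denom


def stability_scan(
    gamma: float, tau: float, h: float, mu0: float = 1.0, resolution: int = 129
) -> AmplificationSpectrum:
    """Evaluate the amplification factor on a uniform (phi1*h, phi2*h) grid.

    ``resolution`` points per axis over [0, pi]; resolution=2 degenerates to
    the four corner modes.
    """
    if resolution < 2:
        raise ValueError(f"resolution must be >= 2, got {resolution}")
    c = scheme_coefficients(gamma, tau, h, mu0)
    phis = np.linspace(0.0, math.pi, resolution)
    cos1 = np.cos(phis)[:, None]
    cos2 = np.cos(phis)[None, :]
    m0 = cos1 + cos2
    m1 = cos1 * cos2
    denom = c.a0 - 2.0 * c.a1 * m0 - 4.0 * c.a2 * m1
    if np.any(np.abs(denom) < 1e-300):
        raise ZeroDivisionError(
            f"amplification denominator vanishes somewhere on the scan grid "
            f"(gamma={gamma}, tau={tau}, h={h}, mu0={mu0})"
        )
    factors = (h * h / 36.0) * (25.0 + 5.0 * m0 + m1) / denom
    return AmplificationSpectrum(
        gamma=gamma, tau=tau, h=h, mu0=mu0, phis=phis, factors=factors
    )


def _run(problem: CableProblem, m: int, n: int, config: SolverConfig
         ) -> tuple[ErrorReport, SolveReport]:
    grid = GridSpec.for_problem(problem, m=m, n=n)
    history, report = march(problem, grid, config)
    return error_report(history, problem), report


def refinement_study(
    problem: Callable[[float], CableProblem],
    gammas: Sequence[float],
    grids: Sequence,
    config: SolverConfig = SolverConfig(),
    mode: str = "table",
) -> RefinementStudy:
    """Run a grid-refinement experiment and tabulate errors and orders.

    Parameters
    ----------
    problem
        Factory mapping a fractional order gamma to a :class:`CableProblem`.
    gammas
        Fractional orders to sweep.
    grids
        Mode-dependent refinement pattern:

        * ``mode="table"``: a sequence of (m, n) pairs; one error row each.
        * ``mode="spatial"``: a sequence of ((m_c, n_c), (m_f, n_f)) pairs
          with m_f = 2*m_c and n_f = 16*n_c (coupled refinement); the order
          column compares the two runs of each pair.
        * ``mode="temporal"``: (m, [n_1, n_2, ...]) with increasing n at
          fixed m; orders between consecutive runs.
    """
    if mode not in ("table", "spatial", "temporal"):
        raise ValueError(f"unknown study mode {mode!r}")
    if len(gammas) == 0:
        raise ValueError("at least one gamma is required")
    study = RefinementStudy(mode=mode)

    for gamma in gammas:
        prob = problem(gamma)
        if mode == "table":
            if len(grids) == 0:
                raise ValueError("table mode needs at least one (m, n) pair")
            for m, n in grids:
                err, rep = _run(prob, m, n, config)
                study.rows.append({
                    "gamma": gamma, "m": m, "n": n,
                    "h": 1.0 / m * (prob.q2 - prob.q1), "tau": prob.T / n,
                    "M_E": err.M_E, "A_E": err.A_E,
                    "iterations": rep.max_iterations_per_step,
                })
        elif mode == "spatial":
            if len(grids) == 0:
                raise ValueError("spatial mode needs at least one grid pair")
            for (mc, nc), (mf, nf) in grids:
                if mf != 2 * mc or nf != 16 * nc:
                    raise ValueError(
                        f"spatial mode expects (2m, 16n) refinement, got "
                        f"({mc},{nc}) -> ({mf},{nf})"
                    )
                ec, rc = _run(prob, mc, nc, config)
                ef, rf = _run(prob, mf, nf, config)
                study.rows.append({
                    "gamma": gamma, "m": mc, "n": nc, "M_E": ec.M_E,
                    "A_E": ec.A_E, "iterations": rc.max_iterations_per_step,
                    "order": np.nan,
                })
                study.rows.append({
                    "gamma": gamma, "m": mf, "n": nf, "M_E": ef.M_E,
                    "A_E": ef.A_E, "iterations": rf.max_iterations_per_step,
                    "order": order_spatial(ec.M_E, ef.M_E),
                })
        else:  # temporal
            m, ns = grids
            if len(ns) < 2:
                raise ValueError("temporal mode needs at least two step counts")
            prev = None
            prev_n = None
            for n in ns:
                err, rep = _run(prob, m, n, config)
                # the temporal-order formula assumes tau halving
                order = (
                    order_temporal(prev, err.M_E)
                    if prev is not None and n == 2 * prev_n
                    else np.nan
                )
                study.rows.append({
                    "gamma": gamma, "m": m, "n": n, "tau": prob.T / n,
                    "M_E": err.M_E, "A_E": err.A_E,
                    "iterations": rep.max_iterations_per_step, "order": order,
                })
                prev = err.M_E
                prev_n = n
    return study
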