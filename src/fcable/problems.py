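"""Continuous problem definitions and the manufactured-solution generator.

A :class:`CableProblem` bundles everything the time stepper needs to know
about the continuous model: the rectangular domain, final time, fractional
order gamma, reaction coefficient mu0, the forcing term, and initial /
Dirichlet boundary data (plus the exact solution when one is known).

Two classic benchmark problems on the unit square are built in:

* :func:`example1` — exact solution ``t^2 sin(pi x) sin(pi y)`` with
  homogeneous Dirichlet boundary,
* :func:`example2` — exact solution ``t^2 e^(x+y)`` with time-dependent
  inhomogeneous boundary data.

:func:`make_manufactured` generalizes both: it takes a separable target
solution ``t^p * X(x) * Y(y)`` and produces the closed-form forcing that
makes it an exact solution of the fractional cable equation, so that every
generated problem has zero-by-construction PDE residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi
from typing import Callable, Optional, Sequence

import numpy as np

from .discretization import FractionalOrder, _as_gamma, caputo_power_rule

__all__ = [
    "CableProblem",
    "SpatialFactor",
    "ManufacturedSpec",
    "example1",
    "example2",
    "make_manufactured",
]

ScalarField3 = Callable[[np.ndarray, np.ndarray, float], np.ndarray]
ScalarField2 = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class CableProblem:
    """A 2-D time-fractional cable-equation problem on a rectangle.

    All function attributes are vectorizable: they accept numpy arrays for
    the spatial arguments and a scalar time, and broadcast.
    """

    q1: float
    q2: float
    q3: float
    q4: float
    T: float
    gamma: float
    mu0: float
    forcing: ScalarField3
    initial: ScalarField2
    boundary: ScalarField3
    exact: Optional[ScalarField3] = None
    name: str = "cable-problem"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", _as_gamma(self.gamma))
        if self.q2 <= self.q1 or self.q4 <= self.q3:
            raise ValueError("domain bounds must satisfy q2 > q1 and q4 > q3")
        if self.T <= 0:
            raise ValueError(f"final time must be positive, got {self.T}")
        if self.mu0 < 0:
            raise ValueError(f"mu0 must be >= 0, got {self.mu0}")
        self._check_compatibility()

    def _check_compatibility(self, npts: int = 17, tol: float = 1e-12) -> None:
        """Initial and boundary data must agree at t=0 on the boundary; when an
        exact solution is supplied, initial/boundary data must be its restriction."""
        xs = np.linspace(self.q1, self.q2, npts)
        ys = np.linspace(self.q3, self.q4, npts)
        bx = np.concatenate([xs, xs, np.full(npts, self.q1), np.full(npts, self.q2)])
        by = np.concatenate([np.full(npts, self.q3), np.full(npts, self.q4), ys, ys])
        mismatch = np.max(np.abs(self.boundary(bx, by, 0.0) - self.initial(bx, by)))
        if mismatch > tol:
            raise ValueError(
                f"initial and boundary data disagree at t=0 (max {mismatch:.3e})"
            )
        if self.exact is not None:
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            d0 = np.max(np.abs(self.exact(X, Y, 0.0) - self.initial(X, Y)))
            tmid = 0.5 * self.T
            db = np.max(np.abs(self.exact(bx, by, tmid) - self.boundary(bx, by, tmid)))
            if max(d0, db) > tol:
                raise ValueError(
                    "initial/boundary data are not the restriction of the exact solution"
                )


@dataclass(frozen=True)
class SpatialFactor:
    """One separable spatial factor: sin(c*x), exp(c*x), or a polynomial.

    Provides the factor and its second derivative in closed form (both are
    needed to build the manufactured forcing).
    """

    family: str  # "sin" | "exp" | "poly"
    c: float = 1.0
    coeffs: Sequence[float] = field(default_factory=tuple)  # low-to-high degree

    def __post_init__(self) -> None:
        if self.family not in ("sin", "exp", "poly"):
            raise ValueError(f"unsupported spatial factor family {self.family!r}")
        if self.family == "poly" and len(self.coeffs) == 0:
            raise ValueError("polynomial factor needs at least one coefficient")
        object.__setattr__(self, "coeffs", tuple(float(a) for a in self.coeffs))

    @classmethod
    def sin(cls, c: float) -> "SpatialFactor":
        return cls(family="sin", c=c)

    @classmethod
    def exp(cls, c: float) -> "SpatialFactor":
        return cls(family="exp", c=c)

    @classmethod
    def poly(cls, coeffs: Sequence[float]) -> "SpatialFactor":
        return cls(family="poly", coeffs=coeffs)

    def value(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "sin":
            return np.sin(self.c * x)
        if self.family == "exp":
            return np.exp(self.c * x)
        return np.polynomial.polynomial.polyval(x, self.coeffs)

    def second_derivative(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "sin":
            return -(self.c**2) * np.sin(self.c * x)
        if self.family == "exp":
            return self.c**2 * np.exp(self.c * x)
        d2 = np.polynomial.polynomial.polyder(self.coeffs, 2)
        return np.polynomial.polynomial.polyval(x, d2) if len(d2) else np.zeros_like(x)


@dataclass(frozen=True)
class ManufacturedSpec:
    """Recipe for a manufactured problem with exact solution t^p * X(x) * Y(y)."""

    gamma: float
    p: float = 2.0
    x_factor: SpatialFactor = field(default_factory=lambda: SpatialFactor.sin(pi))
    y_factor: SpatialFactor = field(default_factory=lambda: SpatialFactor.sin(pi))
    mu0: float = 1.0
    q1: float = 0.0
    q2: float = 1.0
    q3: float = 0.0
    q4: float = 1.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError(f"time power p must be positive, got {self.p}")


def make_manufactured(spec: ManufacturedSpec, name: str = "manufactured") -> CableProblem:
    """Build a :class:`CableProblem` whose exact solution is t^p * X(x) * Y(y).

    The forcing is assembled in closed form from the Caputo power rule and
    the analytic second derivatives of the spatial factors:

        g = D_t^gamma(t^p) * X*Y - t^p * (X''*Y + X*Y'') + mu0 * t^p * X*Y
    """
    g = _as_gamma(spec.gamma)
    X, Y = spec.x_factor, spec.y_factor
    p, mu0 = spec.p, spec.mu0

    def exact(x, y, t):
        return t**p * X.value(x) * Y.value(y)

    def forcing(x, y, t):
        xy = X.value(x) * Y.value(y)
        lap = X.second_derivative(x) * Y.value(y) + X.value(x) * Y.second_derivative(y)
        tp = t**p
        return caputo_power_rule(p, g, t) * xy - tp * lap + mu0 * tp * xy

    return CableProblem(
        q1=spec.q1, q2=spec.q2, q3=spec.q3, q4=spec.q4, T=spec.T,
        gamma=g, mu0=mu0,
        forcing=forcing,
        initial=lambda x, y: exact(x, y, 0.0),
        boundary=exact,
        exact=exact,
        name=name,
    )


def example1(gamma: FractionalOrder | float) -> CableProblem:
    """Benchmark with exact solution ``t^2 sin(pi x) sin(pi y)`` on (0,1)^2.

    Unit reaction coefficient; forcing
    ``(2 t^(2-gamma)/Gamma(3-gamma) + t^2 (1 + 2 pi^2)) sin(pi x) sin(pi y)``;
    homogeneous initial and Dirichlet boundary data; T = 1.
    """
    spec = ManufacturedSpec(
        gamma=_as_gamma(gamma), p=2.0,
        x_factor=SpatialFactor.sin(pi), y_factor=SpatialFactor.sin(pi), mu0=1.0,
    )
    return make_manufactured(spec, name="example1")


def example2(gamma: FractionalOrder | float) -> CableProblem:
    """Benchmark with exact solution ``t^2 e^(x+y)`` on (0,1)^2.

    Unit reaction coefficient; forcing
    ``e^(x+y) (2 t^(2-gamma)/Gamma(3-gamma) - t^2)``; zero initial data and
    time-dependent Dirichlet boundary sampled from the exact solution; T = 1.
    """
    spec = ManufacturedSpec(
        gamma=_as_gamma(gamma), p=2.0,
        x_factor=SpatialFactor.exp(1.0), y_factor=SpatialFactor.exp(1.0), mu0=1.0,
    )
    return make_manufactured(spec, name="example2")
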