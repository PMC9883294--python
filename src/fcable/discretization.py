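"""Pure numerical kernels for the compact-in-space, L1-in-time scheme.

This module holds the four building blocks of the discretization of the 2-D
time-fractional cable equation

    D_t^gamma w = w_xx + w_yy - mu0 * w + g,     0 < gamma < 1,

namely

* the L1 weights ``b_r = (r+1)^(1-gamma) - r^(1-gamma)`` of the Caputo
  derivative discretized on a uniform time grid,
* the Caputo derivative of a pure power ``t^p`` (used to manufacture
  forcing terms with known exact solutions),
* the 9-point compact averaging operator ``A = (1 + dx^2/12)(1 + dy^2/12)``
  with weights 25/36 (center), 5/72 (edge), 1/144 (corner),
* the scalar coefficients ``g0, a0, a1, a2`` of the fully implicit
  one-step system.

Everything here is grid-agnostic: arrays in, arrays out, no problem or
boundary-condition knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gamma as _gamma_fn

import numpy as np

__all__ = [
    "FractionalOrder",
    "CaputoWeights",
    "CompactWeights",
    "SchemeCoefficients",
    "COMPACT_WEIGHTS",
    "caputo_l1_weights",
    "caputo_power_rule",
    "scheme_coefficients",
    "coefficients_from_g0",
    "compact_average",
]


@dataclass(frozen=True)
class FractionalOrder:
    """Fractional time-derivative order, constrained to the open interval (0, 1)."""

    gamma: float

    def __post_init__(self) -> None:
        g = float(self.gamma)
        if not (0.0 < g < 1.0):
            raise ValueError(f"fractional order must satisfy 0 < gamma < 1, got {g}")
        object.__setattr__(self, "gamma", g)

    def __float__(self) -> float:
        return self.gamma


def _as_gamma(gamma: FractionalOrder | float) -> float:
    """Coerce to a validated float in (0, 1)."""
    if isinstance(gamma, FractionalOrder):
        return gamma.gamma
    return FractionalOrder(gamma).gamma


@dataclass(frozen=True)
class CaputoWeights:
    """L1 weights b_0..b_K for a given fractional order.

    Invariants: b_0 = 1; the sequence is strictly positive and strictly
    decreasing; partial sums telescope to sum_{r=0}^{K-1} b_r = K^(1-gamma).
    """

    gamma: float
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, r):
        return self.values[r]


# Exact rational weights of the compact 9-point average; they sum to one.
@dataclass(frozen=True)
class CompactWeights:
    center: Fraction = Fraction(25, 36)
    edge: Fraction = Fraction(5, 72)
    corner: Fraction = Fraction(1, 144)


COMPACT_WEIGHTS = CompactWeights()
assert COMPACT_WEIGHTS.center + 4 * COMPACT_WEIGHTS.edge + 4 * COMPACT_WEIGHTS.corner == 1


@dataclass(frozen=True)
class SchemeCoefficients:
    """Scalar coefficients of the implicit 9-point one-step system.

    ``g0 = tau^gamma * Gamma(2 - gamma)`` scales the right-hand side; a0 is
    the diagonal weight, a1/a2 the edge/corner neighbour weights at the new
    time level.  They satisfy the algebraic identity

        a0 - 4*a1 - 4*a2 = h^2 * (1 + mu0 * g0),

    which guarantees strict diagonal dominance whenever a1, a2 >= 0.
    """

    gamma: float
    tau: float
    h: float
    mu0: float
    g0: float
    a0: float
    a1: float
    a2: float


def caputo_l1_weights(gamma: FractionalOrder | float, K: int) -> CaputoWeights:
    """L1 weights ``b_r = (r+1)^(1-gamma) - r^(1-gamma)`` for r = 0..K.

    Parameters
    ----------
    gamma
        Fractional order in (0, 1).
    K
        Largest weight index (K >= 0).
    """
    g = _as_gamma(gamma)
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    r = np.arange(K + 2, dtype=float)
    powers = r ** (1.0 - g)
    return CaputoWeights(gamma=g, values=np.diff(powers))


def caputo_power_rule(p: float, gamma: FractionalOrder | float, t) -> np.ndarray | float:
    """Caputo derivative of order gamma of the pure power t^p.

        D_t^gamma t^p = Gamma(p+1) / Gamma(p+1-gamma) * t^(p-gamma)

    Only p > 0 is accepted; the Caputo derivative of a constant vanishes and
    is handled separately by callers.  For p < gamma the result is singular
    at t = 0.
    """
    g = _as_gamma(gamma)
    if p <= 0:
        raise ValueError(f"caputo_power_rule requires p > 0, got p={p}")
    coef = _gamma_fn(p + 1.0) / _gamma_fn(p + 1.0 - g)
    t = np.asarray(t, dtype=float)
    out = coef * t ** (p - g)
    return out if out.ndim else float(out)


def coefficients_from_g0(g0: float, h: float, mu0: float) -> tuple[float, float, float]:
    """The (a0, a1, a2) triple as a function of g0; exposed for limit checks."""
    fac = h * h * (1.0 + mu0 * g0)
    a0 = (10.0 / 3.0) * g0 + float(COMPACT_WEIGHTS.center) * fac
    a1 = (2.0 / 3.0) * g0 - float(COMPACT_WEIGHTS.edge) * fac
    a2 = g0 / 6.0 - float(COMPACT_WEIGHTS.corner) * fac
    return a0, a1, a2


def scheme_coefficients(
    gamma: FractionalOrder | float, tau: float, h: float, mu0: float = 1.0
) -> SchemeCoefficients:
    """Assemble the scalar coefficients g0, a0, a1, a2 of the implicit system.

    The reaction coefficient mu0 enters through the factor (1 + mu0*g0);
    mu0 = 1 recovers the coefficients of the standard cable equation with
    unit reaction term.
    """
    g = _as_gamma(gamma)
    if tau <= 0 or h <= 0:
        raise ValueError(f"tau and h must be positive, got tau={tau}, h={h}")
    if mu0 < 0:
        raise ValueError(f"mu0 must be >= 0, got {mu0}")
    g0 = tau**g * _gamma_fn(2.0 - g)
    a0, a1, a2 = coefficients_from_g0(g0, h, mu0)
    return SchemeCoefficients(
        gamma=g, tau=tau, h=h, mu0=mu0, g0=g0, a0=a0, a1=a1, a2=a2
    )


def compact_average(field: np.ndarray, weights: CompactWeights = COMPACT_WEIGHTS) -> np.ndarray:
    """Apply the 9-point compact average to a nodal field; returns the interior.

    At each interior node the result is

        25/36 * center + 5/72 * (4 edge neighbours) + 1/144 * (4 corners).

    The input must include the boundary ring; the output shape is
    ``(M-2, N-2)`` for an ``(M, N)`` input.
    """
    f = np.asarray(field, dtype=float)
    if f.ndim != 2 or f.shape[0] < 3 or f.shape[1] < 3:
        raise ValueError(f"field must be 2-D and at least 3x3, got shape {f.shape}")
    wc, we, wk = (float(weights.center), float(weights.edge), float(weights.corner))
    center = f[1:-1, 1:-1]
    edges = f[2:, 1:-1] + f[:-2, 1:-1] + f[1:-1, 2:] + f[1:-1, :-2]
    corners = f[2:, 2:] + f[:-2, 2:] + f[2:, :-2] + f[:-2, :-2]
    return wc * center + we * edges + wk * corners
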