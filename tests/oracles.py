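"""Independent brute-force oracles for the compact L1 scheme.

Everything here is written as literal nested loops over the 9-point stencil
and solved with dense linear algebra, deliberately sharing no code with the
package's vectorized kernels.  Used as the reference in oracle-equivalence
tests on small grids.
"""

import math

import numpy as np

W_C, W_E, W_K = 25.0 / 36.0, 5.0 / 72.0, 1.0 / 144.0


def l1_weights(gamma, K):
    return [(r + 1) ** (1 - gamma) - r ** (1 - gamma) for r in range(K + 1)]


def coefficients(gamma, tau, h, mu0):
    g0 = tau**gamma * math.gamma(2 - gamma)
    fac = h * h * (1 + mu0 * g0)
    a0 = 10.0 / 3.0 * g0 + W_C * fac
    a1 = 2.0 / 3.0 * g0 - W_E * fac
    a2 = g0 / 6.0 - W_K * fac
    return g0, a0, a1, a2


def nine_point_average(w, i, j):
    """25/36 center + 5/72 edges + 1/144 corners, scalar loops."""
    return (
        W_C * w[i, j]
        + W_E * (w[i + 1, j] + w[i - 1, j] + w[i, j + 1] + w[i, j - 1])
        + W_K * (w[i + 1, j + 1] + w[i - 1, j + 1] + w[i + 1, j - 1] + w[i - 1, j - 1])
    )


def step_rhs(levels, b, g0, h, forcing_full, i, j):
    """Right-hand side at interior node (i, j) for the step k -> k+1."""
    k = len(levels) - 1
    h2 = h * h
    rhs = h2 * nine_point_average(levels[k], i, j)
    for r in range(1, k + 1):
        rhs -= h2 * b[r] * (
            nine_point_average(levels[k + 1 - r], i, j)
            - nine_point_average(levels[k - r], i, j)
        )
    rhs += g0 * h2 * nine_point_average(forcing_full, i, j)
    return rhs


def solve_step_dense(levels, b, gamma, tau, h, mu0, forcing_full, boundary_full):
    """Assemble and solve one implicit step as a dense linear system."""
    m = levels[0].shape[0] - 1
    g0, a0, a1, a2 = coefficients(gamma, tau, h, mu0)
    mi = m - 1
    idx = {(i, j): (i - 1) * mi + (j - 1) for i in range(1, m) for j in range(1, m)}
    A = np.zeros((mi * mi, mi * mi))
    rhs = np.zeros(mi * mi)
    for (i, j), row in idx.items():
        A[row, row] = a0
        rhs[row] = step_rhs(levels, b, g0, h, forcing_full, i, j)
        for di, dj, coef in [
            (1, 0, a1), (-1, 0, a1), (0, 1, a1), (0, -1, a1),
            (1, 1, a2), (-1, 1, a2), (1, -1, a2), (-1, -1, a2),
        ]:
            ii, jj = i + di, j + dj
            if (ii, jj) in idx:
                A[row, idx[(ii, jj)]] = -coef
            else:
                rhs[row] += coef * boundary_full[ii, jj]
    sol = np.linalg.solve(A, rhs)
    out = np.array(boundary_full, dtype=float)
    for (i, j), row in idx.items():
        out[i, j] = sol[row]
    return out


def march_dense(problem, m, n):
    """Full brute-force march of the scheme for a CableProblem on (m, n)."""
    xs = np.linspace(problem.q1, problem.q2, m + 1)
    ys = np.linspace(problem.q3, problem.q4, m + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    h = xs[1] - xs[0]
    tau = problem.T / n
    b = l1_weights(problem.gamma, n)
    levels = [np.asarray(problem.initial(X, Y), dtype=float) * np.ones_like(X)]
    for k in range(n):
        t1 = (k + 1) * tau
        forcing = np.asarray(problem.forcing(X, Y, t1), dtype=float) * np.ones_like(X)
        boundary = np.asarray(problem.boundary(X, Y, t1), dtype=float) * np.ones_like(X)
        levels.append(
            solve_step_dense(levels, b, problem.gamma, tau, h, problem.mu0,
                             forcing, boundary)
        )
    return levels
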