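# Methods

## Model

The solver targets the two-dimensional time-fractional cable equation

    D_t^γ w = w_xx + w_yy − μ₀ w + g(x,y,t),   (x,y) ∈ (Q₁,Q₂)×(Q₃,Q₄),  t ∈ (0,T],

with Caputo derivative of order γ ∈ (0,1), reaction coefficient μ₀ ≥ 0,
Dirichlet boundary data, and an initial condition compatible with the
boundary data at t = 0 (the constructor enforces compatibility to 1e-12 on
sampled boundary points). The fractional derivative gives the equation a
memory: the solution at every earlier time level influences the current
step. The physical setting is subdiffusive ion transport in neuronal
dendrites; in that reading w is the transmembrane potential, μ₀ a leak
term, and γ the anomalous-diffusion exponent.

## Discretization

* Uniform vertex-centered grid, `x_i = Q₁ + i h`, `i = 0..m`, with equal
  spacing in both axes (enforced; non-square grids are out of scope), and
  uniform time steps `τ = T/n`.
* Caputo derivative: L1 formula, weights `b_r = (r+1)^(1−γ) − r^(1−γ)`.
  The weights satisfy `b₀ = 1`, strict positivity and monotone decay, and
  the telescoping identity `Σ_{r<K} b_r = K^(1−γ)`; these are asserted as
  properties, with the weights kept as a single vector per run.
* Space: compact fourth-order operator. Applying the averaging operator
  `A = (1 + δ_x²/12)(1 + δ_y²/12)` to the equation and expanding produces a
  9-point implicit stencil with new-level coefficients

      g₀ = τ^γ Γ(2−γ),
      a₀ = (10/3) g₀ + (25/36) h²(1+μ₀g₀),
      a₁ = (2/3) g₀ − (5/72) h²(1+μ₀g₀),
      a₂ = g₀/6 − (1/144) h²(1+μ₀g₀),

  and a right-hand side

      rhs = h² A(w^k) − h² Σ_{r=1}^{k} b_r (A(w^{k+1−r}) − A(w^{k−r})) + g₀ h² A(g^{k+1}).

  The averaging weights 25/36, 5/72, 1/144 are stored as exact rationals so
  the sum-to-one identity is exact; the coefficient identity
  `a₀ − 4a₁ − 4a₂ = h²(1+μ₀g₀)` then holds to machine rounding. The
  reaction coefficient enters only through the factor `(1+μ₀g₀)`; the unit
  reaction case reduces to the classical printed coefficient block.
* Forcing is sampled pointwise on the full nodal grid at `t_{k+1}` and then
  compact-averaged; averages at nodes adjacent to the boundary use the known
  Dirichlet values of each stored level.
* The full history `w⁰..w^k` is stored (O(n·m²) memory): with n ≤ a few
  hundred and m ≤ a few tens this is negligible, and it keeps the memory
  term exact rather than truncated.

## Per-step solvers

The step system is strictly diagonally dominant whenever `a₁, a₂ ≥ 0`
(which holds in the entire benchmark range; it can fail only when h is
large relative to g₀). Two solvers are provided:

* **Lexicographic point Gauss–Seidel** (default), warm-started from the
  previous time level, stopping when the max-norm of successive-iterate
  differences reaches the tolerance ω (default 1e-10). Within a sweep, the
  in-row dependence is the first-order recurrence
  `a₀ w_{i,j} − a₁ w_{i,j−1} = known`, which is evaluated with a linear
  filter along each row — the iterates are those of the scalar
  lexicographic loop, computed row-vectorized. Non-convergence within
  `max_iterations` raises a flagged failure carrying the last residual and
  the step index.
* **Sparse direct** (`splu` on the Kronecker-assembled 9-point matrix,
  factorized once per marched run), used as oracle and fallback.

The two agree to ≤ 1e-10 in max norm; the tests additionally compare the
whole march against a dense, loop-written brute-force assembly of the
stencil that shares no code with the production path.

## Error metrics and order estimators

`M_E` / `A_E` are the maximum / arithmetic-mean absolute errors over
interior nodes at t = T. (The mean is one of several possible "average
error" conventions; it is the one consistent with the benchmark tables'
A_E ≤ M_E.) Orders are estimated as printed log₂ ratios:

* temporal: `ℑ₁ = log₂(ME(2τ,h)/ME(τ,h))` at fixed h (the study driver
  fills the order column only between runs that actually halve τ);
* spatial: `ℑ₂ = log₂(ME(16τ,2h)/ME(τ,h))` — τ is refined 16-fold per
  spatial halving so that, when the h⁴ term dominates, the estimate ≈ 4.

### What the estimators can and cannot show

The scheme's error model is `C_t τ^(2−γ) + C_s h⁴`, and both constants are
problem-dependent. Two regimes limit the estimators, and both are visible
in the benchmark problems themselves:

* When the spatial constant is very small (the `t² e^(x+y)` benchmark: its
  interior error is strongly constrained by the inhomogeneous boundary
  data), the coupled ℑ₂ refinement measures the *temporal* contraction
  `16^(2−γ)`, i.e. ℑ₂ ≈ 4(2−γ): ≈ 7.4 at γ=0.1, ≈ 5.9 at γ=0.5, decaying
  to ≈ 4.4 at γ=0.9. Order estimates above 5 for that benchmark at small γ
  are therefore expected behavior, not superconvergence.
* When the temporal constant is small (small γ — the L1 error of a `t²`
  profile carries a factor that vanishes as γ → 0), the h⁴ floor at fixed
  h = 1/8 (~9e-5 for the sine benchmark) dominates the τ-ladder, and ℑ₁
  estimates collapse below 2−γ as τ is refined.

The manufactured-solution generator separates the regimes cleanly: per-axis
cubic spatial factors are reproduced exactly in space (machine-precision
error for a linear-in-time profile, which the L1 weights also reproduce
exactly), leaving a pure temporal error whose ℑ₁ tracks 2−γ within ±0.25
over τ = 1/10..1/80 for mid-range γ.

## Stability scan

The first-step von Neumann growth factor of the scheme is

    F(φ₁h, φ₂h) = (h²/36) (25 + 5m₀ + m₁) / (a₀ − 2a₁m₀ − 4a₂m₁),
    m₀ = cos φ₁h + cos φ₂h,  m₁ = cos φ₁h · cos φ₂h.

The scan evaluates F on a uniform grid over [0,π]² (default 129² modes) and
reports max |F| and its argmax. Whenever a₁, a₂ > 0 the maximum sits at the
zero mode and equals `1/(1+μ₀g₀) < 1`. Only the first-step (no-history)
factor is scanned; the history-coupled recursion is exercised empirically
through full solves, since a usable closed-form bound for it is not
available. A vanishing denominator raises a singularity error echoing the
parameters; it cannot occur in the diagonally dominant regime.

## Manufactured problems

`make_manufactured` accepts a separable target `w = t^p X(x) Y(y)` with
p > 0 and X, Y from the families {sin(c·x), exp(c·x), polynomial}; the
forcing

    g = Γ(p+1)/Γ(p+1−γ) t^(p−γ) X Y − t^p (X''Y + XY'') + μ₀ t^p X Y

is assembled in closed form (no symbolic runtime dependency), and the
initial/boundary data are restrictions of the exact solution, so every
generated problem has zero PDE residual by construction — the tests verify
this independently with quadrature of the Caputo integral and
finite-difference Laplacians. Both built-in benchmarks are instances of the
generator. What the generator does *not* emulate: nonseparable solutions,
solutions with weak temporal regularity at t = 0 (the `t^p` profile with
p ≥ 1 is smoother than the worst case covered by L1 theory), and
non-rectangular domains — so passing tests certify correctness of the
scheme's implementation, not sharpness of the L1 error bound for rough
data.

## Numerical and design choices

* Default solver tolerance ω = 1e-10 (max-norm successive difference),
  max 10,000 sweeps; warm start from the previous level. Observed sweep
  counts at the benchmark settings (~40–50) are consistent with the
  reference iteration counts (30–65), whose exact semantics is not defined
  there; the run report records per-step, max-per-step, and total counts.
* Degenerate inputs: m < 2 (no interior nodes), non-square spacing,
  non-finite right-hand sides, γ outside (0,1), p ≤ 0, and empty study
  configurations are rejected with explicit errors before any computation.
* Problem sizes in the shipped experiments are the benchmark tables' own
  (m = n ≤ 30; τ-ladders to 1/80 at h = 1/8; 129² stability modes): every
  study runs in seconds on one core.
* CSV output at 6 significant digits by default, `--full-precision`
  switches to %.17g (bit round-trip); re-reading a full-precision table and
  re-deriving the order column reproduces it exactly (use exact float
  parsing when re-reading).

## Known limitations

* The published reference tables contain internal inconsistencies (a 10×
  discrepancy for one setting between two tables, one non-monotone row, and
  one order entry inconsistent with its own error columns); where that
  happens this implementation reproduces the self-consistent variant, as
  cross-checked by the independent dense oracle.
* Gauss–Seidel convergence is guaranteed only in the diagonally dominant
  regime a₁, a₂ ≥ 0; outside it (coarse h with tiny g₀) the direct solver
  should be selected.
* Single uniform square grid, Dirichlet data only, no short-memory
  acceleration; runtime grows as O(n²m²) from the exact memory term.
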