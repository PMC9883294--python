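# fcable

A compact fourth-order implicit finite-difference solver for the
two-dimensional time-fractional cable equation

```
D_t^γ w(x,y,t) = ∂²w/∂x² + ∂²w/∂y² − μ₀ w + g(x,y,t),   0 < γ < 1,
```

on a rectangle with Dirichlet boundary data, where `D_t^γ` is the Caputo
fractional derivative of order γ. The fractional cable equation models
anomalous (subdiffusive) ion transport along neuronal dendrites, where
trapping in spines makes the mean-squared displacement grow sublinearly in
time; γ interpolates between strong memory (γ → 0) and classical cable
dynamics (γ → 1).

The package is aimed at numerical analysts and computational neuroscientists
who want a verified reference implementation of the scheme, its
convergence-order experiments, and its von Neumann stability scan.

## Method

* **Time.** The Caputo derivative is discretized with the L1 formula on a
  uniform grid `τ = T/n`, with weights `b_r = (r+1)^(1−γ) − r^(1−γ)` and
  truncation `O(τ^(2−γ))`. The full solution history enters each step (the
  memory term is evaluated exactly, no truncation).
* **Space.** Second derivatives use the compact (Padé) operator
  `(1 + δ²/12)^(−1) δ²/h²`, fourth-order accurate on a 9-point stencil with
  averaging weights 25/36 (center), 5/72 (edges), 1/144 (corners).
* **Step system.** Each time level solves
  `a₀w − a₁(edges) − a₂(corners) = rhs` with
  `g₀ = τ^γ Γ(2−γ)`, `a₀ = (10/3)g₀ + (25/36)h²(1+μ₀g₀)`,
  `a₁ = (2/3)g₀ − (5/72)h²(1+μ₀g₀)`, `a₂ = g₀/6 − (1/144)h²(1+μ₀g₀)`,
  by lexicographic point Gauss–Seidel (the system is strictly diagonally
  dominant: `a₀ − 4a₁ − 4a₂ = h²(1+μ₀g₀) > 0`) or a sparse direct solve.
* **Verification.** Built-in manufactured benchmarks
  (`example1`: `w = t² sin(πx) sin(πy)`, `example2`: `w = t² e^(x+y)`), a
  generator for arbitrary separable exact solutions `t^p·X(x)·Y(y)` with
  closed-form forcing, empirical order estimators
  `ℑ₁ = log₂(ME(2τ,h)/ME(τ,h))` and `ℑ₂ = log₂(ME(16τ,2h)/ME(τ,h))`, and a
  scan of the first-step Fourier amplification factor
  `F = (h²/36)(25+5m₀+m₁)/(a₀−2a₁m₀−4a₂m₁)` over mode angles `[0,π]²`.

## Worked example

Solve the first benchmark at γ = 0.1 on a 5×5 grid with 5 time steps:

```sh
fcable solve --problem example1 --gamma 0.1 --m 5 --n 5 --out run1
```

prints

```
solve: example1 gamma=0.1 m=5 n=5 h=0.2 tau=0.2 method=point_iterative
M_E=6.916487e-04 A_E=4.526899e-04 iterations(max per step)=41
artifacts written to run1
```

`M_E` and `A_E` are the maximum and mean absolute nodal errors against the
exact solution at the final time t = 1 over interior nodes — the error of
the scheme itself, at fourth order in h and order 2−γ in τ. A temporal
refinement study at fixed h = 1/8,

```sh
fcable study --problem example2 --gamma 0.5 --mode temporal \
       --grids "8;10,20,40,80" --method direct --out run2
```

tabulates `M_E` per step count with the `ℑ₁` order column
(≈ 1.47, 1.48, 1.49 — tracking the theoretical 2 − γ = 1.5), and

```sh
fcable stability --gammas 0.1,0.5,0.9 --taus 0.2,0.1 --hs 0.2,0.1 --out run3
```

reports `max |F| = 1/(1+g₀) < 1` attained at the zero mode for every
combination, the empirical signature of unconditional first-step stability.

The same machinery is available as a library:

```python
from fcable import example1, GridSpec, march, error_report
problem = example1(0.1)
history, report = march(problem, GridSpec.for_problem(problem, m=5, n=5))
print(error_report(history, problem))   # M_E=6.916e-04, A_E=4.527e-04
```

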