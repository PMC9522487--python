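# Methods

## Models and assumptions

### Hawk–Dove replicator layer

Two replicating cell types contend: cancerous leukocytes (c.leu, the
Hawks) and healthy leukocytes (leu, the Doves).  Frequencies
`x = (x₁, x₂)` live on the simplex, with `x₁ = P_L/p` derived from absolute
counts (`p = P_L + P_I` total cells).  The general n-strategy replicator
equation `ẋᵢ = xᵢ((Ax)ᵢ − xᵀAx)` is implemented for arbitrary payoff
matrices; the normalized two-strategy contest places zeros on the diagonal
(same-type encounters neutral) and `(−a, b)` off-diagonal with `a, b > 0`.

The one-dimensional flow used for fixed-point and basin analysis is

    x₁′ = (a·x₁ − b·(1−x₁))·x₁·(1−x₁).

This is deliberately **not** the replicator flow of the anti-diagonal
matrix above — it is algebraically identical to the replicator dynamics of
the diagonal game `diag(a, b)` (a coordination structure), which is the
form the fixed-point list and phase planes are built on.  Its stationary
points are `0`, `1` (both attracting: derivative `−b` and `−a`
respectively) and the interior point `x* = b/(a+b)` (repelling, derivative
`ab/(a+b) > 0`), so `x*` is the separatrix: the basin of the all-leu state
`x₁ = 0` has Lebesgue size `b/(a+b)` and exceeds ½ exactly when `b > a`.
Both layers are exposed so users can integrate either form; the module
docstring spells out the distinction.

A note on a documented inconsistency: the reported analysis asserts that the
interior mixed point and both pure states are simultaneously
asymptotically stable, which is impossible in a one-dimensional flow.  The
implementation reports the derivative-sign truth (interior point
unstable).

### Leslie–Gower model

Prey `i` (leu) and predator `l` (c.leu), time in days, densities in units
of 10⁹ cells/liter (so the clinical leukocyte range 30–200×10⁹ cells/liter
maps to 30–200 model units; this convention matches the presets, whose
equilibria are of order 1–6, and is configurable):

    di/dt = (r₁ − c₁·l − b·i)·i,     dl/dt = (r₂ − c₂·l/i)·l.

`r₁, r₂` are intrinsic growth rates (1/day); `c₁` the c.leu→leu conversion
coefficient; `b` the predation effectiveness; `c₂` the Gower coefficient
penalizing predator growth by the predator-to-prey ratio.  The Gower term
diverges as `i → 0` with `l > 0`; the implementation raises a
`GowerSingularityError` (guard ε = 10⁻¹²) with the offending time attached
rather than silently clamping.

Closed forms implemented and tested:

* equilibrium `E = (r₁c₂/D, r₁r₂/D)`, `D = b·c₂ + c₁·r₂`;
* Jacobian `J(E) = [[−r₁bc₂/D, −r₁c₁c₂/D], [r₂²/c₂, −r₂]]`, whose
  determinant is identically `r₁r₂` (verified numerically on 1000 random
  parameter sets) and whose trace `−(r₁bc₂ + r₂D)/D` is negative for
  positive rates, so `E` is always locally attracting;
* characteristic polynomial `λ² + ((r₁bc₂ + r₂D)/D)·λ + r₁r₂`;
* node/focus criterion `(√r₁ − √r₂)² ≥ r₁c₁r₂/D`, which is algebraically
  the discriminant sign test (property-tested on the same random sets).

Two reporting conventions require care:

* **Truncation.** Reported equilibria are truncated (not rounded) to two
  decimals — `4.9999… → 4.99`.  `truncate()` implements this; raw values
  are always available at full precision.
* **`reported_trace_quantity`.** The reported eigenvalue sums for the
  acute (0.638) and chronic (0.3) stages do not equal the Jacobian trace
  (−0.862 and −0.9); they equal `(r₂D − r₁bc₂)/D`.  The package computes
  and labels this quantity separately and keeps the true trace in every
  report.  Relatedly, the acute/chronic equilibria are sometimes described
  as unstable, but the closed forms force trace < 0 and det = r₁r₂ > 0;
  the package reports the mathematically forced classification (acute:
  stable focus; chronic: stable focus; early: stable node).

The fitness layer `H₁ = r₁(k−i)/k − b·l`, `H₂ = r₂(1 − l/(c·b·i))` and the
difference equation `i_{t+1} = i(1+H₁)`, `l_{t+1} = l(1+H₂)` are isolated
in `leslie_fitness` / `leslie_map_step` so the readings can be swapped;
they affect neither the equilibrium nor the stability results.  The map
also accepts the flow's own per-capita forms, under which `E` is a fixed
point of the map.  `k` (prey carrying capacity, default 100 density units)
and `c` (nutritional value, default 1) are not part of the stage presets
and default as stated; both are overridable.

### Two-coalition transplant game

The three-player interaction (HSC graft, leu, c.leu) is reduced to two
coalition games — favourable (HSC, leu) vs. c.leu, and leu vs. (HSC,
c.leu) — each a normalized 2×2 contest with constants `a₁, a₂` and
`b₁, b₂`; `m = a₁+a₂`, `n = b₁+b₂`.  The coupled planar replicator system
has the four corners as rest points and the mixed point
`(x₁*, x₂*) = (b₁/n, a₁/m)` when both ratios lie in (0, 1).  (An earlier
algebraic form swaps the two coordinates; the implemented form is the one
consistent with the differential equations.)  The Jacobian at the mixed
point has zero diagonal and off-diagonal entries `−x₁*(1−x₁*)m`,
`−x₂*(1−x₂*)n`, hence eigenvalues `±√(J₁₂J₂₁)`: saddle for a positive
product (`a₁`, `b₁` same sign), linear center for a negative one,
degenerate within 10⁻¹² of zero.  `classify_interior` evaluates the
Jacobian at the *formal* mixed point whenever `m, n ≠ 0`, even if it lies
outside the open square (then it is a virtual equilibrium); the
fixed-point enumeration applies the strict interior check.

The two post-chemotherapy payoff matrices

    [[0, 5×10⁸], [9.2247×10⁶, 0]]     and     [[0, 1009224700], [0.431001, 0]]

are shipped verbatim as named fixtures.  Their entries are plausibly
additive in the clinical counts (9.2247×10⁶ = 9.19×10⁶ + 3.47×10⁴;
1009224700 = 2·5×10⁸ + 9.2247×10⁶; 0.431001 ≈ 0.431 + 1.42×10⁻⁶), but no
construction rule accompanies the reported matrices, so none is enforced
here.  Both have negative determinant (−4.61235×10¹⁵ and −434976854.9) and
are saddles.  A
reported companion value `τ² − 4·det = 83424.39498` for the second matrix
is irreproducible under its own formula (τ = 0 gives ≈1.74×10⁹; the
printed number equals `4·√|det|`) and is therefore documented but not
reproduced.  The NK-cell count 2.08×10⁻⁷ is dimensionally implausible (a
fractional cell) and is stored verbatim, excluded from the coalition
frequency pools.

## Numerical choices

* **Integration.** Default adaptive RK45 (scipy `solve_ivp`) with
  `abs_tol = rel_tol = 10⁻⁹`; fixed-step classical RK4 (`dt = 0.01` day)
  for bitwise-reproducible runs.  Replicator states are clipped to [0, 1]
  and renormalized to the simplex when drift exceeds 10⁻¹².  The solver
  choice is the package's own; only trajectories, not solver details, are
  compared against anything.
* **Basin mapping.** The grid of initial conditions (inclusive endpoints)
  is advanced as one batch by fixed-step RK4, default `dt = 0.05` day to
  horizon 500 days; a point is assigned to an attractor within capture
  radius 10⁻², else labeled "none" (never guessed).  Grid points sitting
  exactly on a separatrix stay there and come out "none".
* **Tolerances.** Fixed-point residual 10⁻⁹; derivative/eigenvalue
  degeneracy 10⁻¹²; sign tests in the trace–determinant classification use
  tol = 10⁻¹² and report "degenerate" at boundaries.  Eigenvalues are
  ordered by real part then imaginary part so reports are deterministic.
* **Map overshoot.** Negative densities produced by the difference
  equation are floored at zero (extinction absorbing); the ODE path raises
  on the Gower singularity instead.

## Synthetic scenarios

`scenarios.random_scenario(stage, seed)` jitters each stage rate by an
independent Uniform(0.9, 1.1) factor, draws the initial leu density
Uniform(30, 200) model units (the recorded clinical variance band — noted
as far above physiologic leukocyte counts, and kept verbatim), the initial
c.leu density as a Uniform(0.1, 1.0) fraction of it, and a horizon of
40–80 whole days (the stated observation window).  The ±10% jitter law and
the c.leu fraction are this package's own choices — modest rate
uncertainty around the presets and a diagnosed-disease burden below the
healthy count — and are exposed as module constants.  One named
`numpy` generator per scenario, seeded explicitly; no global RNG state.

What the generator does *not* emulate: measurement noise, treatment
pharmacokinetics, patient-to-patient parameter correlation, or any
longitudinal sampling irregularity.  Passing tests therefore demonstrate
internal consistency of the models and their analysis at clinically
plausible magnitudes, not fit to patient data.

## Problem sizes

Property suites use 1000 random parameter sets for the closed-form
identities, a 10×10 grid of initial conditions for the global-attraction
check (horizon 500 days), a 1001-point grid for 1-D basin fractions, and
200×200 grids for fixed-point completeness scans — sizes chosen so the
whole suite runs on a laptop in well under a minute while keeping the
statistical checks meaningful.

## Known limitations

* No parameter estimation or fitting to patient data; presets are taken as
  given.
* No bifurcation continuation, delay, or stochastic model variants.
* The global-stability claim for the Leslie equilibrium is checked
  numerically on a grid, not proved (no Lyapunov construction).
* The three-player transplant game is analyzed only through the two
  coalition reductions; no cooperative solution concepts (core, Shapley
  value) and no graft-versus-host pathophysiology.
* Chemotherapy dynamics are out of scope; only post-chemotherapy cell
  counts enter, as initial conditions.
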