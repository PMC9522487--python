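# leukodyn

Dynamical models of leukemia as a contest between healthy leukocytes
(*leu*) and cancerous leukocytes (*c.leu*), for researchers in mathematical
oncology and evolutionary game theory who want reproducible equilibrium and
stability analyses rather than one-off algebra.

Three planar models are implemented and cross-compared:

1. **Hawk–Dove replicator dynamics** (`leukodyn.game_dynamics`).
   Strategy frequencies evolve on the simplex by
   `ẋᵢ = xᵢ((Ax)ᵢ − xᵀAx)` for a payoff matrix `A`; the normalized
   two-strategy contest uses `A = [[0, −a], [b, 0]]` (zero diagonal —
   same-type encounters are neutral).  The companion one-dimensional flow
   `x₁′ = (a·x₁ − b·x₂)·x₁·x₂` with `x₂ = 1 − x₁` has the three stationary
   points `0`, `1` and the interior (dimorphic) point `x* = b/(a+b)`, which
   separates the basins of the two monomorphic states.

2. **Leslie–Gower predator–prey model** (`leukodyn.leslie`), with leu as
   prey (density `i`) and c.leu as predator (density `l`):

       di/dt = (r₁ − c₁·l − b·i)·i
       dl/dt = (r₂ − c₂·l/i)·l

   The Gower term `c₂·l/i` ties the predator's carrying capacity to prey
   abundance.  The coexistence equilibrium has the closed form
   `E = (r₁c₂/D, r₁r₂/D)` with `D = b·c₂ + c₁·r₂`; the Jacobian at `E` has
   determinant identically `r₁r₂` and negative trace, and `E` is a node
   when `(√r₁ − √r₂)² ≥ r₁c₁r₂/D`, a focus otherwise (exactly the
   discriminant sign).  Three disease-stage parameter presets are shipped:
   early prognosis, acute, chronic.

3. **Two-coalition transplant game** (`leukodyn.hsc_game`).  After a
   hematopoietic stem-cell (HSC) transplant, the graft either pools with
   leu against c.leu or — the graft-versus-host-like outcome — with c.leu
   against leu.  The coupled replicator system on the unit square,

       x₁′ = x₁(1−x₁)(a₁ − m·x₂),   x₂′ = x₂(1−x₂)(b₁ − n·x₁),

   has the four corners as rest points plus the mixed point
   `(b₁/n, a₁/m)`; its zero-diagonal Jacobian has eigenvalues
   `±√(J₁₂J₂₁)` — a saddle when `a₁` and `b₁` share a sign, a linear
   center otherwise.  The two post-chemotherapy payoff-matrix fixtures are
   included together with the clinical cell counts that motivate them.

Shared machinery: 2×2 trace–determinant classification
(`leukodyn.linear_stability`), adaptive RK45 / fixed-step RK4 integration,
discrete-map iteration and basin-of-attraction mapping (`leukodyn.engine`),
seeded scenario generation (`leukodyn.scenarios`), and a `leukodyn` CLI
with CSV/JSON reports and re-runnable run manifests.

## Worked example

Classify the early-prognosis stage:

```
$ leukodyn classify --model leslie --stage early
{
  "criterion_label": "node",
  "criterion_lhs": 0.00455488498966777,
  "criterion_rhs": 8.519854821673837e-06,
  "det": 0.29999999999999993,
  ...
  "label": "stable node",
  "point": [4.999914801451783, 5.999897761742139],
  "reported_trace_quantity": 0.1000085198548217,
  "trace": -1.0999914801451782
}
```

The coexistence equilibrium sits at `E ≈ (5.00, 6.00)` (reported truncated
to two decimals as `(4.99, 5.99)`): both cell populations persist.  The
node criterion holds (`4.55×10⁻³ ≥ 8.52×10⁻⁶`), the determinant equals
`r₁r₂ = 0.3`, and both eigenvalues are real and negative — the equilibrium
is a stable node, so nearby cell-count perturbations decay monotonically.
`reported_trace_quantity` is the separate eigenvalue-sum reporting
convention `(r₂D − r₁bc₂)/D` kept alongside the true (negative) trace; see
`docs/methods.md`.

The same analysis in Python:

```python
from leukodyn import table4_scenario, coexistence_equilibrium, leslie_stability_report

params = table4_scenario("acute")
print(coexistence_equilibrium(params).as_tuple())   # (0.448, 0.84)
print(leslie_stability_report(params).label)        # stable focus
```

Simulate and map basins from the shell:

```
leukodyn simulate --model leslie --stage early --x0 1,1 --t-end 100 --out traj.csv
leukodyn basin --model hawkdove --a 1 --b 3 --resolution 1000 --out basin.csv
```

The basin summary (`basin.csv.fractions.json`) shows the all-leu state
capturing a fraction `b/(a+b) = 0.75` of initial conditions — the
separatrix is the interior point.

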