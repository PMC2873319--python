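# Methods

## Model class and simulator

A `NetworkModel` is a list of species, a list of reactions drawn from a fixed
rate-law menu, a set of clamped inputs, and one output species. The ODE
right-hand side is assembled mechanically from the reaction records — each
reaction subtracts its rate from the substrate and adds it to the product, and
modifiers act catalytically — so every system studied here, from the two-cycle
serial cascade to a transcribed pathway model, runs through one simulator with
no model-specific code.

Rate laws (concentrations in arbitrary units, time in arbitrary units — no
unit conversions are ever applied):

| kind | rate |
|---|---|
| `mm_activation`, `mm_deactivation` | `vmax · [modifier] · [S] / (km + [S])` (modifier absent ⇒ 1) |
| `mass_action` | `k · [S] · [modifier or 1]` |
| `zeroth_synthesis` | `k` |
| `first_degradation` | `k · [S]` |

Activation/deactivation cycles declare a conserved pool
(`pool_partner`/`pool_total`); conservation is emergent from the
stoichiometry and is asserted along every trajectory to within `10·atol`.

Integration uses LSODA (stiff-capable) with defaults `rtol = 1e-8`,
`atol = 1e-10`. In the default steady-state readout mode, integration
proceeds in geometrically growing time spans until the max-norm of the
free-species derivatives falls below `steady_tolerance` (default `1e-9`
concentration per time unit — the underlying analysis is a steady-state
statement but states no numerical criterion, so this is a package choice),
capped at `t_end` (default `1e4`). The endpoint is then Newton-polished on
the steady-state equations in pool-reduced coordinates (each conserved pair
contributes one unknown; the partner is eliminated as `total − x`). The
reduction matters: conserved cycles make equilibria non-isolated in the full
coordinates, so the unreduced Jacobian is singular. The polish candidate is
accepted on evidence — residual not increased, no concentration below
`−100·atol`, displacement below `1e-3` relative — rather than on the
solver's success flag, which can report failure when started already at the
root. The polish is what makes the synergy indices well-conditioned: `DS` is
a second difference of outputs, and raw integrator endpoints carry
`O(rtol·y)` noise that a second difference amplifies by `1/(4hh′)`.

Concentrations that dip below zero by integrator roundoff are clipped to
zero at readout only; a drop below `−100·atol` raises instead, since that
indicates a defective model rather than roundoff.

## Synergy indices

All scoring happens in dimensionless scale space: an inhibitor dose is a
positive factor multiplying one kinetic parameter (velocity constants are
scaled below 1; Michaelis constants above 1, since a larger Km weakens a
reaction). The survival ratio is `r(a,b) = output(a,b) / output(1,1)`.

Two algebraic forms of the Synergism Assessment Factor are provided, the
difference form `S = r(a,b) − r(a,1)·r(1,b)` (default, the fractional-product
comparison with `S = 0` as the exact critical point) and the log form
`S = ln r(a,b) − ln[r(a,1)·r(1,b)]`. Both vanish identically on the
single-agent boundaries, vanish everywhere for multiplicatively separable
(Bliss-independent) surfaces, and admit the same integral relation; the form
is recorded in every result and in all CLI logs so numbers are auditable.
The additive band around `S = 0` defaults to `±1e-6`.

`DS = ∂²S/∂a∂b` is estimated by central differences with two independent
stencils that must agree on smooth surfaces (a built-in cross-check):
`four_point_s` differences `S` itself at the four stencil corners;
`two_term_r` differences the survival ratio (mixed partial of `r` minus the
product of the two single-agent derivatives for the difference form; mixed
partial of `ln r` for the log form, whose separable terms drop out). When no
explicit step is given, the step starts at `1e-3·scale` per axis and is
halved until two successive estimates agree to `1e-3` relative; if halving
makes successive estimates diverge, the step has hit the evaluation noise
floor and the last consistent estimate is returned flagged `unreliable`.

`s_from_ds_oracle` recovers `S(a,b)` as the composite-trapezoid double
integral of `DS` over `[a,1] × [b,1]` on an `(mesh+1)²` node grid, with the
stencil step tied to half the node spacing so neighboring stencils share
cached surface evaluations. Convergence is second-order in the spacing; at
mesh 32 the relative error against direct evaluation is ~3e-4 on the serial
motif. This is the operational content of the sign rule: `DS < 0` over a
dose rectangle forces `S < 0` at its corner.

## Built-in motifs and their defaults

Serial: a clamped input A drives a B⇄B-P cycle; B-P drives C⇄C-P; output
C-P. Parallel: two independent upstream cycles drive the C cycle through two
additive activation reactions (logic OR — either branch alone sustains the
output). Negative feedback: the serial motif plus a C-P-mediated
deactivation of B-P with Michaelis constant Km5.

Default parameters — totals 1, input 1, activation Vmax 1 / Km 0.5,
deactivation Vmax 0.5 / Km 0.5, feedback Vmax 1 / Km5 0.5 — are package
defaults, not published values (the source systems defer their
parameterization to earlier work). They place each cycle at an interior,
responsive steady state (serial: B-P ≈ 0.781, C-P ≈ 0.701, cross-checked
against an algebraic fixed-point solve). Every structural claim the tests
make against the literature is a sign or ordering property (negative S
curves, opposite/same sign transfer, parallel magnitude exceeding serial,
feedback lowering output) robust to this choice; printed magnitudes are not
comparable to published figures and are not asserted.

The fixture generator draws motif parameters log-uniformly from declared
ranges (defaults for tests: totals and input 0.5–2, activation Vmax 0.5–2,
Km 0.2–1, deactivation Vmax 0.25–1, Km 0.2–1), deterministically in the
seed. What these fixtures emulate is the space of mid-saturation
activation/deactivation cascades; they do not emulate oscillatory or
bistable regimes, zero-order ultrasensitive limits, synthesis/degradation
turnover, or transient (non-steady) readouts — passing tests therefore
certify the sign-transfer and feedback rules for monotone steady-state
cascades, not for arbitrary kinetics.

## Simplification and sign transfer

`simplify_clamp` computes the full model's baseline steady state, clamps
each mapped intermediate at its baseline level, drops every reaction that
produces or consumes a clamped species (the upstream cycle), prunes species
left unreferenced, and exposes a response surface whose virtual inhibitor
scales multiply the clamp levels. Identity mappings (a parameter already
inside the retained subsystem) keep their original target. The subsystem
must reproduce the full model's baseline output to `1e-6` relative, or the
simplification is rejected.

`Φ(a)` is the steady-state level of the intermediate with the rest of the
system present and the other inhibitor at baseline — the two channels are
treated independently. Its derivative sign comes from a central difference
at `scale·(1 ± 1e-3)`. For the serial motif the second mapping is the
identity (the downstream inhibitor's parameter lies inside the retained
subsystem), so the serial sign flip comes entirely from `Φ′ < 0` under a
Km-increase; both parallel mappings are clamped intermediates with negative
derivatives, giving same-sign transfer.

`corollary_check` evaluates `DS` (full) and `DS′` (simplified, at the
corresponding virtual scales) at every grid point with fixed relative steps
`1e-3·scale`, excludes points where either magnitude falls below `1e-6`
(indeterminate: beneath the estimate's resolution), and reports the fraction
obeying the declared relation. It also verifies the quantitative
factorization `DS = Φ′·Ψ′·DS′` (worst case ~2e-4 relative across 20-fixture
families) and reconstructs the full-system S surface from the simplified one
via `S(a,b) = S′(Φ(a)/x₀, Ψ(b)/y₀)`, an identity for clamped cascades,
which the grids confirm to ~1e-11 relative.

## Feedback analysis

`feedback_check` requires the feedback model to equal the base model plus
the declared feedback reaction(s). The upstream state `x` is chosen as the
species touched by the feedback reaction on which the output's rate actually
depends (largest sampled `|∂(dy/dt)/∂x|`). The loop sign `g` is the feedback
reactions' net stoichiometric contribution to `dx/dt` sampled at ≥ 32 points
along the trajectory; the downstream sensitivity `∂f/∂x` is a finite
difference of the output's rate in `x` at the same samples. Any sign change
across samples yields "mixed" and fails the condition (conservative). The
preservation condition is (`g` negative and `∂f/∂x` positive) or (`g`
positive and `∂f/∂x` negative) — classification is always by the evaluated
sign of `g`, not by a declared label. Output domination
`y_fb(t) ≤ y_base(t)` is then verified pointwise, never assumed: both
models are re-integrated at the same ~300 shared time points (log-spaced to
resolve the transient) with tolerances tightened to `rtol 1e-10 / atol
1e-12` so solver error sits well below the `10·atol` violation band.

## NF-κB case study support

The TNF-α-induced NF-κB pathway (output: ICAM-1 expression) is supported as
data, not code: the package defines the `synmotif-model/1` schema, the
loader, and the drug-to-reaction target mapping (Geldanamycin → RIP1 binding
with the TNFR1 complex, simplified to IKKK-P activating IKK-β; PS-1145 →
IKK-β-P phosphorylating IκB; Aldehyde → IκB degradation; velocity-constant
scales swept from 0.9 down to 1e-4). The pathway's kinetic model itself —
reactions, rate constants, initial concentrations — must be transcribed by
the user from its published supplementary description into
`models/nfkb_tnfa.json`; the corresponding acceptance test fails with an
explanatory message until that document exists. A notable structural
expectation once it does: for the PS-1145 + Aldehyde pair both targets lie
inside the simplified subsystem, so the simplified and full-system S values
coincide exactly.

## Numerical choices and limitations

- Dose grids are logarithmic by default (`make_grid`: 0.9 down to 1e-4),
  matching screens that span several orders of magnitude in scale space;
  Km-increase scans pass ascending ladders explicitly.
- Scan grid points whose integration fails are recorded as missing (NaN) and
  excluded from verdict counts instead of aborting the scan.
- Problem sizes used by the acceptance script: 50 surfaces for the boundary
  suite, mesh 32 for the integral recovery, 20 seeded fixtures per motif kind
  on 8×8 grids for the sign-transfer families, 8-point equal-dose ladders.
  These sizes give each property many independent chances to fail while one
  fixture family still completes in about a minute on one core.
- Dose→scale calibration (IC50-style curves) is out of scope; all screens
  are specified directly in scale space.
- The sign-transfer rules are established here numerically, at steady state,
  for monotone cascades; oscillatory systems are detected (steady state not
  reached) and directed to endpoint mode, where the simplification rules are
  not claimed.
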