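# synmotif

Synergy screening of inhibitor pairs on Michaelis–Menten reaction-network
models, built around an extended Bliss independence criterion.

## The problem

Deciding whether two inhibitors act synergistically on a signaling pathway
normally requires measuring (or simulating) the full dose–response surface of
the pair. `synmotif` implements a structural shortcut for kinetic models:
it scores a dose pair with the **Synergism Assessment Factor**

```
S(a, b) = r(a, b) − r(a, b₀) · r(a₀, b)
```

where `r` is the survival ratio — the output concentration under perturbed
parameters divided by the untreated output — and `a`, `b` are dimensionless
scale factors applied to the two targeted kinetic parameters (`a₀ = b₀ = 1`
is the untreated baseline). `S < 0` marks synergism (the pair suppresses the
output below the Bliss product of the single-agent effects), `S > 0`
antagonism, `S = 0` additivity. A logarithmic form
`ln r(a,b) − ln[r(a,b₀) r(a₀,b)]` is available as an option; every result
records which form produced it.

The derivative index

```
DS(a, b) = ∂²S / ∂a ∂b
```

connects local sensitivity to global verdicts: because `S` vanishes
identically on the single-agent boundaries, the double integral of `DS` over
the dose rectangle `[a,1] × [b,1]` equals `S(a,b)` — so `DS < 0` throughout a
dose range guarantees synergism over that range.

Two structural rules let large models be screened on small subsystems:

* **Simplification.** When an inhibitor acts on an upstream process whose
  steady-state product level `x = Φ(a)` carries the effect downstream, the
  full-system `DS` factors as `Φ′(a)·Ψ′(b)·DS′`, with `DS′` computed on a
  simplified subsystem in which the intermediate is a clamped input scanned
  by a virtual inhibitor. For a serial cascade the sign relation is
  `sign(DS) = −sign(DS′)`; for parallel branches converging on one target,
  `sign(DS) = +sign(DS′)`.
* **Feedback preservation.** Adding a feedback loop whose contribution to the
  upstream state is negative while the downstream rate increases in that
  state (or the mirrored positive case) cannot weaken the combination
  effect; the package verifies the resulting output domination pointwise on
  simulated trajectories rather than assuming it.

Models are declarative: species (with conserved activation/deactivation
cycles), reactions from a small rate-law menu, clamped inputs, and an output
species, serialized as `synmotif-model/1` JSON documents. Built-in motifs
(`serial`, `parallel`, `negative_feedback`) and a seeded random-fixture
generator cover the canonical pathway structures; the same machinery loads
user-transcribed pathway models such as the TNF-α-induced NF-κB cascade
(see `docs/methods.md`).

## Worked example

Score equal doses of two inhibitors on the serial cascade A → B → C, each
raising the Michaelis constant of one activation stage 2-fold:

```python
from synmotif import (serial_motif, Perturbation, ModelSurface, synergy_s,
                      ds_estimate, SimulationSettings)

surface = ModelSurface(
    serial_motif(),
    Perturbation("activation_B", "km"),
    Perturbation("activation_C", "km"),
    SimulationSettings(),
)
score = synergy_s(surface, 2.0, 2.0)
print(f"S       = {score.s_value:.4f}  ({score.classification})")
print(f"r(a,b)  = {score.r_ab:.4f}")
print(f"r(a,1)  = {score.r_a:.4f}")
print(f"r(1,b)  = {score.r_b:.4f}")
print(f"DS      = {ds_estimate(surface, (2.0, 2.0)).ds_value:.5f}")
```

prints

```
S       = -0.0391  (synergism)
r(a,b)  = 0.5951
r(a,1)  = 0.8601
r(1,b)  = 0.7373
DS      = -0.00436
```

Each drug alone leaves 86% and 74% of the output; independent action would
predict 0.8601 × 0.7373 = 63% remaining, but the pair leaves only 59.5% —
the negative `S` quantifies that excess inhibition, and the negative `DS`
shows the synergy deepening locally with dose.

The same operations are available from the shell:

```sh
synmotif scan --model serial --target-a activation_B.km \
    --target-b activation_C.km --from 1.0 --to 6.0 --n 8 --out-dir out/
synmotif simplify-check --model serial --motif serial
synmotif feedback-check --base serial --feedback negative_feedback \
    --edge C-P:feedback
```

`scan` writes the S surface as CSV/JSON, `simplify-check` verifies the
serial/parallel sign-transfer rule (nonzero exit if it fails), and
`feedback-check` classifies the loop and tests output domination.

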