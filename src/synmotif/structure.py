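"""Structure-based simplification and feedback analysis.

Two structural results drive this module:

* **Sign transfer through intermediates.**  When each inhibitor acts on a
  process whose steady-state product level carries the effect downstream
  (x = Phi(a), y = Psi(b)), the mixed partial DS of the full system factors as
  ``DS = Phi'(a) * Psi'(b) * DS'`` where DS' is the same index computed on a
  simplified subsystem in which the intermediates are clamped inputs scanned
  by virtual inhibitors.  Only the signs of Phi' and Psi' are needed to
  transfer the sign of DS' back to the full system: for a serial cascade
  (Phi' < 0 under a Km-increase, Psi the identity) the signs are opposite; for
  a parallel pair of branches (both derivatives negative) they agree.

* **Feedback preservation.**  Adding a feedback loop cannot weaken the
  combination effect when the loop's contribution g to the upstream state x is
  negative while the downstream rate f increases with x (or g positive with f
  decreasing).  The verdict here is never assumed from the sign conditions
  alone: output domination y_fb(t) <= y_base(t) is verified pointwise on the
  simulated trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model_core import (
    NetworkModel,
    SimulationSettings,
    SpeciesSpec,
    build_rhs,
    readout,
    simulate,
)
from .perturb import Perturbation, PerturbationGrid, apply_perturbations
from .synergy import DSEstimate, ModelSurface, ds_estimate, synergy_s

__all__ = [
    "TargetMapping",
    "SimplifiedSystem",
    "SignRule",
    "FeedbackReport",
    "CorollaryReport",
    "StructureError",
    "phi_evaluate",
    "simplify_clamp",
    "lemma1_sign",
    "corollary_check",
    "feedback_check",
]


class StructureError(ValueError):
    """A structural precondition (mapping, motif shape, model diff) failed."""


@dataclass(frozen=True)
class TargetMapping:
    """How one inhibitor's parameter reaches the simplified subsystem.

    Either ``intermediate`` names the species whose steady-state level
    x = Phi(scale) carries the inhibition downstream, or ``identity`` marks a
    parameter that already acts inside the retained subsystem (Psi = id).
    """

    perturbation: Perturbation
    intermediate: str | None = None
    identity: bool = False

    def __post_init__(self):
        if (self.intermediate is None) == (not self.identity):
            raise ValueError("set exactly one of intermediate / identity")


@dataclass
class SimplifiedSystem:
    submodel: NetworkModel
    clamp_baselines: dict[str, float]
    surface: ModelSurface
    virtual_a: Perturbation
    virtual_b: Perturbation
    baseline_output: float


@dataclass(frozen=True)
class SignRule:
    """sign(DS) = phi_sign * psi_sign * sign(DS')."""

    motif: str  # serial | parallel | general
    phi_sign: int
    psi_sign: int

    def predict(self, ds_simplified_sign: int) -> int:
        return self.phi_sign * self.psi_sign * ds_simplified_sign

    @property
    def relation(self) -> int:
        """+1 if original and simplified DS share sign, -1 if opposite."""
        return self.phi_sign * self.psi_sign


EXPECTED_RELATION = {"serial": -1, "parallel": +1}


@dataclass
class FeedbackReport:
    g_sign: str  # negative | positive | mixed
    df_dx_sign: str  # positive | negative | mixed
    condition_met: bool
    domination_holds: bool
    max_violation: float
    x_species: str
    n_samples: int


@dataclass
class CorollaryReport:
    motif: str
    relation_expected: int
    n_points: int
    n_determinate: int
    sign_agreement_fraction: float
    phi_sign: int
    psi_sign: int
    lemma_max_rel_mismatch: float
    s_recon_max_abs_dev: float
    s_recon_max_rel_dev: float
    s_sign_agreement: bool
    diagonal_s: np.ndarray | None
    holds: bool = field(init=False)

    def __post_init__(self):
        self.holds = (
            self.n_determinate > 0
            and self.sign_agreement_fraction == 1.0
            and self.s_sign_agreement
        )


# ---------------------------------------------------------------------------

def phi_evaluate(
    model: NetworkModel,
    mapping: TargetMapping,
    scale: float,
    settings: SimulationSettings | None = None,
    rel_step: float = 1e-3,
) -> tuple[float, int]:
    """Steady-state level of the intermediate under the scaled parameter.

    Returns ``(level, sign of dPhi/dscale)``; the sign comes from a central
    difference at ``scale * (1 +/- rel_step)``.  Identity mappings return
    ``(scale, +1)`` without simulation.
    """
    if mapping.identity:
        return scale, +1
    settings = settings or SimulationSettings()

    def level(s: float) -> float:
        m = apply_perturbations(model, [mapping.perturbation.at(s)])
        traj = simulate(m, settings)
        if settings.readout_mode == "steady_state" and not traj.steady_reached:
            raise StructureError(
                f"system did not reach steady state at scale {s}; "
                "use endpoint readout mode for oscillatory systems"
            )
        if mapping.intermediate not in traj.endpoint:
            raise StructureError(f"intermediate {mapping.intermediate!r} not in model")
        return traj.endpoint[mapping.intermediate]

    x = level(scale)
    hi = level(scale * (1 + rel_step))
    lo = level(scale * (1 - rel_step))
    diff = hi - lo
    sign = 0 if diff == 0 else (1 if diff > 0 else -1)
    return x, sign


def _prune(model: NetworkModel) -> NetworkModel:
    """Drop species unused by any reaction, the output, or a surviving pool."""
    used = {model.output}
    for r in model.reactions:
        for role in (r.substrate, r.product, r.modifier):
            if role is not None:
                used.add(role)
    kept = []
    for s in model.species:
        if s.name not in used:
            continue
        if s.pool_partner is not None and s.pool_partner not in used:
            s = replace(s, pool_partner=None, pool_total=None)
        kept.append(s)
    inputs = {k: v for k, v in model.inputs.items() if k in used}
    return replace(model, species=tuple(kept), inputs=inputs)


def simplify_clamp(
    model: NetworkModel,
    mappings: tuple[TargetMapping, TargetMapping],
    settings: SimulationSettings | None = None,
) -> SimplifiedSystem:
    """Clamp each mapped intermediate at its baseline steady level.

    The returned subsystem drops every reaction that produces or consumes a
    clamped intermediate (the whole upstream cycle), keeps reactions where it
    only appears as a modifier, and exposes a response surface whose virtual
    inhibitor scales multiply the clamp levels (identity mappings keep their
    original parameter target).  The subsystem must reproduce the full model's
    baseline output at clamp scales (1, 1) to 1e-6 relative.
    """
    settings = settings or SimulationSettings()
    baseline_traj = simulate(model, settings)
    baseline_out = readout(baseline_traj, model)

    clamps: dict[str, float] = {}
    for m in mappings:
        if m.identity:
            continue
        if m.intermediate == model.output:
            raise StructureError("cannot clamp the output species itself")
        if m.intermediate not in baseline_traj.endpoint:
            raise StructureError(f"intermediate {m.intermediate!r} not in model")
        clamps[m.intermediate] = baseline_traj.endpoint[m.intermediate]

    reactions = tuple(
        r for r in model.reactions
        if r.substrate not in clamps and r.product not in clamps
    )
    species = []
    for s in model.species:
        if s.name in clamps:
            continue
        if s.pool_partner in clamps:
            s = replace(s, pool_partner=None, pool_total=None)
        species.append(s)
    sub = replace(
        model,
        species=tuple(species),
        reactions=reactions,
        inputs={**model.inputs, **clamps},
    )
    sub = _prune(sub)
    for r in sub.reactions:
        for role in (r.substrate, r.product, r.modifier):
            if role is not None and role not in {s.name for s in sub.species} | set(sub.inputs):
                raise StructureError(
                    f"retained subsystem still references removed species {role!r}"
                )

    def virtual(m: TargetMapping) -> Perturbation:
        if m.identity:
            return m.perturbation
        return Perturbation(target=m.intermediate, field="input")

    va, vb = virtual(mappings[0]), virtual(mappings[1])
    surface = ModelSurface(sub, va, vb, settings)
    sub_base = surface.baseline_output
    if abs(sub_base - baseline_out) > 1e-6 * max(abs(baseline_out), 1e-30):
        raise StructureError(
            f"simplified baseline {sub_base} deviates from full-model baseline "
            f"{baseline_out} beyond 1e-6 relative"
        )
    return SimplifiedSystem(
        submodel=sub,
        clamp_baselines=clamps,
        surface=surface,
        virtual_a=va,
        virtual_b=vb,
        baseline_output=sub_base,
    )


def lemma1_sign(
    ds_simplified: DSEstimate | float, phi_sign: int, psi_sign: int
) -> int:
    """Predicted sign of the full-system DS; 0 means indeterminate."""
    ds = ds_simplified.ds_value if isinstance(ds_simplified, DSEstimate) else ds_simplified
    s = 0 if ds == 0 else (1 if ds > 0 else -1)
    return phi_sign * psi_sign * s


_MOTIF_INTERMEDIATES = {
    # (mapping_a, mapping_b): species clamped, or None for identity
    "serial": ("B-P", None),
    "parallel": ("B1-P", "B2-P"),
}


def motif_mappings(
    motif: str, perturbation_a: Perturbation, perturbation_b: Perturbation
) -> tuple[TargetMapping, TargetMapping]:
    """Default intermediate mappings for the built-in motif shapes."""
    try:
        inter_a, inter_b = _MOTIF_INTERMEDIATES[motif]
    except KeyError:
        raise StructureError(f"no default mappings for motif {motif!r}") from None
    ma = TargetMapping(perturbation_a, intermediate=inter_a)
    mb = (
        TargetMapping(perturbation_b, identity=True)
        if inter_b is None
        else TargetMapping(perturbation_b, intermediate=inter_b)
    )
    return ma, mb


def corollary_check(
    model: NetworkModel,
    motif: str,
    grid: PerturbationGrid,
    settings: SimulationSettings | None = None,
    form: str = "difference",
    ds_rel_step: float = 1e-3,
    determinate_floor: float = 1e-6,
) -> CorollaryReport:
    """Verify the serial/parallel sign relation between DS and DS' on a grid.

    At each grid point the full-system DS and the simplified-system DS'
    (evaluated at the corresponding virtual scales) are compared against the
    declared relation (serial: opposite signs; parallel: same sign).  Points
    where either estimate falls below ``determinate_floor`` in magnitude are
    excluded as indeterminate.  The report also reconstructs the full-system
    S surface from the simplified one via S(a, b) = S'(Phi(a)/x0, Psi(b)/y0)
    and records the worst absolute/relative deviation, plus the equal-dose
    diagonal when the grid is square.
    """
    if motif not in EXPECTED_RELATION:
        raise StructureError(f"motif must be serial or parallel, got {motif!r}")
    settings = settings or SimulationSettings()
    expected = EXPECTED_RELATION[motif]
    pa, pb = grid.perturbation_a, grid.perturbation_b
    mappings = motif_mappings(motif, pa, pb)
    simplified = simplify_clamp(model, mappings, settings)
    original = ModelSurface(model, pa, pb, settings)

    # virtual-scale maps phi(a) = Phi(a)/x0 (normalized), psi(b) likewise
    def level_fn(mapping: TargetMapping):
        if mapping.identity:
            return lambda s: s
        cache: dict[float, float] = {}
        x0 = simplified.clamp_baselines[mapping.intermediate]

        def level(s: float) -> float:
            if s not in cache:
                m = apply_perturbations(model, [mapping.perturbation.at(s)])
                traj = simulate(m, settings)
                cache[s] = traj.endpoint[mapping.intermediate] / x0
            return cache[s]

        return level

    _, phi_sign = phi_evaluate(model, mappings[0], _mid(grid.scales_a), settings)
    _, psi_sign = phi_evaluate(model, mappings[1], _mid(grid.scales_b), settings)

    phi_fn, psi_fn = level_fn(mappings[0]), level_fn(mappings[1])
    phi = {a: phi_fn(a) for a in grid.scales_a}
    psi = {b: psi_fn(b) for b in grid.scales_b}

    n_pts = n_det = n_agree = 0
    lemma_worst = 0.0
    recon_abs = recon_rel = 0.0
    sign_ok = True
    tol = 1e-6
    for a in grid.scales_a:
        for b in grid.scales_b:
            n_pts += 1
            h = (ds_rel_step * a, ds_rel_step * b)
            ds_o = ds_estimate(original, (a, b), steps=h, form=form).ds_value
            hv = (ds_rel_step * phi[a], ds_rel_step * psi[b])
            ds_s = ds_estimate(
                simplified.surface, (phi[a], psi[b]), steps=hv, form=form
            ).ds_value
            s_direct = synergy_s(original, a, b, form=form).s_value
            s_recon = synergy_s(simplified.surface, phi[a], psi[b], form=form).s_value
            recon_abs = max(recon_abs, abs(s_recon - s_direct))
            if abs(s_direct) > 10 * tol:
                recon_rel = max(recon_rel, abs(s_recon - s_direct) / abs(s_direct))
                if (s_recon < -tol) != (s_direct < -tol):
                    sign_ok = False
            if min(abs(ds_o), abs(ds_s)) < determinate_floor:
                continue
            n_det += 1
            if (ds_o > 0) == ((expected * ds_s) > 0):
                n_agree += 1
            # quantitative factorization: DS = phi'(a) psi'(b) DS'
            d = ds_rel_step
            dphi = (phi_fn(a * (1 + d)) - phi_fn(a * (1 - d))) / (2 * a * d)
            dpsi = (psi_fn(b * (1 + d)) - psi_fn(b * (1 - d))) / (2 * b * d)
            pred = dphi * dpsi * ds_s
            lemma_worst = max(lemma_worst, abs(ds_o - pred) / max(abs(ds_o), 1e-30))

    diag = None
    if grid.scales_a == grid.scales_b:
        diag = np.array(
            [synergy_s(original, s, s, form=form).s_value for s in grid.scales_a]
        )
    return CorollaryReport(
        motif=motif,
        relation_expected=expected,
        n_points=n_pts,
        n_determinate=n_det,
        sign_agreement_fraction=(n_agree / n_det) if n_det else float("nan"),
        phi_sign=phi_sign,
        psi_sign=psi_sign,
        lemma_max_rel_mismatch=lemma_worst,
        s_recon_max_abs_dev=recon_abs,
        s_recon_max_rel_dev=recon_rel,
        s_sign_agreement=sign_ok,
        diagonal_s=diag,
    )


def _mid(scales: Sequence[float]) -> float:
    return scales[len(scales) // 2]


# ---------------------------------------------------------------------------
# feedback

def _output_on_grid(
    model: NetworkModel, settings: SimulationSettings, t_grid: np.ndarray
) -> np.ndarray:
    """Output time course sampled exactly at ``t_grid`` (tight tolerances)."""
    from scipy.integrate import solve_ivp

    rhs, free = build_rhs(model)
    y0 = np.array([next(s.initial for s in model.species if s.name == n) for n in free])
    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), y0, method="LSODA", t_eval=t_grid,
        rtol=min(settings.rtol, 1e-10), atol=min(settings.atol, 1e-12),
    )
    if not sol.success:
        raise StructureError(f"domination integration failed: {sol.message}")
    if model.output in model.inputs:
        return np.full_like(t_grid, model.inputs[model.output])
    return sol.y[free.index(model.output)]


def _signs_to_label(neg: bool, pos: bool) -> str:
    if neg and pos:
        return "mixed"
    return "negative" if neg else "positive"


def feedback_check(
    base_model: NetworkModel,
    feedback_model: NetworkModel,
    feedback_edge: tuple[str, str],
    perturbations: Sequence[Perturbation] = (),
    settings: SimulationSettings | None = None,
    n_samples: int = 64,
) -> FeedbackReport:
    """Classify a feedback loop and verify output domination numerically.

    ``feedback_edge`` is ``(modifier species, feedback reaction label)``.  The
    two models must differ exactly by the labeled feedback reaction(s).  The
    loop sign g is the feedback reactions' sampled contribution to the
    upstream state x; the downstream sensitivity is the sampled sign of
    d(dy/dt)/dx along the trajectory.  Domination (y_fb <= y_base) is checked
    pointwise on the union time grid, never inferred from the sign condition.
    """
    settings = settings or SimulationSettings()
    modifier, label = feedback_edge
    base_rx = set(base_model.reactions)
    extra = [r for r in feedback_model.reactions if r not in base_rx]
    missing = [r for r in base_model.reactions if r not in set(feedback_model.reactions)]
    if missing or not extra:
        raise StructureError("feedback model must equal the base model plus feedback reactions")
    if any(r.label != label for r in extra) or any(r.modifier != modifier for r in extra):
        raise StructureError(
            f"extra reactions do not all match the declared feedback edge "
            f"({modifier!r}, {label!r})"
        )
    if base_model.output != feedback_model.output:
        raise StructureError("models disagree on the output species")

    base = apply_perturbations(base_model, list(perturbations))
    fb = apply_perturbations(feedback_model, list(perturbations))
    traj_b = simulate(base, settings)
    traj_f = simulate(fb, settings)

    rhs_f, free_f = build_rhs(fb)
    rhs_b, free_b = build_rhs(base)
    idx_b = {n: i for i, n in enumerate(free_b)}
    out = base.output
    if out not in idx_b:
        raise StructureError("output must be a dynamic species for feedback analysis")

    # sample states along the feedback trajectory
    n_t = len(traj_f.times)
    take = np.unique(np.linspace(0, n_t - 1, min(n_samples, n_t)).astype(int))
    samples_b = [
        np.array([traj_f.concentrations[n][t_i] for n in free_b]) for t_i in take
    ]

    def df_dx(y_b: np.ndarray, name: str) -> float:
        """d(dy/dt)/d[name] on the shared downstream structure."""
        i = idx_b[name]
        x0 = y_b[i]
        delta = 1e-6 * max(abs(x0), 1.0)
        y_hi, y_lo = y_b.copy(), y_b.copy()
        y_hi[i] = x0 + delta
        y_lo[i] = max(x0 - delta, 0.0)
        return (rhs_b(0.0, y_hi)[idx_b[out]] - rhs_b(0.0, y_lo)[idx_b[out]]) / (
            y_hi[i] - y_lo[i]
        )

    # x: the species the feedback reaction touches that the downstream output
    # rate actually depends on (largest sampled |df/dx| breaks ties)
    fb_rx = extra[0]
    candidates = [
        n for n in (fb_rx.substrate, fb_rx.product) if n is not None and n in idx_b
    ]
    if not candidates:
        raise StructureError("feedback reaction touches no dynamic species")
    sensitivity = {
        n: max(abs(df_dx(y, n)) for y in samples_b) for n in candidates
    }
    x_species = max(candidates, key=lambda n: sensitivity[n])

    g_neg = g_pos = False
    df_pos = df_neg = False
    from .model_core import _rate_fn  # rate vector over the feedback model

    rates_f, _ = _rate_fn(fb)
    fb_indices = [i for i, r in enumerate(fb.reactions) if r in extra]
    for k, t_i in enumerate(take):
        y_f = np.array([traj_f.concentrations[n][t_i] for n in free_f])
        v = rates_f(y_f)
        contrib = 0.0
        for i in fb_indices:
            r = fb.reactions[i]
            if r.substrate == x_species:
                contrib -= v[i]
            if r.product == x_species:
                contrib += v[i]
        if contrib < -1e-14:
            g_neg = True
        elif contrib > 1e-14:
            g_pos = True
        df = df_dx(samples_b[k], x_species)
        if df > 1e-12:
            df_pos = True
        elif df < -1e-12:
            df_neg = True

    if not (g_neg or g_pos):
        g_sign = "negative"  # identically zero loop: harmless, treat as inactive
    else:
        g_sign = _signs_to_label(g_neg, g_pos)
    df_sign = _signs_to_label(df_neg, df_pos) if (df_neg or df_pos) else "mixed"
    condition = (g_sign == "negative" and df_sign == "positive") or (
        g_sign == "positive" and df_sign == "negative"
    )

    # domination on a shared time grid: re-integrate both models at the same
    # sample points with tightened tolerances so solver error stays well below
    # the 10*atol violation band
    t_max = max(traj_b.times[-1], traj_f.times[-1])
    t_grid = np.unique(np.concatenate([
        [0.0],
        np.geomspace(max(t_max * 1e-6, 1e-9), t_max, 300),
    ]))
    y_base = _output_on_grid(base, settings, t_grid)
    y_fb = _output_on_grid(fb, settings, t_grid)
    max_violation = float(np.max(y_fb - y_base, initial=0.0))
    domination = bool(np.all(y_fb <= y_base + 10 * settings.atol))

    return FeedbackReport(
        g_sign=g_sign,
        df_dx_sign=df_sign,
        condition_met=condition,
        domination_holds=domination,
        max_violation=max_violation,
        x_species=x_species,
        n_samples=len(take),
    )
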