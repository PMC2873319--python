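"""Michaelis-Menten reaction networks as data-driven ODE systems.

A :class:`NetworkModel` is a declarative description of a signaling motif:
species (optionally tied into conserved activation/deactivation cycles),
reactions drawn from a small menu of rate laws, a designated output species,
and clamped inputs held constant during integration.  The right-hand side of
the ODE system is assembled from the reaction records, so any network that
fits the schema -- from a two-cycle cascade to a transcribed pathway model --
runs through the same simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "SpeciesSpec",
    "ReactionSpec",
    "NetworkModel",
    "SimulationSettings",
    "Trajectory",
    "SimulationError",
    "ModelValidationError",
    "validate_model",
    "simulate",
    "readout",
]

#: rate-law kinds understood by the simulator
MM_KINDS = frozenset({"mm_activation", "mm_deactivation"})
REACTION_KINDS = MM_KINDS | frozenset(
    {"mass_action", "zeroth_synthesis", "first_degradation"}
)


class ModelValidationError(ValueError):
    """Raised when an operation requires a valid model and gets violations."""


class SimulationError(RuntimeError):
    """Integration failure; carries the solver status message."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species with optional conserved-cycle bookkeeping.

    ``pool_partner``/``pool_total`` declare that this species and its partner
    form an inactive/active pair whose concentrations sum to ``pool_total``
    (e.g. B and B-P in an activation cycle).  Declare the pool on one member
    only.
    """

    name: str
    initial: float = 0.0
    pool_partner: str | None = None
    pool_total: float | None = None


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction with a rate law from a fixed menu.

    kinds:
      * ``mm_activation`` / ``mm_deactivation`` --
        ``vmax * [modifier] * [substrate] / (km + [substrate])``;
        an absent modifier contributes a factor of 1.
      * ``mass_action`` -- ``rate_constant * [substrate] * [modifier or 1]``
      * ``zeroth_synthesis`` -- ``rate_constant`` (product only)
      * ``first_degradation`` -- ``rate_constant * [substrate]``

    ``label`` is an optional handle used by perturbation paths.
    """

    kind: str
    substrate: str | None = None
    product: str | None = None
    modifier: str | None = None
    vmax: float | None = None
    km: float | None = None
    rate_constant: float | None = None
    label: str | None = None


@dataclass(frozen=True)
class NetworkModel:
    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    output: str
    inputs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "inputs", dict(self.inputs))

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def free_species(self) -> list[str]:
        """Species integrated by the ODE solver (declared, not clamped)."""
        return [s.name for s in self.species if s.name not in self.inputs]

    def reaction_by_label(self, label: str) -> tuple[int, ReactionSpec]:
        hits = [(i, r) for i, r in enumerate(self.reactions) if r.label == label]
        if len(hits) != 1:
            raise KeyError(
                f"label {label!r} resolves to {len(hits)} reactions, need exactly 1"
            )
        return hits[0]

    def with_reaction(self, index: int, reaction: ReactionSpec) -> "NetworkModel":
        rs = list(self.reactions)
        rs[index] = reaction
        return replace(self, reactions=tuple(rs))


@dataclass(frozen=True)
class SimulationSettings:
    """Solver configuration.

    ``steady_state`` readout integrates until the max-norm of the free-species
    derivatives drops below ``steady_tolerance`` (or ``t_end`` is reached),
    then polishes the endpoint with a Newton solve on the reduced steady-state
    equations.  Tolerances are deliberately tight: downstream synergy indices
    are second differences of outputs and amplify solver noise.
    """

    t_end: float = 1e4
    readout_mode: str = "steady_state"  # or "endpoint"
    steady_tolerance: float = 1e-9
    rtol: float = 1e-8
    atol: float = 1e-10
    max_steps: int = 100_000

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if min(self.steady_tolerance, self.rtol, self.atol) <= 0:
            raise ValueError("tolerances must be > 0")
        if self.readout_mode not in ("endpoint", "steady_state"):
            raise ValueError(f"unknown readout_mode {self.readout_mode!r}")


@dataclass
class Trajectory:
    times: np.ndarray
    concentrations: dict[str, np.ndarray]  # includes clamped species
    steady_reached: bool
    endpoint: dict[str, float]


# ---------------------------------------------------------------------------
# validation

def _check_reaction(i: int, r: ReactionSpec, known: set[str]) -> list[str]:
    tag = f"reaction[{i}]" + (f" ({r.label})" if r.label else "")
    out: list[str] = []
    if r.kind not in REACTION_KINDS:
        out.append(f"{tag}: unknown kind {r.kind!r}")
        return out
    if r.kind in MM_KINDS:
        if r.vmax is None or r.vmax <= 0:
            out.append(f"{tag}: vmax must be > 0 for {r.kind}")
        if r.km is None or r.km <= 0:
            out.append(f"{tag}: km must be > 0 for {r.kind}")
        if r.substrate is None or r.product is None:
            out.append(f"{tag}: substrate and product required for {r.kind}")
    else:
        if r.rate_constant is None or r.rate_constant < 0:
            out.append(f"{tag}: rate_constant must be >= 0 for {r.kind}")
        if r.kind == "mass_action" and (r.substrate is None or r.product is None):
            out.append(f"{tag}: substrate and product required for mass_action")
        if r.kind == "zeroth_synthesis" and r.product is None:
            out.append(f"{tag}: product required for zeroth_synthesis")
        if r.kind == "first_degradation" and r.substrate is None:
            out.append(f"{tag}: substrate required for first_degradation")
    if r.substrate is not None and r.substrate == r.product:
        out.append(f"{tag}: substrate equals product ({r.substrate!r})")
    for role in ("substrate", "product", "modifier"):
        name = getattr(r, role)
        if name is not None and name not in known:
            out.append(f"{tag}: {role} {name!r} is not declared or clamped")
    return out


def validate_model(model: NetworkModel) -> list[str]:
    """Collect invariant violations; an empty list means the model is valid.

    Never raises: every problem is reported as a message naming the offending
    element.
    """
    out: list[str] = []
    declared = {s.name for s in model.species}
    known = declared | set(model.inputs)
    by_name = {s.name: s for s in model.species}

    seen: set[str] = set()
    for s in model.species:
        if s.name in seen:
            out.append(f"species {s.name!r}: declared more than once")
        seen.add(s.name)
        if s.initial < 0:
            out.append(f"species {s.name!r}: initial concentration {s.initial} < 0")
        if s.pool_partner is not None:
            if s.pool_partner not in declared:
                out.append(
                    f"species {s.name!r}: pool partner {s.pool_partner!r} not declared"
                )
            elif s.pool_total is not None:
                partner = by_name[s.pool_partner]
                tot = s.initial + partner.initial
                if abs(tot - s.pool_total) > 1e-9 * max(1.0, abs(s.pool_total)):
                    out.append(
                        f"species {s.name!r}: pool with {s.pool_partner!r} sums to "
                        f"{tot}, declared total {s.pool_total}"
                    )
            else:
                out.append(f"species {s.name!r}: pool_partner set without pool_total")
    for i, r in enumerate(model.reactions):
        out.extend(_check_reaction(i, r, known))
    if model.output not in known:
        out.append(f"output species {model.output!r} is not declared or clamped")
    for name, value in model.inputs.items():
        if value < 0:
            out.append(f"input {name!r}: clamped level {value} < 0")
        if name in declared:
            out.append(f"input {name!r}: clamped species also declared as dynamic")
    return out


def conserved_pools(model: NetworkModel) -> list[tuple[str, str, float]]:
    """(member, partner, total) triples, one per declared cycle."""
    out = []
    for s in model.species:
        if s.pool_partner is not None and s.pool_total is not None:
            out.append((s.name, s.pool_partner, s.pool_total))
    return out


# ---------------------------------------------------------------------------
# RHS assembly

def _rate_fn(model: NetworkModel) -> tuple[Callable[[np.ndarray], np.ndarray], list[str]]:
    """Compile the reaction list into ``rates(y) -> per-reaction rate vector``."""
    free = model.free_species()
    idx = {n: i for i, n in enumerate(free)}
    clamped = dict(model.inputs)

    def conc(name: str | None, y: np.ndarray) -> float:
        if name is None:
            return 1.0
        if name in idx:
            return y[idx[name]]
        return clamped[name]

    def rates(y: np.ndarray) -> np.ndarray:
        v = np.empty(len(model.reactions))
        for i, r in enumerate(model.reactions):
            if r.kind in MM_KINDS:
                s = max(conc(r.substrate, y), 0.0)
                v[i] = r.vmax * conc(r.modifier, y) * s / (r.km + s)
            elif r.kind == "mass_action":
                v[i] = r.rate_constant * conc(r.substrate, y) * conc(r.modifier, y)
            elif r.kind == "zeroth_synthesis":
                v[i] = r.rate_constant
            else:  # first_degradation
                v[i] = r.rate_constant * conc(r.substrate, y)
        return v

    return rates, free


def build_rhs(model: NetworkModel) -> tuple[Callable[[float, np.ndarray], np.ndarray], list[str]]:
    """ODE right-hand side over the free species, plus their ordering."""
    rates, free = _rate_fn(model)
    idx = {n: i for i, n in enumerate(free)}
    # stoichiometry: substrate -1, product +1 (modifiers are catalytic)
    stoich = np.zeros((len(free), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        if r.substrate in idx:
            stoich[idx[r.substrate], j] -= 1.0
        if r.product in idx:
            stoich[idx[r.product], j] += 1.0

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return stoich @ rates(y)

    return rhs, free


def _polish_steady_state(
    model: NetworkModel, y_end: np.ndarray, free: list[str], settings: SimulationSettings
) -> np.ndarray | None:
    """Newton-polish the integrator endpoint on the reduced steady-state system.

    Conserved cycles make the full Jacobian singular (equilibria form a family
    across pool slices), so each pool is reduced to its declared member with
    the partner eliminated as ``total - member``.
    """
    rhs, _ = build_rhs(model)
    idx = {n: i for i, n in enumerate(free)}
    pools = conserved_pools(model)
    eliminated = {p for _, p, _ in pools if p in idx}
    reduced = [n for n in free if n not in eliminated]
    if not reduced:
        return None
    partner_of = {m: (p, t) for m, p, t in pools}
    ridx = {n: i for i, n in enumerate(reduced)}

    def expand(z: np.ndarray) -> np.ndarray:
        y = np.empty(len(free))
        for n in free:
            if n in ridx:
                y[idx[n]] = z[ridx[n]]
        for m, (p, t) in partner_of.items():
            if p in idx and m in ridx:
                y[idx[p]] = t - z[ridx[m]]
        return y

    def residual(z: np.ndarray) -> np.ndarray:
        f = rhs(0.0, expand(z))
        return np.array([f[idx[n]] for n in reduced])

    z0 = np.array([y_end[idx[n]] for n in reduced])
    sol = root(residual, z0, method="hybr", tol=1e-13)
    # hybr can flag "not making good progress" when started already at the
    # root; judge the candidate by its residual, not by the flag
    if np.max(np.abs(residual(sol.x))) > np.max(np.abs(residual(z0))):
        return None
    y = expand(sol.x)
    # reject a polish that jumped to a distant (or unphysical) equilibrium
    if np.any(y < -100 * settings.atol):
        return None
    scale = np.maximum(np.abs(y_end), 1.0)
    if np.max(np.abs(y - y_end) / scale) > 1e-3:
        return None
    return y


def simulate(model: NetworkModel, settings: SimulationSettings | None = None) -> Trajectory:
    """Integrate the model and return its trajectory.

    In ``steady_state`` mode integration proceeds in geometrically growing
    spans until ``max |d[X]/dt| < steady_tolerance`` over the free species,
    then the endpoint is Newton-polished on the steady-state equations.

    Raises :class:`ModelValidationError` for invalid models and
    :class:`SimulationError` when the integrator fails.
    """
    if settings is None:
        settings = SimulationSettings()
    violations = validate_model(model)
    if violations:
        raise ModelValidationError("; ".join(violations))

    rhs, free = build_rhs(model)
    y0 = np.array(
        [next(s.initial for s in model.species if s.name == n) for n in free]
    )

    times = [np.array([0.0])]
    states = [y0[:, None]]
    steady = False

    if not free:
        t_grid = np.array([0.0, settings.t_end])
        times, states = [t_grid], [np.zeros((0, 2))]
        y_end = y0
        steady = True
    else:
        t0, y = 0.0, y0
        span = min(1.0, settings.t_end)
        while True:
            t1 = min(t0 + span, settings.t_end)
            sol = solve_ivp(
                rhs,
                (t0, t1),
                y,
                method="LSODA",
                rtol=settings.rtol,
                atol=settings.atol,
                dense_output=False,
            )
            if not sol.success:
                raise SimulationError(
                    f"integration failed on [{t0:g}, {t1:g}]: {sol.message}",
                    status=sol.status,
                )
            times.append(sol.t[1:])
            states.append(sol.y[:, 1:])
            t0, y = sol.t[-1], sol.y[:, -1]
            if settings.readout_mode == "steady_state":
                if np.max(np.abs(rhs(t0, y))) < settings.steady_tolerance:
                    steady = True
                    break
            if t0 >= settings.t_end:
                break
            span *= 4.0
        y_end = y
        if settings.readout_mode == "steady_state" and steady:
            polished = _polish_steady_state(model, y_end, free, settings)
            if polished is not None:
                y_end = polished

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1)
    if y_all.size and y_all.min() < -100 * settings.atol:
        worst = free[int(np.argmin(y_all.min(axis=1)))]
        raise SimulationError(
            f"species {worst!r} fell below -100*atol ({y_all.min():.3e}); "
            "the model, not roundoff, is producing negative concentrations"
        )

    conc = {n: y_all[i] for i, n in enumerate(free)}
    for name, level in model.inputs.items():
        conc[name] = np.full_like(t_all, level)
    endpoint = {n: float(max(conc[n][-1] if n in free or n in model.inputs else 0.0, 0.0)) for n in conc}
    for i, n in enumerate(free):
        endpoint[n] = float(max(y_end[i], 0.0))
    return Trajectory(times=t_all, concentrations=conc, steady_reached=steady, endpoint=endpoint)


def readout(trajectory: Trajectory, model: NetworkModel) -> float:
    """Output-species concentration at the readout point (clipped at 0)."""
    if model.output not in trajectory.endpoint:
        raise KeyError(f"output species {model.output!r} not in trajectory")
    return max(trajectory.endpoint[model.output], 0.0)


def trajectory_to_csv(trajectory: Trajectory, path) -> None:
    """Write ``time,<species...>`` CSV."""
    import pandas as pd

    df = pd.DataFrame({"time": trajectory.times})
    for name, series in trajectory.concentrations.items():
        df[name] = series
    df.to_csv(path, index=False)
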