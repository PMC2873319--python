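"""Built-in signaling motifs, model JSON I/O, and seeded random fixtures.

Three canonical motifs are provided, each built from Michaelis-Menten
activation/deactivation cycles with conserved totals:

* ``serial`` -- a two-stage cascade: a clamped input A drives the B cycle,
  activated B-P drives the C cycle, and activated C-P is the output.
  Inhibitor slots are the Michaelis constants of the two activation steps
  (labels ``activation_B`` and ``activation_C``); raising a Km (scale > 1)
  weakens that stage.
* ``parallel`` -- two independent upstream cycles (B1, B2) converge on the C
  cycle through additive activation rates (logic OR: either branch alone
  sustains the output).  Inhibitor slots are the Km of the two upstream
  activations.
* ``negative_feedback`` -- the serial motif plus a deactivation of B-P
  mediated by the output C-P (Michaelis constant Km5), closing a negative
  loop from output back to the first stage.

Default parameter values (totals 1, input 1, activation Vmax 1 / Km 0.5,
deactivation Vmax 0.5 / Km 0.5, feedback Vmax 1 / Km5 0.5, arbitrary units)
are package defaults chosen to put every cycle in a responsive mid-saturation
regime; every structural claim checked elsewhere is a sign or ordering
property robust to this choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .model_core import NetworkModel, ReactionSpec, SpeciesSpec

__all__ = [
    "MotifParams",
    "FixtureSpec",
    "SchemaError",
    "serial_motif",
    "parallel_motif",
    "negative_feedback_motif",
    "builtin_model",
    "BUILTIN_MOTIFS",
    "NFKB_TARGET_MAPPING",
    "random_motif",
    "load_model",
    "save_model",
    "load_model_file",
    "save_model_file",
]

SCHEMA_ID = "synmotif-model/1"

#: Reactions inhibited by the three NF-kB pathway drugs, in the full model and
#: in its clamped simplification.  The kinetic model itself is supplied as an
#: external ``synmotif-model/1`` document (transcribed from its published
#: supplementary description); only the target mapping is package knowledge.
NFKB_TARGET_MAPPING: dict[str, dict[str, str]] = {
    "geldanamycin": {
        "original": "RIP1 binding with TNFR1 complex",
        "simplified": "IKKK-P activates IKK-beta",
    },
    "ps1145": {
        "original": "IKK-beta-P phosphorylates IkB",
        "simplified": "IKK-beta-P phosphorylates IkB",
    },
    "aldehyde": {
        "original": "IkB degradation",
        "simplified": "IkB degradation",
    },
    "output": "ICAM-1",
}


@dataclass(frozen=True)
class MotifParams:
    """Kinetic parameters shared by the built-in motifs.

    ``totals`` lists per-cycle conserved totals, upstream cycles first
    (serial/feedback: B then C; parallel: B1, B2, C -- a length-2 tuple is
    broadcast to three cycles).
    """

    totals: tuple[float, ...] = (1.0, 1.0)
    input_level: float = 1.0
    activation_vmax: float = 1.0
    activation_km: float = 0.5
    deactivation_vmax: float = 0.5
    deactivation_km: float = 0.5
    feedback_vmax: float = 1.0
    feedback_km: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "totals", tuple(self.totals))
        vals = [*self.totals, self.input_level, self.activation_vmax,
                self.activation_km, self.deactivation_vmax, self.deactivation_km,
                self.feedback_vmax, self.feedback_km]
        if any(v <= 0 for v in vals):
            raise ValueError("all motif parameters must be > 0")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a seeded random motif (log-uniform parameter draws)."""

    kind: str  # serial | parallel | negative_feedback
    seed: int
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            # lo == hi pins the field to a point
            if not 0 < lo <= hi:
                raise ValueError(f"range for {name!r} must satisfy 0 < lo <= hi")


class SchemaError(ValueError):
    """Model document violates the synmotif-model/1 schema; names the path."""


def _cycle(
    inactive: str, active: str, total: float, modifier: str | None,
    act_vmax: float, act_km: float, deact_vmax: float, deact_km: float,
    label_suffix: str,
) -> tuple[list[SpeciesSpec], list[ReactionSpec]]:
    species = [
        SpeciesSpec(inactive, initial=total, pool_partner=active, pool_total=total),
        SpeciesSpec(active, initial=0.0),
    ]
    reactions = [
        ReactionSpec("mm_activation", substrate=inactive, product=active,
                     modifier=modifier, vmax=act_vmax, km=act_km,
                     label=f"activation_{label_suffix}"),
        ReactionSpec("mm_deactivation", substrate=active, product=inactive,
                     vmax=deact_vmax, km=deact_km,
                     label=f"deactivation_{label_suffix}"),
    ]
    return species, reactions


def serial_motif(params: MotifParams | None = None) -> NetworkModel:
    """Two-stage cascade A -> B -> C; output is activated C (C-P)."""
    p = params or MotifParams()
    if len(p.totals) != 2:
        raise ValueError("serial motif needs totals for exactly 2 cycles (B, C)")
    sp_b, rx_b = _cycle("B", "B-P", p.totals[0], "A",
                        p.activation_vmax, p.activation_km,
                        p.deactivation_vmax, p.deactivation_km, "B")
    sp_c, rx_c = _cycle("C", "C-P", p.totals[1], "B-P",
                        p.activation_vmax, p.activation_km,
                        p.deactivation_vmax, p.deactivation_km, "C")
    return NetworkModel(
        species=tuple(sp_b + sp_c),
        reactions=tuple(rx_b + rx_c),
        output="C-P",
        inputs={"A": p.input_level},
    )


def parallel_motif(params: MotifParams | None = None) -> NetworkModel:
    """Two upstream cycles converge on C through additive (OR) activation."""
    p = params or MotifParams()
    totals = p.totals if len(p.totals) == 3 else (*p.totals, p.totals[-1])
    if len(totals) != 3:
        raise ValueError("parallel motif needs totals for 3 cycles (B1, B2, C)")
    sp1, rx1 = _cycle("B1", "B1-P", totals[0], "A1",
                      p.activation_vmax, p.activation_km,
                      p.deactivation_vmax, p.deactivation_km, "B1")
    sp2, rx2 = _cycle("B2", "B2-P", totals[1], "A2",
                      p.activation_vmax, p.activation_km,
                      p.deactivation_vmax, p.deactivation_km, "B2")
    species_c = [
        SpeciesSpec("C", initial=totals[2], pool_partner="C-P", pool_total=totals[2]),
        SpeciesSpec("C-P", initial=0.0),
    ]
    rx_c = [
        ReactionSpec("mm_activation", substrate="C", product="C-P", modifier="B1-P",
                     vmax=p.activation_vmax, km=p.activation_km,
                     label="activation_C_via_B1"),
        ReactionSpec("mm_activation", substrate="C", product="C-P", modifier="B2-P",
                     vmax=p.activation_vmax, km=p.activation_km,
                     label="activation_C_via_B2"),
        ReactionSpec("mm_deactivation", substrate="C-P", product="C",
                     vmax=p.deactivation_vmax, km=p.deactivation_km,
                     label="deactivation_C"),
    ]
    return NetworkModel(
        species=tuple(sp1 + sp2 + species_c),
        reactions=tuple(rx1 + rx2 + rx_c),
        output="C-P",
        inputs={"A1": p.input_level, "A2": p.input_level},
    )


def negative_feedback_motif(params: MotifParams | None = None) -> NetworkModel:
    """Serial motif plus C-P-mediated deactivation of B-P (negative loop)."""
    p = params or MotifParams()
    base = serial_motif(p)
    feedback = ReactionSpec(
        "mm_deactivation", substrate="B-P", product="B", modifier="C-P",
        vmax=p.feedback_vmax, km=p.feedback_km, label="feedback",
    )
    return replace(base, reactions=(*base.reactions, feedback))


BUILTIN_MOTIFS = {
    "serial": serial_motif,
    "parallel": parallel_motif,
    "negative_feedback": negative_feedback_motif,
}


def builtin_model(name: str, params: MotifParams | None = None) -> NetworkModel:
    try:
        return BUILTIN_MOTIFS[name](params)
    except KeyError:
        raise KeyError(
            f"unknown builtin motif {name!r}; available: {sorted(BUILTIN_MOTIFS)}"
        ) from None


def random_motif(spec: FixtureSpec) -> NetworkModel:
    """Deterministic-in-seed motif with log-uniform parameter draws.

    Fields absent from ``spec.ranges`` keep their defaults; a range collapsed
    to a point pins the field.  Draw order is the declaration order of
    :class:`MotifParams`, so identical seeds give identical models.
    """
    if spec.kind not in BUILTIN_MOTIFS:
        raise ValueError(f"unknown motif kind {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    kwargs = {}
    n_totals = 3 if spec.kind == "parallel" else 2
    for f in fields(MotifParams):
        if f.name not in spec.ranges:
            continue
        lo, hi = spec.ranges[f.name]
        if f.name == "totals":
            draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_totals))
            kwargs["totals"] = tuple(float(d) for d in draws)
        else:
            kwargs[f.name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return builtin_model(spec.kind, MotifParams(**kwargs))


# ---------------------------------------------------------------------------
# JSON I/O

def save_model(model: NetworkModel) -> dict:
    """Serialize to a synmotif-model/1 document (plain dict)."""
    doc: dict = {"schema": SCHEMA_ID, "species": [], "reactions": [],
                 "output": model.output, "inputs": dict(model.inputs)}
    for s in model.species:
        entry: dict = {"name": s.name, "initial": s.initial}
        if s.pool_partner is not None:
            entry["pool_partner"] = s.pool_partner
            entry["pool_total"] = s.pool_total
        doc["species"].append(entry)
    for r in model.reactions:
        entry = {"kind": r.kind}
        for key in ("substrate", "product", "modifier", "vmax", "km", "label"):
            if getattr(r, key) is not None:
                entry[key] = getattr(r, key)
        if r.rate_constant is not None:
            entry["k"] = r.rate_constant
        doc["reactions"].append(entry)
    return doc


def _require(doc: dict, key: str, typ, path: str):
    if key not in doc:
        raise SchemaError(f"missing required key at {path}.{key}")
    if not isinstance(doc[key], typ):
        raise SchemaError(
            f"{path}.{key}: expected {typ.__name__ if isinstance(typ, type) else typ}, "
            f"got {type(doc[key]).__name__}"
        )
    return doc[key]


def load_model(document: dict) -> NetworkModel:
    """Parse a synmotif-model/1 document; schema errors name the JSON path."""
    if not isinstance(document, dict):
        raise SchemaError("$: document must be a JSON object")
    if document.get("schema") != SCHEMA_ID:
        raise SchemaError(f"$.schema: expected {SCHEMA_ID!r}, got {document.get('schema')!r}")
    species = []
    for i, entry in enumerate(_require(document, "species", list, "$")):
        path = f"$.species[{i}]"
        if not isinstance(entry, dict):
            raise SchemaError(f"{path}: expected object")
        name = _require(entry, "name", str, path)
        initial = float(_require(entry, "initial", (int, float), path))
        partner = entry.get("pool_partner")
        total = entry.get("pool_total")
        if (partner is None) != (total is None):
            raise SchemaError(f"{path}: pool_partner and pool_total must appear together")
        species.append(SpeciesSpec(name, initial, partner,
                                   None if total is None else float(total)))
    reactions = []
    for i, entry in enumerate(_require(document, "reactions", list, "$")):
        path = f"$.reactions[{i}]"
        if not isinstance(entry, dict):
            raise SchemaError(f"{path}: expected object")
        kind = _require(entry, "kind", str, path)
        reactions.append(ReactionSpec(
            kind=kind,
            substrate=entry.get("substrate"),
            product=entry.get("product"),
            modifier=entry.get("modifier"),
            vmax=None if "vmax" not in entry else float(entry["vmax"]),
            km=None if "km" not in entry else float(entry["km"]),
            rate_constant=None if "k" not in entry else float(entry["k"]),
            label=entry.get("label"),
        ))
    output = _require(document, "output", str, "$")
    inputs = document.get("inputs", {})
    if not isinstance(inputs, dict):
        raise SchemaError("$.inputs: expected object")
    return NetworkModel(
        species=tuple(species),
        reactions=tuple(reactions),
        output=output,
        inputs={k: float(v) for k, v in inputs.items()},
    )


def save_model_file(model: NetworkModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(save_model(model), indent=2) + "\n")


def load_model_file(path: str | Path) -> NetworkModel:
    return load_model(json.loads(Path(path).read_text()))
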