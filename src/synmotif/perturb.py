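"""Inhibitors as multiplicative parameter perturbations, plus dose grids.

An inhibitor dose is represented abstractly as a positive scale factor applied
to one kinetic parameter (a velocity constant, a Michaelis constant, or a
clamped input level).  Scale 1 is the untreated baseline.  Velocity-constant
inhibition uses scales below 1; Michaelis-constant inhibition uses scales
above 1 (a larger Km weakens the reaction).  Dose-to-scale calibration is out
of scope: screens are specified directly in scale space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import NetworkModel, ReactionSpec

__all__ = ["Perturbation", "PerturbationGrid", "apply_perturbations", "make_grid"]

_FIELDS = ("vmax", "km", "rate_constant", "input")


@dataclass(frozen=True)
class Perturbation:
    """Scale one parameter of a model.

    ``target`` is a reaction label or integer index; ``field`` one of
    ``vmax``/``km``/``rate_constant``, or ``input`` with ``target`` naming a
    clamped species.  ``scale`` multiplies the parameter.
    """

    target: str | int
    field: str
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.field not in _FIELDS:
            raise ValueError(f"field must be one of {_FIELDS}, got {self.field!r}")

    @property
    def baseline(self) -> bool:
        return self.scale == 1.0

    def at(self, scale: float) -> "Perturbation":
        """The same target at a different dose."""
        return replace(self, scale=scale)


@dataclass(frozen=True)
class PerturbationGrid:
    """Two perturbation templates with per-axis dose ladders."""

    perturbation_a: Perturbation
    perturbation_b: Perturbation
    scales_a: tuple[float, ...]
    scales_b: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "scales_a", tuple(self.scales_a))
        object.__setattr__(self, "scales_b", tuple(self.scales_b))
        for name, scales in (("scales_a", self.scales_a), ("scales_b", self.scales_b)):
            if any(s <= 0 for s in scales):
                raise ValueError(f"{name}: all scale factors must be > 0")


def _resolve(model: NetworkModel, p: Perturbation) -> tuple[int | str, str]:
    if p.field == "input":
        if p.target not in model.inputs:
            raise KeyError(f"no clamped input named {p.target!r}")
        return p.target, "input"
    if isinstance(p.target, int):
        if not 0 <= p.target < len(model.reactions):
            raise KeyError(f"reaction index {p.target} out of range")
        index = p.target
    else:
        index, _ = model.reaction_by_label(p.target)
    r = model.reactions[index]
    if getattr(r, p.field) is None:
        raise KeyError(
            f"reaction {p.target!r} has no {p.field} (kind {r.kind})"
        )
    return index, p.field


def apply_perturbations(
    model: NetworkModel, perturbations: list[Perturbation] | tuple[Perturbation, ...]
) -> NetworkModel:
    """Return a new model with each targeted parameter scaled.

    Pure: the input model is untouched, and repeated perturbations on the
    same path compose multiplicatively.
    """
    out = model
    for p in perturbations:
        where, field = _resolve(out, p)
        if field == "input":
            inputs = dict(out.inputs)
            inputs[where] = inputs[where] * p.scale
            out = replace(out, inputs=inputs)
        else:
            r: ReactionSpec = out.reactions[where]
            out = out.with_reaction(where, replace(r, **{field: getattr(r, field) * p.scale}))
    return out


def make_grid(
    template_a: Perturbation,
    template_b: Perturbation,
    n: int = 16,
    lo: float = 1e-4,
    hi: float = 0.9,
) -> PerturbationGrid:
    """Log-spaced descending dose ladder from ``hi`` (default 0.9) to ``lo``.

    Mirrors the screening convention of sweeping velocity-constant scales over
    roughly four orders of magnitude below the untreated value.
    """
    if lo <= 0:
        raise ValueError("lo must be > 0")
    if not lo < hi:
        raise ValueError("need lo < hi")
    if n < 2:
        raise ValueError("need n >= 2")
    scales = tuple(np.geomspace(hi, lo, n))
    return PerturbationGrid(template_a, template_b, scales, scales)
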