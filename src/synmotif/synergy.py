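"""Bliss-independence synergy scoring over dose-response surfaces.

The central objects are the survival ratio

    r(a, b) = output(a, b) / output(a0, b0),

the Synergism Assessment Factor

    S(a, b) = r(a, b) - r(a, b0) * r(a0, b)        (difference form)
    S(a, b) = ln r(a, b) - ln[r(a, b0) * r(a0, b)] (log form)

and its second-order mixed partial DS = d^2 S / da db, all taken in the
dimensionless scale space of the two inhibitor perturbations (a0 = b0 = 1).
S < 0 marks synergism (the pair suppresses the output below the Bliss product
of the single-agent effects), S > 0 antagonism, S = 0 additivity.  Because S
vanishes identically on the a = 1 and b = 1 boundary lines, the double
integral of DS over the rectangle [a, 1] x [b, 1] recovers S(a, b); hence a
uniformly negative DS over a dose rectangle guarantees synergism at its
corner.

Both the difference and the log form satisfy every property used here (the
S = 0 critical point, the boundary identity, the integral relation, and the
DS < 0 implies S < 0 sign rule); the form used is recorded in every result.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from functools import cached_property
from typing import Callable

import numpy as np

from .model_core import NetworkModel, SimulationSettings, readout, simulate
from .perturb import Perturbation, PerturbationGrid, apply_perturbations

__all__ = [
    "ResponseSurface",
    "FunctionSurface",
    "ModelSurface",
    "SynergyScore",
    "DSEstimate",
    "ScanResult",
    "survival_ratio",
    "bliss_expected",
    "synergy_s",
    "classify",
    "ds_estimate",
    "s_from_ds_oracle",
    "scan_surface",
]

#: default half-width of the additive band around S = 0
DEFAULT_TOL = 1e-6

FORMS = ("difference", "log")
STENCILS = ("four_point_s", "two_term_r")


class ResponseSurface(ABC):
    """Deterministic map from a pair of perturbation scales to an output."""

    @abstractmethod
    def evaluate(self, scale_a: float, scale_b: float) -> float:
        """Output concentration at the given perturbation scales."""

    @cached_property
    def baseline_output(self) -> float:
        return self.evaluate(1.0, 1.0)


class FunctionSurface(ResponseSurface):
    """Closed-form surface, mainly for tests and oracles."""

    def __init__(self, fn: Callable[[float, float], float]):
        self._fn = fn

    def evaluate(self, scale_a: float, scale_b: float) -> float:
        return float(self._fn(scale_a, scale_b))


class ModelSurface(ResponseSurface):
    """ODE-model surface: perturb, simulate to readout, cache.

    Caching makes repeated stencil/quadrature evaluations cheap and keeps the
    surface exactly deterministic.
    """

    def __init__(
        self,
        model: NetworkModel,
        template_a: Perturbation,
        template_b: Perturbation,
        settings: SimulationSettings | None = None,
    ):
        self.model = model
        self.template_a = template_a
        self.template_b = template_b
        self.settings = settings or SimulationSettings()
        self._cache: dict[tuple[float, float], float] = {}

    def evaluate(self, scale_a: float, scale_b: float) -> float:
        key = (float(scale_a), float(scale_b))
        if key not in self._cache:
            perturbed = apply_perturbations(
                self.model,
                [self.template_a.at(key[0]), self.template_b.at(key[1])],
            )
            traj = simulate(perturbed, self.settings)
            self._cache[key] = readout(traj, perturbed)
        return self._cache[key]


@dataclass(frozen=True)
class SynergyScore:
    s_value: float
    r_ab: float
    r_a: float
    r_b: float
    classification: str  # synergism | additive | antagonism
    form: str
    point: tuple[float, float]


@dataclass(frozen=True)
class DSEstimate:
    ds_value: float
    point: tuple[float, float]
    steps: tuple[float, float]
    stencil: str
    form: str
    unreliable: bool = False
    note: str | None = None


@dataclass
class ScanResult:
    grid: PerturbationGrid
    s_surface: np.ndarray  # shape (len(scales_a), len(scales_b)); NaN = failed
    ds_surface: np.ndarray | None
    verdict_counts: dict[str, int]
    form: str

    def diagonal(self) -> np.ndarray:
        """Equal-dose S curve; requires identical dose ladders on both axes."""
        if self.grid.scales_a != self.grid.scales_b:
            raise ValueError("equal-dose diagonal needs matching scale ladders")
        return np.diagonal(self.s_surface).copy()


# ---------------------------------------------------------------------------

def survival_ratio(surface: ResponseSurface, scale_a: float, scale_b: float) -> float:
    """r(a, b): output under perturbation divided by baseline output."""
    base = surface.baseline_output
    if base <= 0:
        raise ZeroDivisionError(
            f"baseline output must be > 0 to form a survival ratio (got {base})"
        )
    out = surface.evaluate(scale_a, scale_b)
    if out < 0:
        raise ValueError(
            f"negative output {out} at ({scale_a}, {scale_b}); model integrity violated"
        )
    return out / base


def bliss_expected(r_a: float, r_b: float) -> float:
    """Bliss-independent expectation: the product of single-agent survivals."""
    if r_a <= 0 or r_b <= 0:
        raise ValueError(f"survival ratios must be > 0, got ({r_a}, {r_b})")
    return r_a * r_b


def classify(s_value: float, tol: float = DEFAULT_TOL) -> str:
    """Synergism below -tol, antagonism above +tol, additive in between."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if s_value < -tol:
        return "synergism"
    if s_value > tol:
        return "antagonism"
    return "additive"


def synergy_s(
    surface: ResponseSurface,
    scale_a: float,
    scale_b: float,
    form: str = "difference",
    tol: float = DEFAULT_TOL,
) -> SynergyScore:
    """Score one dose pair against the Bliss expectation."""
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}")
    r_ab = survival_ratio(surface, scale_a, scale_b)
    r_a = survival_ratio(surface, scale_a, 1.0)
    r_b = survival_ratio(surface, 1.0, scale_b)
    if form == "difference":
        s = r_ab - bliss_expected(r_a, r_b)
    else:
        s = math.log(r_ab) - math.log(bliss_expected(r_a, r_b))
    return SynergyScore(
        s_value=s,
        r_ab=r_ab,
        r_a=r_a,
        r_b=r_b,
        classification=classify(s, tol),
        form=form,
        point=(scale_a, scale_b),
    )


def _s_value(surface: ResponseSurface, a: float, b: float, form: str) -> float:
    return synergy_s(surface, a, b, form=form).s_value


def _log_r(surface: ResponseSurface, a: float, b: float) -> float:
    return math.log(survival_ratio(surface, a, b))


def _mixed_central(f: Callable[[float, float], float], a, b, h, k) -> float:
    return (f(a + h, b + k) - f(a + h, b - k) - f(a - h, b + k) + f(a - h, b - k)) / (
        4.0 * h * k
    )


def _ds_at(
    surface: ResponseSurface,
    point: tuple[float, float],
    steps: tuple[float, float],
    stencil: str,
    form: str,
) -> float:
    a, b = point
    h, k = steps
    if stencil == "four_point_s":
        return _mixed_central(lambda x, y: _s_value(surface, x, y, form), a, b, h, k)
    # two_term_r: differentiate the r-level identity for S directly
    if form == "log":
        # single-agent log terms are separable and drop out of the mixed partial
        return _mixed_central(lambda x, y: _log_r(surface, x, y), a, b, h, k)
    mixed = _mixed_central(lambda x, y: survival_ratio(surface, x, y), a, b, h, k)
    dra = (survival_ratio(surface, a + h, 1.0) - survival_ratio(surface, a - h, 1.0)) / (2 * h)
    drb = (survival_ratio(surface, 1.0, b + k) - survival_ratio(surface, 1.0, b - k)) / (2 * k)
    return mixed - dra * drb


def ds_estimate(
    surface: ResponseSurface,
    point: tuple[float, float],
    steps: tuple[float, float] | None = None,
    stencil: str = "four_point_s",
    form: str = "difference",
) -> DSEstimate:
    """Finite-difference estimate of DS = d^2 S / da db at a dose pair.

    With explicit ``steps`` a single central-difference evaluation is made.
    Otherwise the step starts at 1e-3 of each scale and is halved until two
    successive estimates agree to 1e-3 relative; if halving makes successive
    estimates diverge (the step has reached the noise floor of the surface),
    the last consistent estimate is returned flagged ``unreliable``.
    """
    if stencil not in STENCILS:
        raise ValueError(f"stencil must be one of {STENCILS}")
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}")
    a, b = point
    if steps is not None:
        h, k = steps
        if h <= 0 or k <= 0 or a - h <= 0 or b - k <= 0:
            raise ValueError("steps must be > 0 and keep the stencil inside scale > 0")
        return DSEstimate(_ds_at(surface, point, (h, k), stencil, form), point, (h, k), stencil, form)

    h = 1e-3 * a
    k = 1e-3 * b
    prev = _ds_at(surface, point, (h, k), stencil, form)
    prev_gap = math.inf
    for _ in range(12):
        h2, k2 = h / 2, k / 2
        cur = _ds_at(surface, point, (h2, k2), stencil, form)
        gap = abs(cur - prev)
        scale = max(abs(cur), abs(prev), 1e-300)
        if gap <= 1e-3 * scale:
            return DSEstimate(cur, point, (h2, k2), stencil, form)
        if gap > 4.0 * prev_gap:
            # halving stopped helping: differences are dominated by evaluation noise
            return DSEstimate(
                prev, point, (h, k), stencil, form,
                unreliable=True,
                note="step control hit the surface noise floor before converging",
            )
        prev, prev_gap, h, k = cur, gap, h2, k2
    return DSEstimate(
        prev, point, (h, k), stencil, form,
        unreliable=True,
        note="step control exhausted its halving budget without converging",
    )


def s_from_ds_oracle(
    surface: ResponseSurface,
    target: tuple[float, float],
    mesh: int = 32,
    form: str = "difference",
    stencil: str = "four_point_s",
) -> float:
    """Recover S(target) as the double integral of DS over [a,1] x [b,1].

    Composite trapezoidal quadrature on an (mesh+1)^2 node grid, with the
    finite-difference step tied to half the node spacing so adjacent stencils
    share surface evaluations.  Converges to ``synergy_s(target)`` at second
    order in the mesh spacing; a degenerate rectangle gives 0 exactly.
    """
    if mesh < 4:
        raise ValueError("mesh must be >= 4")
    ta, tb = target
    if ta == 1.0 or tb == 1.0:
        return 0.0
    a_nodes = np.linspace(ta, 1.0, mesh + 1)
    b_nodes = np.linspace(tb, 1.0, mesh + 1)
    h = abs(a_nodes[1] - a_nodes[0]) / 2
    k = abs(b_nodes[1] - b_nodes[0]) / 2
    ds = np.empty((mesh + 1, mesh + 1))
    for i, a in enumerate(a_nodes):
        for j, b in enumerate(b_nodes):
            ds[i, j] = ds_estimate(
                surface, (a, b), steps=(h, k), stencil=stencil, form=form
            ).ds_value
    inner = np.trapezoid(ds, b_nodes, axis=1)
    return float(np.trapezoid(inner, a_nodes))


def scan_surface(
    surface: ResponseSurface,
    grid: PerturbationGrid,
    form: str = "difference",
    tol: float = DEFAULT_TOL,
    compute_ds: bool = False,
) -> ScanResult:
    """S (and optionally DS) at every grid point.

    A grid point whose evaluation fails is recorded as NaN and excluded from
    the verdict counts rather than aborting the scan.
    """
    na, nb = len(grid.scales_a), len(grid.scales_b)
    s = np.full((na, nb), np.nan)
    ds = np.full((na, nb), np.nan) if compute_ds else None
    counts = {"synergism": 0, "additive": 0, "antagonism": 0, "failed": 0}
    for i, a in enumerate(grid.scales_a):
        for j, b in enumerate(grid.scales_b):
            try:
                score = synergy_s(surface, a, b, form=form, tol=tol)
            except Exception:
                counts["failed"] += 1
                continue
            s[i, j] = score.s_value
            counts[score.classification] += 1
            if compute_ds:
                try:
                    ds[i, j] = ds_estimate(surface, (a, b), form=form).ds_value
                except Exception:
                    pass
    return ScanResult(grid=grid, s_surface=s, ds_surface=ds, verdict_counts=counts, form=form)
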