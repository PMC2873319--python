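import math

import numpy as np
import pytest

from synmotif.model_core import SimulationSettings
from synmotif.models import (
    negative_feedback_motif,
    parallel_motif,
    serial_motif,
)
from synmotif.perturb import Perturbation, PerturbationGrid
from synmotif.synergy import FunctionSurface


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def serial_model():
    return serial_motif()


@pytest.fixture(scope="session")
def parallel_model():
    return parallel_motif()


@pytest.fixture(scope="session")
def feedback_model():
    return negative_feedback_motif()


def gamma_surface(gamma: float, baseline: float = 1.0) -> FunctionSurface:
    """r(a,b) = exp(-u - v - gamma*u*v) with u = 1-a, v = 1-b.

    A smooth closed-form dose-response surface whose log-form DS is exactly
    -gamma everywhere; gamma > 0 gives synergism, gamma < 0 antagonism,
    gamma = 0 is Bliss-independent (separable).
    """

    def fn(a, b):
        u, v = 1.0 - a, 1.0 - b
        return baseline * math.exp(-u - v - gamma * u * v)

    return FunctionSurface(fn)


def separable_surface(p: float = 1.3, q: float = 0.7, baseline: float = 2.0) -> FunctionSurface:
    """r(a,b) = u(a)*v(b): the Bliss-null case, S and DS vanish identically."""
    return FunctionSurface(lambda a, b: baseline * (a ** p) * (b ** q))


@pytest.fixture
def serial_km_grid():
    scales = tuple(np.geomspace(1.2, 6.0, 4))
    return PerturbationGrid(
        Perturbation("activation_B", "km"),
        Perturbation("activation_C", "km"),
        scales,
        scales,
    )


@pytest.fixture
def parallel_km_grid():
    scales = tuple(np.geomspace(1.2, 6.0, 4))
    return PerturbationGrid(
        Perturbation("activation_B1", "km"),
        Perturbation("activation_B2", "km"),
        scales,
        scales,
    )
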