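"""Synergy index tests: survival ratios, S, DS stencils, integral recovery.

Closed-form expectations come from symbolic differentiation (sympy) of the
test surfaces, independent of the finite-difference path under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from synmotif.perturb import Perturbation, PerturbationGrid
from synmotif.synergy import (
    FunctionSurface,
    ModelSurface,
    bliss_expected,
    classify,
    ds_estimate,
    s_from_ds_oracle,
    scan_surface,
    survival_ratio,
    synergy_s,
)

from conftest import gamma_surface, separable_surface


def symbolic_ds(gamma: float, a0: float, b0: float, form: str) -> float:
    """Oracle: exact mixed partial of S for the gamma surface via sympy."""
    import sympy as sp

    a, b = sp.symbols("a b", positive=True)
    u, v = 1 - a, 1 - b
    r = sp.exp(-u - v - gamma * u * v)
    r_a = r.subs(b, 1)
    r_b = r.subs(a, 1)
    if form == "difference":
        s = r - r_a * r_b
    else:
        s = sp.log(r) - sp.log(r_a) - sp.log(r_b)
    return float(sp.diff(s, a, b).subs({a: a0, b: b0}))


class TestSurvivalRatio:
    def test_baseline_is_one(self):
        assert survival_ratio(gamma_surface(0.5), 1.0, 1.0) == pytest.approx(1.0)

    def test_insensitive_surface_is_one_everywhere(self):
        flat = FunctionSurface(lambda a, b: 3.7)
        for a, b in [(0.5, 0.5), (0.1, 0.9), (1.0, 0.2)]:
            assert survival_ratio(flat, a, b) == pytest.approx(1.0)

    def test_closed_form_value(self):
        surf = FunctionSurface(lambda a, b: 5.0 * math.exp(-(1 - a) - (1 - b)))
        assert survival_ratio(surf, 0.5, 1.0) == pytest.approx(math.exp(-0.5))

    def test_zero_baseline_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            survival_ratio(FunctionSurface(lambda a, b: 0.0), 0.5, 0.5)

    def test_negative_output_is_model_integrity_error(self):
        surf = FunctionSurface(lambda a, b: 1.0 if a == b == 1.0 else -1.0)
        with pytest.raises(ValueError):
            survival_ratio(surf, 0.5, 0.5)


@pytest.mark.parametrize(
    "r_a, r_b, expected", [(1.0, 0.3, 0.3), (0.5, 0.5, 0.25), (0.9, 0.2, 0.18)]
)
def test_bliss_expected_is_the_product(r_a, r_b, expected):
    assert bliss_expected(r_a, r_b) == pytest.approx(expected)


def test_bliss_expected_rejects_nonpositive():
    with pytest.raises(ValueError):
        bliss_expected(0.0, 0.5)


@pytest.mark.parametrize(
    "s, tol, expected",
    [
        (-0.2678, 1e-6, "synergism"),
        (0.0, 1e-6, "additive"),
        (5e-7, 1e-6, "additive"),
        (0.01, 1e-6, "antagonism"),
    ],
)
def test_classify_thresholds(s, tol, expected):
    assert classify(s, tol) == expected


class TestSynergyS:
    @pytest.mark.parametrize("form", ["difference", "log"])
    @pytest.mark.parametrize("s", [0.2, 0.7, 1.0, 1.6])
    def test_boundary_identity(self, form, s):
        surf = gamma_surface(0.8)
        tol = 0 if form == "difference" else 1e-12
        assert abs(synergy_s(surf, 1.0, s, form=form).s_value) <= tol
        assert abs(synergy_s(surf, s, 1.0, form=form).s_value) <= tol

    @given(
        p=st.floats(0.1, 3.0),
        q=st.floats(0.1, 3.0),
        a=st.floats(0.05, 1.5),
        b=st.floats(0.05, 1.5),
    )
    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    def test_separable_surface_is_bliss_null(self, p, q, a, b):
        surf = separable_surface(p, q)
        for form in ("difference", "log"):
            assert synergy_s(surf, a, b, form=form).s_value == pytest.approx(0.0, abs=1e-10)

    def test_difference_form_closed_value(self):
        # r = exp(-u-v-gamma*u*v): at u=v=0.5, S = e^-1 (e^-0.125 - 1) < 0
        score = synergy_s(gamma_surface(0.5), 0.5, 0.5, form="difference")
        assert score.s_value == pytest.approx(math.exp(-1) * (math.exp(-0.125) - 1))
        assert score.classification == "synergism"

    def test_score_carries_ratios_and_form(self):
        score = synergy_s(gamma_surface(0.5), 0.5, 0.5, form="log")
        assert score.form == "log"
        assert score.r_ab == pytest.approx(math.exp(-1 - 0.125))
        assert score.r_a == score.r_b == pytest.approx(math.exp(-0.5))


class TestDSEstimate:
    @pytest.mark.parametrize("stencil", ["four_point_s", "two_term_r"])
    @pytest.mark.parametrize("form", ["difference", "log"])
    def test_separable_surface_has_zero_ds(self, stencil, form):
        est = ds_estimate(separable_surface(), (0.6, 0.8), steps=(0.01, 0.01),
                          stencil=stencil, form=form)
        assert abs(est.ds_value) < 1e-6

    @pytest.mark.parametrize("point", [(1.0, 1.0), (0.7, 0.6), (0.4, 1.2)])
    def test_log_form_ds_is_minus_gamma_everywhere(self, point):
        gamma = 0.37
        est = ds_estimate(gamma_surface(gamma), point, form="log")
        assert est.ds_value == pytest.approx(-gamma, rel=1e-4)
        assert not est.unreliable

    def test_difference_form_at_baseline_is_minus_gamma(self):
        gamma = 0.8
        est = ds_estimate(gamma_surface(gamma), (1.0, 1.0), form="difference")
        assert est.ds_value == pytest.approx(-gamma, rel=1e-4)

    @pytest.mark.parametrize("form", ["difference", "log"])
    def test_matches_symbolic_oracle_off_baseline(self, form):
        gamma, point = 0.5, (0.7, 0.6)
        expected = symbolic_ds(gamma, *point, form)
        est = ds_estimate(gamma_surface(gamma), point, form=form)
        assert est.ds_value == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("form", ["difference", "log"])
    def test_stencils_agree_on_smooth_surface(self, form):
        surf = gamma_surface(0.9)
        point, steps = (0.6, 0.75), (5e-3, 5e-3)
        a = ds_estimate(surf, point, steps=steps, stencil="four_point_s", form=form)
        b = ds_estimate(surf, point, steps=steps, stencil="two_term_r", form=form)
        assert a.ds_value == pytest.approx(b.ds_value, rel=1e-4)

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            ds_estimate(gamma_surface(0.5), (0.01, 0.5), steps=(0.02, 0.01))


class TestIntegralRecovery:
    def test_degenerate_rectangle_is_zero(self):
        assert s_from_ds_oracle(gamma_surface(0.5), (1.0, 0.5)) == 0.0
        assert s_from_ds_oracle(gamma_surface(0.5), (0.7, 1.0)) == 0.0

    def test_constant_ds_integrates_exactly(self):
        # log form: DS = -gamma, so the integral over [0.5,1]^2 is -gamma/4
        gamma = 0.62
        val = s_from_ds_oracle(gamma_surface(gamma), (0.5, 0.5), mesh=8, form="log")
        assert val == pytest.approx(-gamma * 0.25, rel=1e-6)

    def test_second_order_mesh_convergence(self):
        surf = gamma_surface(0.9)
        target = (0.4, 0.5)
        exact = synergy_s(surf, *target, form="difference").s_value
        errs = [
            abs(s_from_ds_oracle(surf, target, mesh=m, form="difference") - exact)
            for m in (8, 16, 32)
        ]
        assert errs[0] > errs[1] > errs[2]
        # halving the spacing should cut the error by about 4x
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0

    def test_recovers_s_on_serial_motif_surface(self, serial_model, settings):
        surf = ModelSurface(
            serial_model,
            Perturbation("activation_B", "km"),
            Perturbation("activation_C", "km"),
            settings,
        )
        target = (2.0, 2.0)  # Km-increase doses
        direct = synergy_s(surf, *target).s_value
        via_ds = s_from_ds_oracle(surf, target, mesh=32)
        assert via_ds == pytest.approx(direct, rel=1e-3)

    def test_negative_ds_mesh_implies_synergism_at_corner(self):
        surf = gamma_surface(0.7)
        target = (0.5, 0.6)
        nodes_a = np.linspace(target[0], 1.0, 9)
        nodes_b = np.linspace(target[1], 1.0, 9)
        ds_vals = [
            ds_estimate(surf, (a, b), steps=(0.01, 0.01)).ds_value
            for a in nodes_a
            for b in nodes_b
        ]
        assert all(d < 0 for d in ds_vals)
        assert synergy_s(surf, *target).s_value <= 0


class TestScan:
    def test_single_baseline_point(self):
        p = Perturbation("activation_B", "km")
        grid = PerturbationGrid(p, p, (1.0,), (1.0,))
        res = scan_surface(gamma_surface(0.5), grid)
        assert res.s_surface.shape == (1, 1)
        assert res.s_surface[0, 0] == pytest.approx(0.0)
        assert res.verdict_counts["additive"] == 1

    def test_separable_surface_scans_to_zero(self):
        p = Perturbation("activation_B", "km")
        scales = tuple(np.geomspace(0.9, 0.01, 5))
        res = scan_surface(separable_surface(), PerturbationGrid(p, p, scales, scales))
        assert np.allclose(res.s_surface, 0.0, atol=1e-9)

    def test_boundary_row_and_column_are_zero(self):
        p = Perturbation("activation_B", "km")
        scales = (1.0, 0.5, 0.25)
        res = scan_surface(gamma_surface(0.5), PerturbationGrid(p, p, scales, scales))
        assert np.allclose(res.s_surface[0, :], 0.0, atol=1e-12)
        assert np.allclose(res.s_surface[:, 0], 0.0, atol=1e-12)

    def test_serial_motif_diagonal_is_synergistic(self, serial_model, settings):
        surf = ModelSurface(
            serial_model,
            Perturbation("activation_B", "km"),
            Perturbation("activation_C", "km"),
            settings,
        )
        p = Perturbation("activation_B", "km")
        scales = tuple(np.geomspace(1.2, 8.0, 5))
        res = scan_surface(surf, PerturbationGrid(p, p, scales, scales))
        diag = res.diagonal()
        assert np.all(diag < 0)
        assert res.verdict_counts["synergism"] == 25

    def test_failed_points_recorded_not_fatal(self):
        def fn(a, b):
            if a < 0.5:
                raise RuntimeError("boom")
            return math.exp(-(1 - a) - (1 - b))

        p = Perturbation("activation_B", "km")
        scales = (0.9, 0.6, 0.3)
        res = scan_surface(FunctionSurface(fn), PerturbationGrid(p, p, scales, scales))
        assert res.verdict_counts["failed"] == 3
        assert np.isnan(res.s_surface[2, :]).all()
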