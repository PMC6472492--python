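"""Adaptive dynamics: gradients, singular strategies, robustness."""

import numpy as np
import pytest

import debpop as dp
from debpop.evolve import CSSNotFoundError, _gradient_one

N = dp.NumericsConfig()


def test_resident_has_unit_fitness_in_own_environment(eq_default, p_default):
    assert dp.mutant_R0(p_default, eq_default.R_tilde, N) == pytest.approx(
        1.0, abs=1e-7
    )


def test_positive_selection_below_the_singular_point(eq_default, p_default):
    # the one-trait CSS of Q at P=1 sits just above 1, so Q=1.01 invades
    r0 = dp.mutant_R0(p_default.replace(Q=1.01), eq_default.R_tilde, N)
    assert r0 > 1.0


def test_fitness_increases_with_assimilation_efficiency(eq_default, p_default):
    vals = [
        dp.mutant_R0(p_default.replace(sigma=s), eq_default.R_tilde, N)
        for s in (0.45, 0.5, 0.55, 0.6)
    ]
    assert np.all(np.diff(vals) > 0)


def test_gradient_sign_change_across_singular_point():
    assert dp.selection_gradient("Q", dp.ModelParams(Q=0.9), N) > 0
    assert dp.selection_gradient("Q", dp.ModelParams(Q=1.1), N) < 0


def test_gradient_robust_to_step_halving(eq_default, p_default):
    p = p_default.replace(Q=1.05)
    eq = dp.solve_equilibrium(p, N)
    g1 = _gradient_one("Q", p, eq.R_tilde, N)
    g2 = _gradient_one("Q", p, eq.R_tilde, N.replace(fd_step=N.fd_step / 2))
    assert abs(g2 / g1 - 1.0) < 1e-5


class TestFindCSS:
    def test_one_trait_css_location_and_classification(self):
        sp = dp.find_css("Q", dp.ModelParams(), N)
        # the CSS of the evolving exponent tracks the fixed one
        assert abs(sp.traits["Q"] - 1.0) < 0.05
        assert sp.evolutionarily_stable
        assert sp.convergence_stable
        assert sp.is_css
        assert sp.resource_minimized
        assert abs(sp.gradient["Q"]) < N.gradient_tol

    def test_missing_sign_change_reported_with_endpoints(self):
        with pytest.raises(CSSNotFoundError) as err:
            dp.find_css("Q", dp.ModelParams(), N, bracket=(1.2, 1.5))
        assert err.value.gradients is not None


class TestJointCSS:
    def test_exponents_converge_to_common_value(self, joint_css_default):
        sp = joint_css_default
        assert abs(sp.traits["Q"] - sp.traits["P"]) < 1e-3
        assert sp.evolutionarily_stable
        assert abs(sp.gradient["Q"]) < N.gradient_tol
        assert abs(sp.gradient["P"]) < N.gradient_tol

    def test_mrd_flat_but_production_scaling_superlinear(self, joint_css_default):
        """At the joint CSS competitive ability is size-independent even
        though mass-specific production still rises with size."""
        sp = joint_css_default
        p = sp.equilibrium.params
        s = np.geomspace(p.s_b, p.s_m, 41)
        mrd = dp.maintenance_resource_density(s, p)
        # flatness is limited only by the residual |Q - P| of the solve
        tol = 2.0 * abs(p.Q - p.P) * np.log(p.s_m / p.s_b) + 1e-12
        assert np.max(np.abs(mrd / mrd[0] - 1.0)) < tol
        mass_specific = (
            np.asarray(dp.biomass_production(sp.equilibrium.R_tilde, s, p)) / s
        )
        assert np.all(np.diff(mass_specific) > 0)  # since common value > 1

    def test_isocline_point_matches_joint_css(self, joint_css_default):
        """Cross-operation consistency: the Q-isocline evaluated at the
        joint-CSS value of P returns the joint-CSS value of Q."""
        sp = joint_css_default
        curve = dp.evolutionary_isocline(
            "Q", [sp.traits["P"]], dp.ModelParams(), N,
            bracket=(sp.traits["Q"] - 0.05, sp.traits["Q"] + 0.05),
        )
        assert curve.table["Q_css"].iloc[0] == pytest.approx(
            sp.traits["Q"], abs=1e-4
        )


@pytest.fixture(scope="module")
def base_value(joint_css_default):
    return joint_css_default.common_value


class TestSensitivity:
    """Which parameters move the joint CSS.

    Resource and feeding-level parameters leave the common value
    untouched; the maintenance constant and background mortality shift
    it slightly; the reference mass shifts it strongly (downward).
    """

    @pytest.mark.parametrize("change", [dict(Rmax=40.0), dict(sigma=0.6)])
    def test_supply_parameters_do_not_move_the_css(self, change, base_value):
        sp = dp.find_joint_css(dp.ModelParams(**change), N)
        assert abs(sp.common_value - base_value) < 1e-7
        assert abs(sp.traits["Q"] - sp.traits["P"]) < 1e-3

    @pytest.mark.parametrize("change", [dict(T=0.012), dict(mu_c=0.002)])
    def test_maintenance_and_background_mortality_shift_it(self, change, base_value):
        sp = dp.find_joint_css(dp.ModelParams(**change), N)
        assert abs(sp.common_value - base_value) > 3e-7
        assert abs(sp.traits["Q"] - sp.traits["P"]) < 1e-3

    def test_larger_reference_mass_lowers_the_css(self, base_value):
        sp = dp.find_joint_css(dp.ModelParams(s_r=1.5), N)
        assert sp.common_value < base_value - 0.1
        assert abs(sp.traits["Q"] - sp.traits["P"]) < 1e-3


class TestReproductionScaling:
    def test_hyperallometric_at_the_css(self, joint_css_default):
        expo = dp.reproduction_scaling_check(joint_css_default)
        assert expo > 1.0

    def test_step_allocation_variant_is_exactly_linear(self, eq_default):
        # all-to-reproduction adults with Q=P=1: flux proportional to s
        expo = dp.reproduction_scaling_check(eq_default, step_allocation=True)
        assert expo == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_resource_conversion_constant(self, eq_default):
        eq2 = dp.solve_equilibrium(dp.ModelParams(chi=2.0), N)
        assert dp.reproduction_scaling_check(eq2) == pytest.approx(
            dp.reproduction_scaling_check(eq_default), rel=1e-9
        )
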