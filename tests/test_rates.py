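"""Unit and property tests of the individual-level rate functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import debpop as dp

P = dp.ModelParams()


class TestIngestion:
    def test_no_resource_no_intake(self):
        assert dp.ingestion_rate(0.0, 1.0, P) == 0.0
        assert dp.ingestion_rate(0.0, 5.0, P) == 0.0

    def test_half_saturation_gives_half_maximum(self):
        # s = s_r = 1, R = H: I = M/2
        assert dp.ingestion_rate(3.0, 1.0, P) == pytest.approx(0.05)

    def test_saturation_limit(self):
        # s=2, Q=1: bound M*(s/s_r)^Q = 0.2 g/day
        bound = 0.2
        assert dp.ingestion_rate(1e12, 2.0, P) == pytest.approx(bound, rel=1e-10)
        R = np.linspace(0.0, 100.0, 50)
        vals = dp.ingestion_rate(R, 2.0, P)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals <= bound)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            dp.ingestion_rate(1.0, 0.0, P)
        with pytest.raises(ValueError):
            dp.ingestion_rate(-1.0, 1.0, P)

    @given(st.floats(0.11, 9.9), st.floats(0.5, 1.5))
    @settings(deadline=None, max_examples=50)
    def test_power_law_homogeneity(self, s, Q):
        # I(R, s) = (s/s_rI)^Q * I(R, s_rI)
        p = P.replace(Q=Q)
        lhs = dp.ingestion_rate(2.0, s, p)
        rhs = (s / p.ref_mass_ingestion) ** Q * dp.ingestion_rate(
            2.0, p.ref_mass_ingestion, p
        )
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestBiomassProduction:
    def test_table_value(self):
        # sigma*I - T = 0.5*0.05 - 0.01 at s=1, R=H
        assert dp.biomass_production(3.0, 1.0, P) == pytest.approx(0.015)

    def test_zero_at_maintenance_resource_density(self):
        for s in (0.1, 1.0, 7.5):
            mrd = dp.maintenance_resource_density(s, P)
            assert dp.biomass_production(mrd, s, P) == pytest.approx(0.0, abs=1e-15)

    def test_sign_convention_below_mrd(self):
        mrd = dp.maintenance_resource_density(1.0, P)
        om = dp.biomass_production(0.5 * mrd, 1.0, P)
        assert om < 0
        assert dp.omega_plus(0.5 * mrd, 1.0, P) == 0.0
        assert dp.omega_minus(0.5 * mrd, 1.0, P) == om

    @given(st.floats(0.0, 30.0), st.floats(0.11, 9.9),
           st.floats(0.6, 1.4), st.floats(0.6, 1.4))
    @settings(deadline=None, max_examples=100)
    def test_parts_partition(self, R, s, Q, Pexp):
        p = P.replace(Q=Q, P=Pexp)
        plus = dp.omega_plus(R, s, p)
        minus = dp.omega_minus(R, s, p)
        assert plus * minus == 0.0
        assert plus + minus == pytest.approx(dp.biomass_production(R, s, p))


class TestAllocation:
    def test_juveniles_allocate_everything_to_growth(self):
        s = 0.5 * P.s_b + 0.5 * P.s_j
        assert dp.allocation_fraction(s, P) == 1.0

    def test_midpoint_is_half(self):
        assert dp.allocation_fraction((P.s_j + P.s_m) / 2, P) == pytest.approx(0.5)

    def test_zero_at_maximum_size(self):
        assert dp.allocation_fraction(P.s_m, P) == 0.0

    def test_monotone_bounded_and_smooth_at_maturation(self):
        s = np.linspace(P.s_b, P.s_m, 2001)
        k = dp.allocation_fraction(s, P)
        assert np.all((k >= 0) & (k <= 1))
        assert np.all(np.diff(k) <= 0)
        # C1 across s_j: value 1 and slope ~ 0 just above
        eps = 1e-6
        assert dp.allocation_fraction(P.s_j + eps, P) == pytest.approx(1.0, abs=1e-10)
        slope = (dp.allocation_fraction(P.s_j + eps, P) - 1.0) / eps
        assert abs(slope) < 1e-5

    def test_domain_error_and_overshoot_clamp(self):
        with pytest.raises(ValueError):
            dp.allocation_fraction(P.s_b / 2, P)
        with pytest.raises(ValueError):
            dp.allocation_fraction(2 * P.s_m, P)
        # float overshoot clamps to zero
        assert dp.allocation_fraction(P.s_m * (1 + 1e-9), P) == 0.0


class TestGrowthAndFecundity:
    def test_growth_zero_under_starvation_and_at_max_size(self):
        mrd = dp.maintenance_resource_density(1.0, P)
        assert dp.growth_rate(0.5 * mrd, 1.0, P) == 0.0
        assert dp.growth_rate(25.0, P.s_m, P) == 0.0

    def test_juvenile_growth_equals_production(self):
        assert dp.growth_rate(3.0, 1.0, P) == pytest.approx(0.015)

    def test_fecundity_zero_for_juveniles_and_under_starvation(self):
        assert dp.fecundity_rate(3.0, 0.5, P) == 0.0
        mrd = dp.maintenance_resource_density(5.0, P)
        assert dp.fecundity_rate(0.9 * mrd, 5.0, P) == 0.0

    def test_fecundity_at_maximum_size(self):
        # kappa(s_m)=0: b = Omega+/s_b
        omp = dp.omega_plus(3.0, P.s_m, P)
        assert dp.fecundity_rate(3.0, P.s_m, P) == pytest.approx(omp / P.s_b)


class TestMortality:
    def test_background_only_when_fed(self):
        assert dp.mortality_rate(3.0, 1.5, P) == pytest.approx(0.0015)

    def test_stage_specific_additions(self):
        p = P.replace(mu_j=0.002, mu_a=0.004)
        assert dp.mortality_rate(3.0, 0.5, p) == pytest.approx(0.0015 + 0.002)
        assert dp.mortality_rate(3.0, 5.0, p) == pytest.approx(0.0015 + 0.004)

    def test_starvation_adds_mass_specific_deficit(self):
        # R=0, s=1: Omega = -T = -0.01, so mu = mu_c + 0.01
        assert dp.mortality_rate(0.0, 1.0, P) == pytest.approx(0.0115)

    @given(st.floats(0.0, 30.0), st.floats(0.11, 9.9))
    @settings(deadline=None, max_examples=50)
    def test_never_below_background(self, R, s):
        assert dp.mortality_rate(R, s, P) >= P.mu_c


class TestMaintenanceResourceDensity:
    def test_size_independent_at_equal_exponents(self):
        s = np.geomspace(P.s_b, P.s_m, 101)
        for c in (0.8, 1.0, 1.3):
            p = P.replace(Q=c, P=c)
            mrd = dp.maintenance_resource_density(s, p)
            ref = p.H * p.T / (p.sigma * p.M - p.T)
            assert np.all(np.abs(mrd / ref - 1.0) < 1e-12)

    def test_default_closed_form(self):
        # H*T/(sigma*M - T) = 3*0.01/0.04
        assert dp.maintenance_resource_density(1.0, P) == pytest.approx(0.75)

    def test_monotone_in_size_follows_exponent_order(self):
        s = np.geomspace(P.s_b, P.s_m, 51)
        up = dp.maintenance_resource_density(s, P.replace(Q=1.0, P=1.2))
        dn = dp.maintenance_resource_density(s, P.replace(Q=1.2, P=1.0))
        assert np.all(np.diff(up) > 0)  # P > Q: large individuals inferior
        assert np.all(np.diff(dn) < 0)  # Q > P: large individuals superior

    def test_infinite_when_maintenance_uncoverable(self):
        p = P.replace(Q=1.0, P=2.5)
        assert np.isinf(dp.maintenance_resource_density(9.9, p))

    @given(st.floats(0.11, 9.9), st.floats(0.7, 1.3), st.floats(0.7, 1.3))
    @settings(deadline=None, max_examples=100)
    def test_roundtrip_production_zero(self, s, Q, Pexp):
        p = P.replace(Q=Q, P=Pexp)
        mrd = dp.maintenance_resource_density(s, p)
        if np.isfinite(mrd):
            scale = p.T * (s / p.s_r) ** Pexp
            assert abs(dp.biomass_production(mrd, s, p)) < 1e-12 * scale


class TestResourceGrowth:
    def test_zero_at_capacity_and_renewal_from_empty(self):
        assert dp.resource_growth_rate(P.Rmax, P) == 0.0
        assert dp.resource_growth_rate(0.0, P) == pytest.approx(0.3)

    def test_affine(self):
        g1 = dp.resource_growth_rate(2.0, P)
        g2 = dp.resource_growth_rate(10.0, P)
        assert g1 + g2 == pytest.approx(2 * dp.resource_growth_rate(6.0, P))
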