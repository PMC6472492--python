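"""Cohort (EBT) simulator: integrator oracles, stability, invasions."""

import numpy as np
import pytest

import debpop as dp
from debpop.ebt import CohortOverflowError, EBTState

from conftest import make_timeseries

N = dp.NumericsConfig()


def _empty_state(R):
    return EBTState(R=R, mass=np.array([]), density=np.array([]),
                    age=np.array([]), lineage=np.array([], dtype=np.int64))


def test_consumer_free_resource_matches_semichemostat_closed_form():
    p = dp.ModelParams()
    ts = dp.simulate(p, 500.0, initial_state=_empty_state(5.0))
    exact = p.Rmax - (p.Rmax - 5.0) * np.exp(-p.delta * ts.time)
    assert np.max(np.abs(ts.resource - exact) / exact) < 1e-8


def test_stable_regime_converges_to_equilibrium(stable_run, eq_default):
    ts = stable_run
    assert abs(ts.resource[-1] / eq_default.R_tilde - 1.0) < 0.01
    assert abs(ts.juvenile_biomass[-1] / eq_default.juvenile_biomass - 1.0) < 0.01
    assert abs(ts.adult_biomass[-1] / eq_default.adult_biomass - 1.0) < 0.01


def test_state_nonnegative_throughout(stable_run):
    ts = stable_run
    p = dp.ModelParams()
    assert np.all(ts.resource >= 0)
    assert np.all(ts.resource <= p.Rmax)
    assert np.all(ts.juvenile_biomass >= 0)
    assert np.all(ts.adult_biomass >= 0)
    st = ts.final_state
    assert np.all(st.density >= 0)
    assert np.all(st.mass >= p.s_b)
    assert np.all(st.mass <= p.s_m * (1 + 1e-9))


def test_refining_steps_leaves_long_run_state_unchanged():
    """Halving both the closure interval and the internal step changes
    the quasi-stationary resource by well under 0.5%."""
    p = dp.ModelParams()
    eq = dp.solve_equilibrium(p, N)
    runs = {}
    for tag, opts in {
        "coarse": dp.EBTOptions(delta_t_cohort=1.0, dt_max=0.5),
        "fine": dp.EBTOptions(delta_t_cohort=0.5, dt_max=0.25),
    }.items():
        state = dp.initial_state_from_equilibrium(eq, p, perturbation=0.02)
        ts = dp.simulate(p, 2000.0, initial_state=state, options=opts)
        sel = ts.time >= 1500.0
        runs[tag] = (np.mean(ts.resource[sel]), np.mean(ts.total_biomass[sel]))
    assert abs(runs["fine"][0] / runs["coarse"][0] - 1.0) < 0.005
    assert abs(runs["fine"][1] / runs["coarse"][1] - 1.0) < 0.005


def test_cohort_cap_overflow_raises():
    p = dp.ModelParams()
    eq = dp.solve_equilibrium(p, N)
    state = dp.initial_state_from_equilibrium(eq, p)
    with pytest.raises(CohortOverflowError, match="delta_t_cohort"):
        dp.simulate(p, 50.0, initial_state=state,
                    options=dp.EBTOptions(max_cohorts=100))


class TestDetectCycles:
    def test_constant_series_is_stable(self):
        t = np.arange(0.0, 4000.0, 10.0)
        rep = dp.detect_cycles(make_timeseries(t, np.full_like(t, 2.0)),
                               transient=1000.0)
        assert not rep.cyclic
        assert rep.amplitude == 0.0

    def test_synthetic_sinusoid_period_recovered(self):
        t = np.arange(0.0, 3000.0, 1.0)
        R = 1.0 + 0.05 * np.sin(2 * np.pi * t / 100.0)
        rep = dp.detect_cycles(make_timeseries(t, R), transient=500.0)
        assert rep.cyclic
        assert rep.amplitude == pytest.approx(0.1, rel=0.02)
        assert rep.period == pytest.approx(100.0, abs=1.0)

    def test_envelopes_bracket_the_series(self):
        t = np.arange(0.0, 2000.0, 1.0)
        R = 1.0 + 0.2 * np.sin(2 * np.pi * t / 250.0)
        rep = dp.detect_cycles(make_timeseries(t, R), transient=100.0)
        lo, hi = rep.envelopes["resource"]
        assert lo == pytest.approx(0.8, abs=1e-3)
        assert hi == pytest.approx(1.2, abs=1e-3)


class TestInvasion:
    """Mutant fate in a dynamically stable resident population.

    The resident sits below the one-trait CSS of Q (about 1.009 at
    P=1), so mutants between the resident and the CSS are predicted to
    invade and mutants on the far side to fail -- matching the sign of
    the selection gradient.
    """

    OPTS = dp.EBTOptions(delta_t_cohort=2.0)

    def test_neutral_mutant_share_drifts_below_tolerance(self):
        out = dp.invasion_experiment(
            dp.ModelParams(Q=0.95), ("Q", 0.95), N, t_attractor=200.0,
            t_invasion=12000.0, options=self.OPTS,
            introduce_at_resource_max=False,
        )
        assert out.outcome == "neutral"
        assert abs(out.growth_rate) < 1e-5

    @pytest.mark.parametrize(
        "mutant_q, expected",
        [(0.98, "invades_and_replaces"), (0.90, "fails")],
    )
    def test_outcome_agrees_with_selection_gradient_sign(self, mutant_q, expected):
        resident = dp.ModelParams(Q=0.95)
        out = dp.invasion_experiment(
            resident, ("Q", mutant_q), N, t_attractor=200.0,
            t_invasion=6000.0, options=self.OPTS,
            introduce_at_resource_max=False,
        )
        assert out.outcome == expected
        # cross-validation against the analytic invasion fitness
        eq = dp.solve_equilibrium(resident, N)
        r0 = dp.mutant_R0(resident.replace(Q=mutant_q), eq.R_tilde, N)
        assert (r0 > 1) == (expected == "invades_and_replaces")


def test_timeseries_frame_roundtrip(stable_run, tmp_path):
    f = tmp_path / "ts.csv"
    stable_run.to_csv(f)
    import pandas as pd

    df = pd.read_csv(f)
    assert {"time", "resource", "juvenile_biomass", "adult_biomass"} <= set(
        df.columns
    )
    assert len(df) == len(stable_run.time)
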