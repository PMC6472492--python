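"""Shared fixtures.

The expensive objects (equilibria, joint singular strategies, long EBT
runs) are session-scoped so that acceptance-level and unit-level tests
share one computation.
"""

import numpy as np
import pytest
from hypothesis import settings

import debpop as dp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def numerics():
    return dp.NumericsConfig()


@pytest.fixture(scope="session")
def p_default():
    return dp.ModelParams()


@pytest.fixture(scope="session")
def eq_default(p_default, numerics):
    return dp.solve_equilibrium(p_default, numerics)


@pytest.fixture(scope="session")
def joint_css_default(p_default, numerics):
    """Joint CSS of (Q, P) at the default parameterization."""
    return dp.find_joint_css(p_default, numerics)


@pytest.fixture(scope="session")
def joint_css_small_birth(p_default, numerics):
    """Joint CSS with size at birth reduced to 0.05 g."""
    return dp.find_joint_css(p_default.replace(s_b=0.05), numerics,
                             start=(0.9, 0.9))


@pytest.fixture(scope="session")
def cyclic_run(numerics):
    """Long EBT run in the adult-driven-cycle regime (Q=1.2, P=1).

    Started from the (unstable) equilibrium with a 1% density kick;
    30,000 days leaves a 10,000-day window after the 20,000-day
    transient, about two full cycle periods.
    """
    p = dp.ModelParams(Q=1.2)
    eq = dp.solve_equilibrium(p, dp.NumericsConfig())
    state = dp.initial_state_from_equilibrium(eq, p, perturbation=0.01)
    ts = dp.simulate(p, 30000.0, initial_state=state)
    return p, eq, ts


@pytest.fixture(scope="session")
def stable_run(p_default, eq_default):
    """EBT run at the (stable) default equilibrium with a 5% kick."""
    state = dp.initial_state_from_equilibrium(eq_default, p_default,
                                              perturbation=0.05)
    ts = dp.simulate(p_default, 6000.0, initial_state=state)
    return ts


def make_timeseries(time, resource):
    """Minimal PopulationTimeSeries wrapper for synthetic series."""
    z = np.zeros((1, len(time)))
    return dp.PopulationTimeSeries(
        time=np.asarray(time, dtype=float),
        resource=np.asarray(resource, dtype=float),
        juvenile_biomass_by_lineage=z,
        adult_biomass_by_lineage=z.copy(),
        birth_rate_by_lineage=z.copy(),
        n_cohorts=np.zeros(len(time), dtype=int),
        params=(dp.ModelParams(),),
        final_state=dp.EBTState(
            R=float(resource[-1]),
            mass=np.array([]), density=np.array([]),
            age=np.array([]), lineage=np.array([], dtype=np.int64),
        ),
    )
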