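"""Escalator Boxcar Train (EBT) simulation of the full size distribution.

The population is represented by cohorts of similarly sized individuals.
Within a cohort-closure window each cohort's mean body mass grows by
g(R, m) and its density declines by mortality mu(R, m) (including
starvation), while the shared resource follows semi-chemostat renewal
minus total consumption.  Newborns produced during a window are pooled
into a boundary cohort that is closed at the end of the window and
inserted at the birth size (a first-order EBT variant).

This is the tool for everything the equilibrium map cannot do:
population cycles, stability classification by perturbation, and
explicit mutant-invasion experiments in which a rare second lineage
with different scaling exponents competes through the shared resource.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .params import ModelParams, NumericsConfig

__all__ = [
    "EBTOptions",
    "EBTState",
    "Cohort",
    "PopulationTimeSeries",
    "CycleReport",
    "InvasionOutcome",
    "simulate",
    "detect_cycles",
    "invasion_experiment",
    "initial_state_from_equilibrium",
    "cycle_statistics_for_equilibrium",
    "CohortOverflowError",
]

RESIDENT, MUTANT = 0, 1
_LINEAGE_NAMES = ("resident", "mutant")


class CohortOverflowError(RuntimeError):
    """Cohort count exceeded the configured cap.

    Usually means the closure interval is too short for the configured
    extinction threshold; increase ``delta_t_cohort`` (or the threshold,
    or the cap).
    """


@dataclass(frozen=True)
class EBTOptions:
    """Numerical settings of the cohort simulator.

    delta_t_cohort : float
        Boundary-cohort closure interval (days): newborns within a
        window are pooled into one cohort at the birth size.
    dt_max : float
        Maximum internal RK4 step (days).
    extinction_relative : float
        Cohorts are dropped once their density falls below this
        fraction of the initial total density.
    max_cohorts : int
        Hard cap on the number of simultaneously tracked cohorts.
    record_every : float
        Output sampling interval (days, rounded to whole windows).
    snapshot_every : float or None
        If set, store full cohort snapshots at this interval.
    """

    delta_t_cohort: float = 1.0
    dt_max: float = 0.5
    extinction_relative: float = 1e-12
    max_cohorts: int = 20000
    record_every: float = 1.0
    snapshot_every: float | None = None


@dataclass
class Cohort:
    """One cohort: density (per unit volume), mean mass (g), age (days)."""

    density: float
    mass: float
    age: float = 0.0
    lineage: int = RESIDENT


@dataclass
class EBTState:
    """Full simulator state: resource plus cohort arrays."""

    R: float
    mass: np.ndarray
    density: np.ndarray
    age: np.ndarray
    lineage: np.ndarray

    @classmethod
    def from_cohorts(cls, R: float, cohorts: Sequence[Cohort]) -> "EBTState":
        return cls(
            R=float(R),
            mass=np.array([c.mass for c in cohorts], dtype=float),
            density=np.array([c.density for c in cohorts], dtype=float),
            age=np.array([c.age for c in cohorts], dtype=float),
            lineage=np.array([c.lineage for c in cohorts], dtype=np.int64),
        )

    def copy(self) -> "EBTState":
        return EBTState(self.R, self.mass.copy(), self.density.copy(),
                        self.age.copy(), self.lineage.copy())


@dataclass
class PopulationTimeSeries:
    """Recorded output of one EBT run.

    Per-lineage biomass arrays have shape (n_lineages, n_times); for a
    single-lineage run the convenience properties return 1-D views.
    """

    time: np.ndarray
    resource: np.ndarray
    juvenile_biomass_by_lineage: np.ndarray
    adult_biomass_by_lineage: np.ndarray
    birth_rate_by_lineage: np.ndarray
    n_cohorts: np.ndarray
    params: tuple[ModelParams, ...]
    final_state: EBTState = field(repr=False)
    snapshots: list[pd.DataFrame] = field(default_factory=list, repr=False)

    @property
    def juvenile_biomass(self) -> np.ndarray:
        return self.juvenile_biomass_by_lineage.sum(axis=0)

    @property
    def adult_biomass(self) -> np.ndarray:
        return self.adult_biomass_by_lineage.sum(axis=0)

    @property
    def total_biomass(self) -> np.ndarray:
        return self.juvenile_biomass + self.adult_biomass

    @property
    def total_biomass_by_lineage(self) -> np.ndarray:
        return self.juvenile_biomass_by_lineage + self.adult_biomass_by_lineage

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.time, "resource": self.resource,
             "n_cohorts": self.n_cohorts}
        for l, p in enumerate(self.params):
            tag = _LINEAGE_NAMES[l] if len(self.params) > 1 else ""
            suff = f"_{tag}" if tag else ""
            d[f"juvenile_biomass{suff}"] = self.juvenile_biomass_by_lineage[l]
            d[f"adult_biomass{suff}"] = self.adult_biomass_by_lineage[l]
            d[f"birth_rate{suff}"] = self.birth_rate_by_lineage[l]
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _lineage_derivs(R, mass, dens, idx, p: ModelParams):
    """Vital rates of one lineage's cohorts at resource density R."""
    m = np.minimum(mass[idx], p.s_m)
    d = dens[idx]
    fr = R / (R + p.H)
    ingest = p.M * (m / p.ref_mass_ingestion) ** p.Q * fr
    om = p.sigma * ingest - p.T * (m / p.ref_mass_maintenance) ** p.P
    omp = np.maximum(om, 0.0)
    L = np.clip((m - p.s_j) / (p.s_m - p.s_j), 0.0, 1.0)
    kap = 1.0 - 3.0 * L * L + 2.0 * L * L * L
    g = kap * omp
    births = float(np.sum((1.0 - kap) * omp * d)) / p.s_b
    mu = p.mu_c + np.where(m < p.s_j, p.mu_j, p.mu_a) - (om - omp) / m
    consumption = float(np.sum(ingest * d))
    return g, -mu * d, births, consumption


def simulate(
    params: ModelParams | Sequence[ModelParams],
    t_max: float,
    initial_state: EBTState | None = None,
    options: EBTOptions | None = None,
    n: NumericsConfig | None = None,
) -> PopulationTimeSeries:
    """Run the cohort simulation for ``t_max`` days.

    Parameters
    ----------
    params : ModelParams or sequence of ModelParams
        One parameter set per lineage (index = lineage tag in the
        state).  Lineages interact only through the shared resource.
    t_max : float
        Simulated time span (days).
    initial_state : EBTState, optional
        Defaults to a resource at Rmax plus a single newborn cohort of
        density 0.01 per unit volume.
    options : EBTOptions, optional
    n : NumericsConfig, optional
        Unused by the fixed-step core; accepted for interface symmetry.
    """
    plist = tuple(params) if isinstance(params, (list, tuple)) else (params,)
    if options is None:
        options = EBTOptions()
    p0 = plist[0]
    if initial_state is None:
        initial_state = EBTState.from_cohorts(
            p0.Rmax, [Cohort(density=0.01, mass=p0.s_b)]
        )
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if np.any(initial_state.density < 0) or initial_state.R < 0:
        raise ValueError("initial state must be nonnegative")
    if initial_state.lineage.size and initial_state.lineage.max() >= len(plist):
        raise ValueError("lineage tag exceeds the number of parameter sets")

    dt_c = options.delta_t_cohort
    n_windows = int(np.ceil(t_max / dt_c))
    n_sub = max(1, int(np.ceil(dt_c / options.dt_max)))
    dt = dt_c / n_sub
    record_stride = max(1, int(round(options.record_every / dt_c)))
    snap_stride = (
        None
        if options.snapshot_every is None
        else max(1, int(round(options.snapshot_every / dt_c)))
    )

    st = initial_state.copy()
    nlin = len(plist)
    threshold = options.extinction_relative * float(np.sum(st.density))

    def pack(R, Bacc, mass, dens):
        return np.concatenate([[R], Bacc, mass, dens])

    def derivs(y, idx_by_lin, ncoh):
        R = max(y[0], 0.0)
        mass = y[1 + nlin : 1 + nlin + ncoh]
        dens = np.maximum(y[1 + nlin + ncoh :], 0.0)
        dmass = np.zeros(ncoh)
        ddens = np.zeros(ncoh)
        dB = np.zeros(nlin)
        dR = p0.delta * (p0.Rmax - R)
        for l, idx in enumerate(idx_by_lin):
            if idx.size == 0:
                continue
            g, dd, births, cons = _lineage_derivs(R, mass, dens, idx, plist[l])
            dmass[idx] = g
            ddens[idx] = dd
            dB[l] = births
            dR -= plist[l].chi * cons
        return np.concatenate([[dR], dB, dmass, ddens])

    times, res, ncoh_out = [], [], []
    juv = [[] for _ in range(nlin)]
    adu = [[] for _ in range(nlin)]
    brate = [[] for _ in range(nlin)]
    snapshots: list[pd.DataFrame] = []

    def record(t):
        times.append(t)
        res.append(st.R)
        ncoh_out.append(st.mass.size)
        for l in range(nlin):
            sel = st.lineage == l
            m, d = st.mass[sel], st.density[sel]
            is_juv = m < plist[l].s_j
            juv[l].append(float(np.sum(m[is_juv] * d[is_juv])))
            adu[l].append(float(np.sum(m[~is_juv] * d[~is_juv])))

    def snapshot(t):
        snapshots.append(
            pd.DataFrame(
                {
                    "time": t,
                    "cohort_age": st.age,
                    "mass": st.mass,
                    "density": st.density,
                    "lineage": [_LINEAGE_NAMES[l] for l in st.lineage],
                }
            )
        )

    record(0.0)
    for l in range(nlin):
        brate[l].append(0.0)
    if snap_stride is not None:
        snapshot(0.0)

    t = 0.0
    for w in range(1, n_windows + 1):
        ncoh = st.mass.size
        idx_by_lin = [np.flatnonzero(st.lineage == l) for l in range(nlin)]
        y = pack(st.R, np.zeros(nlin), st.mass, st.density)
        for _ in range(n_sub):
            k1 = derivs(y, idx_by_lin, ncoh)
            k2 = derivs(y + 0.5 * dt * k1, idx_by_lin, ncoh)
            k3 = derivs(y + 0.5 * dt * k2, idx_by_lin, ncoh)
            k4 = derivs(y + dt * k3, idx_by_lin, ncoh)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = w * dt_c

        st.R = max(float(y[0]), 0.0)
        Bacc = y[1 : 1 + nlin]
        st.mass = y[1 + nlin : 1 + nlin + ncoh]
        st.density = np.maximum(y[1 + nlin + ncoh :], 0.0)
        st.age = st.age + dt_c

        # close the boundary cohorts: pool the window's newborns at s_b
        new_m, new_d, new_l = [], [], []
        for l in range(nlin):
            if Bacc[l] > 0.0:
                new_m.append(plist[l].s_b)
                new_d.append(Bacc[l])
                new_l.append(l)
        if new_m:
            st.mass = np.concatenate([st.mass, new_m])
            st.density = np.concatenate([st.density, new_d])
            st.age = np.concatenate([st.age, np.zeros(len(new_m))])
            st.lineage = np.concatenate([st.lineage, np.array(new_l, dtype=np.int64)])

        keep = st.density > threshold
        if not np.all(keep):
            st.mass, st.density = st.mass[keep], st.density[keep]
            st.age, st.lineage = st.age[keep], st.lineage[keep]
        if st.mass.size > options.max_cohorts:
            raise CohortOverflowError(
                f"{st.mass.size} cohorts at t={t:.0f} exceeds the cap "
                f"{options.max_cohorts}; increase delta_t_cohort"
            )

        if w % record_stride == 0 or w == n_windows:
            record(t)
            for l in range(nlin):
                brate[l].append(float(Bacc[l]) / dt_c)
            if snap_stride is not None and w % snap_stride == 0:
                snapshot(t)

    return PopulationTimeSeries(
        time=np.asarray(times),
        resource=np.asarray(res),
        juvenile_biomass_by_lineage=np.asarray(juv),
        adult_biomass_by_lineage=np.asarray(adu),
        birth_rate_by_lineage=np.asarray(brate),
        n_cohorts=np.asarray(ncoh_out),
        params=plist,
        final_state=st,
        snapshots=snapshots,
    )


# ---------------------------------------------------------------------
# cycle detection and stability classification


@dataclass
class CycleReport:
    """Attractor classification of a (post-transient) time series."""

    cyclic: bool
    amplitude: float
    period: float
    envelopes: dict[str, tuple[float, float]]


def detect_cycles(
    ts: PopulationTimeSeries, transient: float, threshold: float = 0.01
) -> CycleReport:
    """Classify the attractor from the resource series after a transient.

    Cyclic iff the relative peak-to-trough resource amplitude
    (max - min)/mean exceeds ``threshold`` (default 1%).  The period is
    the mean spacing of resource peaks; envelopes are the min/max of
    each recorded series over the analysis window.
    """
    sel = ts.time >= transient
    if np.count_nonzero(sel) < 8:
        raise ValueError("too few samples after the transient")
    R = ts.resource[sel]
    tt = ts.time[sel]
    mean = float(np.mean(R))
    amp = float((R.max() - R.min()) / mean) if mean > 0 else 0.0
    cyclic = amp > threshold

    period = np.nan
    if cyclic:
        peaks, _ = find_peaks(R, prominence=0.25 * (R.max() - R.min()))
        if len(peaks) >= 2:
            period = float(np.mean(np.diff(tt[peaks])))

    env = {"resource": (float(R.min()), float(R.max()))}
    for name, series in (
        ("juvenile_biomass", ts.juvenile_biomass),
        ("adult_biomass", ts.adult_biomass),
        ("total_biomass", ts.total_biomass),
    ):
        s = series[sel]
        env[name] = (float(s.min()), float(s.max()))
    return CycleReport(cyclic=cyclic, amplitude=amp, period=period, envelopes=env)


def initial_state_from_equilibrium(
    eq, p: ModelParams, spacing: float = 1.0, perturbation: float = 0.0
) -> EBTState:
    """Discretize the stationary age distribution into cohorts.

    Cohort k holds the individuals of age in [k, k+1)*spacing with
    density b~ F(a_k) * spacing and the trajectory's mass at a_k.
    ``perturbation`` multiplies all densities by (1 + perturbation) to
    kick the system off the fixed point for stability probing.
    """
    traj = eq.trajectory
    if traj is None or eq.extinct:
        raise ValueError("need a non-extinct equilibrium with its trajectory")
    a_end = traj.age[-1]
    ages = np.arange(0.5 * spacing, a_end, spacing)
    F = np.interp(ages, traj.age, traj.survivorship)
    m = np.interp(ages, traj.age, traj.size)
    dens = eq.b_tilde * F * spacing * (1.0 + perturbation)
    return EBTState(
        R=eq.R_tilde,
        mass=m[::-1].copy(),  # oldest first, newest last (insertion order)
        density=dens[::-1].copy(),
        age=ages[::-1].copy(),
        lineage=np.zeros(ages.size, dtype=np.int64),
    )


def cycle_statistics_for_equilibrium(
    eq,
    p: ModelParams,
    n: NumericsConfig | None = None,
    t_max: float = 20000.0,
    transient: float = 12000.0,
    perturbation: float = 0.01,
    options: EBTOptions | None = None,
    threshold: float = 0.01,
) -> dict:
    """Probe dynamic stability of an equilibrium by perturbed simulation.

    Returns a flat mapping (for sweep tables): ``stable``, ``period``
    and min/max envelopes of resource and stage biomasses.
    """
    state = initial_state_from_equilibrium(eq, p, perturbation=perturbation)
    ts = simulate(p, t_max, initial_state=state, options=options, n=n)
    rep = detect_cycles(ts, transient=transient, threshold=threshold)
    out = {"stable": not rep.cyclic, "period": rep.period,
           "amplitude": rep.amplitude}
    for k, (lo, hi) in rep.envelopes.items():
        out[f"{k}_min"] = lo
        out[f"{k}_max"] = hi
    return out


# ---------------------------------------------------------------------
# mutant invasion experiments


@dataclass
class InvasionOutcome:
    """Result of a mutant-invasion experiment.

    ``outcome`` is "invades_and_replaces", "fails" or "neutral" (no
    systematic growth either way; in this one-resource model sustained
    coexistence of distinct types is not expected, so a near-zero rate
    is reported as neutral/coexisting).  ``growth_rate`` is the fitted
    exponential rate (per day) of the mutant biomass share.
    """

    outcome: str
    growth_rate: float
    mutant_share: np.ndarray
    time: np.ndarray
    timeseries: PopulationTimeSeries = field(repr=False)


def invasion_experiment(
    resident_p: ModelParams,
    mutant_trait: tuple[str, float],
    n: NumericsConfig | None = None,
    t_attractor: float = 5000.0,
    t_invasion: float = 20000.0,
    mutant_fraction: float = 1e-6,
    options: EBTOptions | None = None,
    rate_tol: float = 1e-5,
    introduce_at_resource_max: bool = True,
) -> InvasionOutcome:
    """Introduce a rare mutant into the resident attractor and watch its fate.

    The resident is started from its (possibly unstable) equilibrium
    state and run for ``t_attractor`` days to settle on its attractor.
    A mutant cohort carrying a different value of one scaling exponent
    is then injected at the birth size with ``mutant_fraction`` of the
    resident biomass -- by default at a resource maximum of the cycle,
    where newborns can grow.  The outcome is classified from the fitted
    exponential growth rate of the mutant biomass share over the second
    half of the invasion phase.
    """
    from .equilibrium import solve_equilibrium

    trait, value = mutant_trait
    mutant_p = resident_p.replace(**{trait: value})
    if options is None:
        options = EBTOptions()

    eq = solve_equilibrium(resident_p, n)
    if eq.extinct:
        raise ValueError("resident population is not viable")
    state = initial_state_from_equilibrium(
        eq, resident_p, spacing=options.delta_t_cohort, perturbation=0.01
    )
    burn = simulate(resident_p, t_attractor, initial_state=state, options=options)
    st = burn.final_state

    if introduce_at_resource_max:
        # advance to the next local resource maximum (at most one period)
        half = burn.resource[burn.time >= t_attractor / 2]
        r_hi = np.quantile(half, 0.95)
        for _ in range(4000):
            if st.R >= r_hi:
                break
            nxt = simulate(resident_p, options.delta_t_cohort,
                           initial_state=st, options=options)
            st = nxt.final_state

    resident_biomass = float(np.sum(st.mass * st.density))
    inject = mutant_fraction * resident_biomass / mutant_p.s_b
    st.mass = np.concatenate([st.mass, [mutant_p.s_b]])
    st.density = np.concatenate([st.density, [inject]])
    st.age = np.concatenate([st.age, [0.0]])
    st.lineage = np.concatenate([st.lineage, [MUTANT]])

    ts = simulate((resident_p, mutant_p), t_invasion, initial_state=st,
                  options=options)
    tot = ts.total_biomass_by_lineage
    share = tot[MUTANT] / np.maximum(tot.sum(axis=0), 1e-300)

    # skip the age-structure transient of the injected newborn cohort
    # (about two generations) before fitting the share growth rate
    sel = (ts.time >= 2.0 * t_invasion / 3.0) & (share > 0)
    if np.count_nonzero(sel) < 4 or share[-1] <= 0:
        rate = -np.inf
    else:
        rate = float(np.polyfit(ts.time[sel], np.log(share[sel]), 1)[0])

    if share[-1] > 0.5:
        outcome = "invades_and_replaces"
    elif rate > rate_tol:
        outcome = "invades_and_replaces"
    elif rate < -rate_tol:
        outcome = "fails"
    else:
        outcome = "neutral"
    return InvasionOutcome(outcome=outcome, growth_rate=rate,
                           mutant_share=share, time=ts.time, timeseries=ts)
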