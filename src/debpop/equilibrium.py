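"""Ecological equilibrium of the consumer-resource system.

At equilibrium the resource density R~ makes the expected lifetime
reproductive success of one recruit exactly one, R0(R~) = 1, and the
population birth rate b~ follows from the resource mass balance: the
stationary age distribution has density b~ F(a), so total consumption
b~ * chi * Theta_inf(R~) must equal the semi-chemostat renewal
G(R~) = delta (Rmax - R~), with Theta_inf the lifetime cumulative
ingestion of one recruit.

R0 is strictly increasing in R, so the root on (0, Rmax) is unique and
safely found by bracketing + Brent.  All stage-structured outputs are
survivorship-weighted integrals of the single life-history trajectory
at R~ -- no further integration is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .life_history import LifeHistoryTrajectory, integrate_life_history
from .params import ModelParams, NumericsConfig

__all__ = [
    "Equilibrium",
    "SweepTable",
    "solve_equilibrium",
    "population_outputs",
    "ecological_sweep",
    "EquilibriumError",
]

_DEFAULT_NUMERICS = NumericsConfig()


class EquilibriumError(RuntimeError):
    """Failure to bracket or converge on the equilibrium resource density."""


@dataclass
class Equilibrium:
    """Ecological equilibrium (or extinction marker) of the model.

    ``R_tilde`` is the equilibrium resource density (mg/L) solving
    R0 = 1; ``b_tilde`` the population birth rate (newborns/day per
    unit system volume).  Stage biomasses are standing stocks (g);
    the maturation and reproduction rates are biomass fluxes (g/day):
    ``b_tilde * F(a_j) * s_j`` (mass flux of individuals crossing the
    maturation size) and ``b_tilde * s_b`` (mass flux of newborns).
    ``asymptotic_size`` is the terminal body mass of the life-history
    trajectory at R~.  For an extinct population (R0(Rmax) <= 1) the
    marker has ``extinct=True``, ``R_tilde=Rmax`` and zero population.
    """

    params: ModelParams
    R_tilde: float
    b_tilde: float
    juvenile_biomass: float
    adult_biomass: float
    maturation_rate_biomass: float
    reproduction_rate_biomass: float
    asymptotic_size: float
    extinct: bool = False
    trajectory: LifeHistoryTrajectory | None = field(default=None, repr=False)

    @property
    def total_biomass(self) -> float:
        return self.juvenile_biomass + self.adult_biomass

    def as_row(self) -> dict:
        """Flat mapping of the equilibrium outputs (for tables/CSV)."""
        return {
            "R_tilde": self.R_tilde,
            "b_tilde": self.b_tilde,
            "juvenile_biomass": self.juvenile_biomass,
            "adult_biomass": self.adult_biomass,
            "total_biomass": self.total_biomass,
            "maturation_rate_biomass": self.maturation_rate_biomass,
            "reproduction_rate_biomass": self.reproduction_rate_biomass,
            "asymptotic_size": self.asymptotic_size,
            "extinct": self.extinct,
        }


def solve_equilibrium(
    p: ModelParams,
    n: NumericsConfig | None = None,
    r_guess: float | None = None,
) -> Equilibrium:
    """Solve the ecological equilibrium R0(R~) = 1 and the mass balance.

    Parameters
    ----------
    p, n : model parameters and numerical settings.
    r_guess : float, optional
        Warm-start value for R~; the bracket is first sought in a
        window around it (useful during sweeps and trait iteration).

    Returns
    -------
    Equilibrium
        With ``extinct=True`` if even a resource at Rmax cannot sustain
        replacement (R0(Rmax) <= 1).
    """
    if n is None:
        n = _DEFAULT_NUMERICS
    lo = 1e-6
    hi = p.Rmax * (1.0 - 1e-9)

    cache: dict[float, LifeHistoryTrajectory] = {}

    def f(R: float) -> float:
        traj = integrate_life_history(R, p, n)
        cache[R] = traj
        return traj.R0 - 1.0

    f_hi = f(hi)
    if f_hi <= 0.0:
        return Equilibrium(
            params=p, R_tilde=p.Rmax, b_tilde=0.0, juvenile_biomass=0.0,
            adult_biomass=0.0, maturation_rate_biomass=0.0,
            reproduction_rate_biomass=0.0, asymptotic_size=np.nan, extinct=True,
        )

    a, b = lo, hi
    fa = None
    if r_guess is not None and lo < r_guess < hi:
        ga, gb = max(lo, r_guess / 1.5), min(hi, r_guess * 1.5)
        fga, fgb = f(ga), f(gb)
        if fga < 0.0 < fgb:
            a, b, fa, f_hi = ga, gb, fga, fgb
    if fa is None:
        fa = f(a)
        if fa >= 0.0:
            raise EquilibriumError(
                f"R0 >= 1 already at R={a}: no positive lower bracket "
                "(check mortality and maintenance parameters)"
            )

    R_tilde = brentq(f, a, b, xtol=n.root_tol, rtol=1e-14)
    traj = cache.get(R_tilde) or integrate_life_history(R_tilde, p, n)

    b_tilde = p.delta * (p.Rmax - R_tilde) / (p.chi * traj.lifetime_ingestion)
    return _assemble(p, R_tilde, b_tilde, traj)


def _assemble(p: ModelParams, R_tilde: float, b_tilde: float,
              traj: LifeHistoryTrajectory) -> Equilibrium:
    out = population_outputs(traj, b_tilde, p)
    return Equilibrium(
        params=p, R_tilde=R_tilde, b_tilde=b_tilde, trajectory=traj, **out
    )


def population_outputs(
    traj: LifeHistoryTrajectory, b_tilde: float, p: ModelParams
) -> dict:
    """Stage-structured outputs of a stationary population.

    With stationary age-distribution density b~ F(a), stage biomasses
    are b~ * int s(a) F(a) da over the juvenile/adult age ranges; the
    maturation biomass flux is b~ F(a_j) s_j and the reproduction
    (newborn mass) flux is b~ s_b.
    """
    F_j = traj.survivorship_at_maturation
    return {
        "juvenile_biomass": b_tilde * traj.juvenile_mass_integral,
        "adult_biomass": b_tilde * traj.adult_mass_integral,
        "maturation_rate_biomass": (0.0 if F_j is None else b_tilde * F_j * p.s_j),
        "reproduction_rate_biomass": b_tilde * p.s_b,
        "asymptotic_size": traj.terminal_size,
    }


@dataclass
class SweepTable:
    """Equilibrium (and optional cycle-envelope) outputs along a parameter grid.

    ``table`` has one row per grid point; the swept parameter is the
    first column.  When cycle detection was requested the columns
    ``stable``, ``period`` and min/max envelopes of the resource and
    stage biomasses are present as well.
    """

    parameter: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def ecological_sweep(
    param_name: str,
    grid: Sequence[float],
    p: ModelParams,
    n: NumericsConfig | None = None,
    with_cycles: bool = False,
    cycle_kwargs: dict | None = None,
) -> SweepTable:
    """Solve the equilibrium along a one-parameter grid.

    With ``with_cycles=True``, each grid point additionally runs the
    cohort (EBT) simulator from a perturbed equilibrium state and
    records whether the equilibrium is dynamically stable, plus the
    min/max envelopes of resource and stage biomasses over the
    attractor.  Stability is decided by simulation (perturbation decay
    versus sustained oscillation), not by spectral analysis of the
    linearized system.
    """
    if n is None:
        n = _DEFAULT_NUMERICS
    grid = np.asarray(list(grid), dtype=float)
    if grid.size and not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("sweep grid must be strictly monotone")

    rows = []
    r_guess = None
    for value in grid:
        pi = p.replace(**{param_name: float(value)})
        try:
            eq = solve_equilibrium(pi, n, r_guess=r_guess)
        except EquilibriumError as err:
            warnings.warn(f"{param_name}={value}: {err}", stacklevel=2)
            continue
        if not eq.extinct:
            r_guess = eq.R_tilde
        row = {param_name: value, **eq.as_row()}
        if with_cycles and not eq.extinct:
            from .ebt import cycle_statistics_for_equilibrium

            row.update(
                cycle_statistics_for_equilibrium(eq, pi, n, **(cycle_kwargs or {}))
            )
        rows.append(row)
    return SweepTable(parameter=param_name, table=pd.DataFrame(rows))
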