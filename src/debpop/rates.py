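"""Individual-level rate functions of the DEB model.

Pure, stateless functions of resource density ``R`` (mg/L), body mass
``s`` (g) and a :class:`~debpop.params.ModelParams`.  Every other module
(life-history integration, equilibrium solving, cohort simulation)
composes these.

All public functions are vectorized over ``s`` (and ``R`` where it makes
sense) via numpy broadcasting; scalars in give Python floats out.

The model in brief: ingestion follows a Holling type-II functional
response with a power-law maximum ``M (s/s_rI)^Q``; assimilated intake
minus power-law maintenance ``T (s/s_rT)^P`` gives the biomass
production rate Omega (net-production DEB: maintenance is paid first).
Positive production is split between somatic growth and reproduction by
a smooth allocation function kappa(s); negative production is paid as
extra (starvation) mortality rather than shrinkage.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = [
    "ingestion_rate",
    "biomass_production",
    "omega_plus",
    "omega_minus",
    "allocation_fraction",
    "growth_rate",
    "fecundity_rate",
    "mortality_rate",
    "maintenance_resource_density",
    "resource_growth_rate",
]

#: relative overshoot of s_m tolerated before allocation_fraction errors
_SM_SLACK = 1e-6


def _check_mass(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("body mass s must be positive")
    return s


def _maybe_scalar(x: np.ndarray):
    return float(x) if np.ndim(x) == 0 else x


def ingestion_rate(R, s, p: ModelParams):
    """Resource ingestion rate I(R, s) in g/day.

    ``M (s/s_rI)^Q * R/(R+H)``: a Holling type-II functional response of
    resource density with half-saturation constant ``H``, saturating at
    the power-law maximum ingestion rate.
    """
    s = _check_mass(s)
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("resource density R must be nonnegative")
    out = p.M * (s / p.ref_mass_ingestion) ** p.Q * R / (R + p.H)
    return _maybe_scalar(out)


def biomass_production(R, s, p: ModelParams):
    """Net biomass production Omega(R, s) = sigma*I(R,s) - T*(s/s_rT)^P (g/day).

    The mass available for growth and reproduction per unit time;
    negative when food does not cover maintenance.
    """
    s = _check_mass(s)
    out = p.sigma * np.asarray(ingestion_rate(R, s, p)) - p.T * (
        s / p.ref_mass_maintenance
    ) ** p.P
    return _maybe_scalar(out)


def omega_plus(R, s, p: ModelParams):
    """Positive part max(Omega, 0) of the biomass production rate (g/day)."""
    return _maybe_scalar(np.maximum(np.asarray(biomass_production(R, s, p)), 0.0))


def omega_minus(R, s, p: ModelParams):
    """Negative part min(Omega, 0) of the biomass production rate (g/day)."""
    return _maybe_scalar(np.minimum(np.asarray(biomass_production(R, s, p)), 0.0))


def allocation_fraction(s, p: ModelParams):
    """Fraction kappa(s) of positive production allocated to growth.

    One for juveniles (s < s_j); for adults a cubic smoothstep
    ``1 - 3L^2 + 2L^3`` with L = (s - s_j)/(s_m - s_j), which decreases
    from one at maturation to zero at the maximum size with zero slope
    at both ends.  Tiny floating-point overshoot above s_m clamps to 0.
    """
    s = _check_mass(s)
    if np.any(s < p.s_b) or np.any(s > p.s_m * (1.0 + _SM_SLACK)):
        raise ValueError(f"body mass outside [s_b, s_m] = [{p.s_b}, {p.s_m}]")
    L = np.clip((s - p.s_j) / (p.s_m - p.s_j), 0.0, 1.0)
    out = 1.0 - 3.0 * L**2 + 2.0 * L**3
    return _maybe_scalar(out)


def growth_rate(R, s, p: ModelParams):
    """Somatic growth rate g(R, s) = kappa(s) * Omega+(R, s) in g/day.

    Zero under starvation (Omega <= 0) and zero at the maximum size
    (kappa(s_m) = 0): individuals never shrink.
    """
    out = np.asarray(allocation_fraction(s, p)) * np.asarray(omega_plus(R, s, p))
    return _maybe_scalar(out)


def fecundity_rate(R, s, p: ModelParams):
    """Per-capita fecundity b(R, s) = (1 - kappa(s)) Omega+(R, s)/s_b (offspring/day)."""
    out = (
        (1.0 - np.asarray(allocation_fraction(s, p)))
        * np.asarray(omega_plus(R, s, p))
        / p.s_b
    )
    return _maybe_scalar(out)


def mortality_rate(R, s, p: ModelParams):
    """Instantaneous mortality mu(R, s) per day.

    Background mortality mu_c plus stage-specific additions (mu_j below
    maturation, mu_a at and above), plus starvation mortality equal to
    the mass-specific biomass deficit -Omega-(R,s)/s when production is
    negative.
    """
    s = _check_mass(s)
    stage_extra = np.where(s < p.s_j, p.mu_j, p.mu_a)
    out = p.mu_c + stage_extra - np.asarray(omega_minus(R, s, p)) / s
    return _maybe_scalar(out)


def maintenance_resource_density(s, p: ModelParams):
    """Maintenance resource density MRD(s) in mg/L.

    The resource level at which assimilation exactly covers maintenance,
    Omega(MRD, s) = 0: the model's measure of size-dependent competitive
    ability (a superior competitor has a lower MRD).  Closed form
    ``H*theta/(sigma*M - theta)`` with
    ``theta = T (s/s_rT)^P / (s/s_rI)^Q``; returns ``inf`` where even
    saturating food cannot cover maintenance (theta >= sigma*M).

    For Q = P with a common reference mass theta is size-independent and
    the MRD is the same for every individual: competitive symmetry.
    """
    s = _check_mass(s)
    theta = p.T * (s / p.ref_mass_maintenance) ** p.P / (s / p.ref_mass_ingestion) ** p.Q
    cap = p.sigma * p.M
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(theta < cap, p.H * theta / (cap - theta), np.inf)
    return _maybe_scalar(out)


def resource_growth_rate(R, p: ModelParams):
    """Semi-chemostat resource renewal G(R) = delta*(Rmax - R) in mg/(L day)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("resource density R must be nonnegative")
    return _maybe_scalar(p.delta * (p.Rmax - R))
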