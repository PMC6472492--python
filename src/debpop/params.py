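"""Model parameterization and numerical settings.

:class:`ModelParams` is the single source of truth for one model instance:
the energetics constants of the individual-level dynamic energy budget
(DEB) model, the consumer size thresholds, the mortality rates and the
resource dynamics.  Defaults are the standard parameterization of the
size-structured consumer-resource model (a roach-like planktivorous fish
feeding on a shared zooplankton resource).

Units follow the conventional bookkeeping: consumer body mass in grams,
resource density in mg/L, time in days.  The constant ``chi`` converts
total consumer ingestion (g/day) into resource depletion (mg L^-1 day^-1);
it rescales only absolute population sizes, never per-capita quantities,
equilibrium resource density or any evolutionary output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ModelParams", "NumericsConfig", "DEFAULTS_FILE"]

DEFAULTS_FILE = Path(__file__).parent / "defaults.yaml"

#: guard range for the scaling exponents accepted from config files
_EXPONENT_GUARD = (0.0, 3.0)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the size-structured DEB consumer-resource model.

    Attributes
    ----------
    Rmax : float
        Maximum resource density (mg/L) of the semi-chemostat resource.
    delta : float
        Resource renewal rate (per day).
    Q : float
        Body-mass scaling exponent of maximum ingestion (dimensionless).
    P : float
        Body-mass scaling exponent of maintenance (dimensionless).
    M : float
        Maximum ingestion rate of an individual at the ingestion
        reference mass (g/day).
    T : float
        Maintenance rate of an individual at the maintenance reference
        mass (g/day).
    mu_c, mu_j, mu_a : float
        Background mortality, and additional juvenile and adult
        mortality (per day).
    sigma : float
        Assimilation efficiency (dimensionless, in (0, 1]).
    H : float
        Half-saturation density of the Holling type-II functional
        response (mg/L).
    s_b, s_j, s_m : float
        Body mass at birth, at maturation, and the maximum body mass (g).
    s_r : float
        Reference body mass (g): the rotation point of the ingestion and
        maintenance power laws.  The default equals ``s_j``, which makes
        the exponents a juvenile--adult trade-off.
    s_rI, s_rT : float or None
        Optional separate reference masses for ingestion and maintenance
        (g); ``None`` means "use ``s_r``".
    chi : float
        Ingestion-to-resource-depletion conversion constant (mg L^-1
        per g), default 1.
    """

    Rmax: float = 30.0
    delta: float = 0.01
    Q: float = 1.0
    P: float = 1.0
    M: float = 0.1
    T: float = 0.01
    mu_c: float = 0.0015
    mu_j: float = 0.0
    mu_a: float = 0.0
    sigma: float = 0.5
    H: float = 3.0
    s_b: float = 0.1
    s_j: float = 1.0
    s_m: float = 10.0
    s_r: float = 1.0
    s_rI: float | None = None
    s_rT: float | None = None
    chi: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.s_b < self.s_j < self.s_m):
            raise ValueError(
                f"size thresholds must satisfy 0 < s_b < s_j < s_m, got "
                f"s_b={self.s_b}, s_j={self.s_j}, s_m={self.s_m}"
            )
        if not (0.0 < self.sigma <= 1.0):
            raise ValueError(f"sigma must be in (0, 1], got {self.sigma}")
        for name in ("Rmax", "delta", "M", "T", "mu_c", "mu_j", "mu_a", "H", "s_r", "chi"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.s_r <= 0:
            raise ValueError("s_r must be positive")
        for name in ("s_rI", "s_rT"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not (self.s_b <= self.s_r <= self.s_m):
            warnings.warn(
                "reference mass s_r outside [s_b, s_m]: the juvenile-adult "
                "trade-off in the scaling exponents degenerates and selection "
                "on Q and P may run away",
                stacklevel=2,
            )
        # a reference-sized individual must be viable at saturating food
        ref_ingest = self.sigma * self.M * (self.s_r / self.ref_mass_ingestion) ** self.Q
        ref_maint = self.T * (self.s_r / self.ref_mass_maintenance) ** self.P
        if ref_ingest <= ref_maint:
            raise ValueError(
                "sigma*M must exceed T at the reference mass, otherwise no "
                "individual can ever cover maintenance"
            )

    @property
    def ref_mass_ingestion(self) -> float:
        """Reference mass used by the maximum-ingestion power law (g)."""
        return self.s_r if self.s_rI is None else self.s_rI

    @property
    def ref_mass_maintenance(self) -> float:
        """Reference mass used by the maintenance power law (g)."""
        return self.s_r if self.s_rT is None else self.s_rT

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # drop the "inherit s_r" sentinels from the flat mapping
        if d["s_rI"] is None:
            del d["s_rI"]
        if d["s_rT"] is None:
            del d["s_rT"]
        return d

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(
                f"unknown parameter name(s): {', '.join(unknown)}; "
                f"valid names are {', '.join(sorted(known))}"
            )
        for exp in ("Q", "P"):
            if exp in mapping:
                lo, hi = _EXPONENT_GUARD
                if not (lo <= float(mapping[exp]) <= hi):
                    raise ValueError(
                        f"{exp}={mapping[exp]} outside guard range [{lo}, {hi}]"
                    )
        return cls(**{k: (None if v is None else float(v)) for k, v in mapping.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ValueError(f"expected a mapping of parameters in {path}")
        return cls.from_dict(data)

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class NumericsConfig:
    """Numerical settings shared by the ODE and root-finding machinery.

    Attributes
    ----------
    rel_tol, abs_tol : float
        Relative/absolute tolerances of the life-history ODE integrator.
    survival_cutoff : float
        Life-history integration stops once survivorship drops below
        this value; with background mortality 0.0015/day the horizon is
        then about 1.4e4 days.
    max_age : float
        Hard cap on the integration horizon (days).
    root_tol : float
        Bracketing tolerance for scalar root solves (equilibrium
        resource density, singular-strategy location).
    fd_step : float
        Central finite-difference step for selection gradients, in trait
        (exponent) units.
    gradient_tol : float
        Convergence tolerance on the selection gradient for singular
        point searches.  Finite-difference gradients carry noise of
        order rel_tol/fd_step, so this is necessarily much looser than
        ``root_tol``.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    survival_cutoff: float = 1e-9
    max_age: float = 1e5
    root_tol: float = 1e-10
    fd_step: float = 1e-4
    gradient_tol: float = 1e-4

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.survival_cutoff >= 1:
            raise ValueError("survival_cutoff must be < 1")

    def replace(self, **changes: Any) -> "NumericsConfig":
        return dataclasses.replace(self, **changes)
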