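"""Adaptive dynamics of the body-size scaling exponents.

Invasion fitness is the lifetime reproductive success R0 of a rare
mutant with scaling exponents (Q_m, P_m) living in the resident's
equilibrium environment -- which, in this model, is fully described by
the single number R~.  The selection gradient is the derivative of
mutant R0 with respect to the mutant trait at the resident value;
singular strategies are its roots.  Because the environment is
one-dimensional and R0 is increasing in R, an interior singular point
minimizes the equilibrium resource density over the resident trait,
and every evolutionarily stable strategy is also convergence stable
(a continuously stable strategy, CSS).

Gradients are central finite differences (step ``fd_step``); each
resident evaluation re-solves the ecological equilibrium.  The joint
CSS of (Q, P) is found as a simultaneous root of both gradients by a
damped Newton iteration with finite-difference Jacobian -- the two
evolutionary isoclines lie nearly on top of each other, which makes
alternating one-trait relaxation ill-conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibrium import Equilibrium, SweepTable, solve_equilibrium
from .life_history import integrate_life_history
from .params import ModelParams, NumericsConfig
from . import rates

__all__ = [
    "SingularPoint",
    "IsoclineCurve",
    "mutant_R0",
    "selection_gradient",
    "find_css",
    "find_joint_css",
    "evolutionary_isocline",
    "css_sweep",
    "reproduction_scaling_check",
    "CSSNotFoundError",
]

_DEFAULT_NUMERICS = NumericsConfig()

#: curvature below this magnitude is reported as degenerate/near-neutral
_CURVATURE_FLOOR = 1e-6

#: default resident-trait bracket for singular-point searches
_DEFAULT_BRACKET = (0.5, 1.6)


class CSSNotFoundError(RuntimeError):
    """No singular point in the search bracket (endpoint gradients attached)."""

    def __init__(self, message: str, gradients=None):
        super().__init__(message)
        self.gradients = gradients


@dataclass
class SingularPoint:
    """A located singular strategy with its classification.

    ``traits`` maps trait name(s) to the singular value(s).
    ``evolutionarily_stable`` is decided from the sign of the
    second-order mutant curvature of R0 (negative: a fitness maximum,
    uninvadable); ``convergence_stable`` from the slope of the
    selection gradient across residents (negative: attracting).  Either
    is None when the underlying curvature is below the degeneracy
    floor.  ``resource_minimized`` records the direct check that the
    equilibrium resource density is locally minimal at the point.
    """

    traits: dict[str, float]
    gradient: dict[str, float]
    second_derivative: dict[str, float]
    evolutionarily_stable: bool | None
    convergence_stable: bool | None
    resource_minimized: bool | None
    equilibrium: Equilibrium = field(repr=False)

    @property
    def is_css(self) -> bool | None:
        if self.evolutionarily_stable is None or self.convergence_stable is None:
            return None
        return self.evolutionarily_stable and self.convergence_stable

    @property
    def common_value(self) -> float:
        """Mean of the singular trait values (for joint points, Q~=P)."""
        return float(np.mean(list(self.traits.values())))


@dataclass
class IsoclineCurve:
    """CSS value of one evolving trait along a grid of the other trait."""

    evolving: str
    fixed: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def mutant_R0(
    mutant_p: ModelParams,
    resident_R: float,
    n: NumericsConfig | None = None,
) -> float:
    """Invasion fitness: lifetime reproductive success of a mutant at R~.

    The mutant experiences the resident's equilibrium resource density;
    R0 > 1 means the mutant can invade.
    """
    return integrate_life_history(resident_R, mutant_p, n).R0


def _gradient_one(trait: str, p: ModelParams, R: float, n: NumericsConfig) -> float:
    h = n.fd_step
    up = mutant_R0(p.replace(**{trait: getattr(p, trait) + h}), R, n)
    dn = mutant_R0(p.replace(**{trait: getattr(p, trait) - h}), R, n)
    return (up - dn) / (2.0 * h)


def selection_gradient(
    trait: str,
    p: ModelParams,
    n: NumericsConfig | None = None,
    equilibrium: Equilibrium | None = None,
) -> float:
    """d R0(mutant)/d trait at the resident value, in the resident environment.

    Central finite difference with step ``n.fd_step``; the resident's
    equilibrium is solved first (or passed in) and held fixed.
    """
    if n is None:
        n = _DEFAULT_NUMERICS
    if equilibrium is None:
        equilibrium = solve_equilibrium(p, n)
    if equilibrium.extinct:
        raise ValueError("resident population is extinct; no selection gradient")
    return _gradient_one(trait, p, equilibrium.R_tilde, n)


def _second_derivative(trait: str, p: ModelParams, R: float, n: NumericsConfig,
                       h: float | None = None) -> float:
    """Mutant fitness curvature d2 R0 / d trait2 at the resident value."""
    if h is None:
        h = 100.0 * n.fd_step
    x = getattr(p, trait)
    up = mutant_R0(p.replace(**{trait: x + h}), R, n)
    mid = mutant_R0(p, R, n)
    dn = mutant_R0(p.replace(**{trait: x - h}), R, n)
    return (up - 2.0 * mid + dn) / h**2


def _classify(sd: float) -> bool | None:
    if abs(sd) <= _CURVATURE_FLOOR:
        return None
    return sd < 0.0


def find_css(
    trait: str,
    p: ModelParams,
    n: NumericsConfig | None = None,
    bracket: tuple[float, float] = _DEFAULT_BRACKET,
) -> SingularPoint:
    """Locate and classify the singular strategy of one scaling exponent.

    Finds the root of the selection gradient over the resident trait by
    Brent's method (every evaluation re-solves the resident
    equilibrium, warm-starting the resource bracket), then classifies:
    evolutionary stability from the mutant curvature, convergence
    stability from the gradient slope across residents, and the
    resource-minimization property of the singular point directly.
    """
    if n is None:
        n = _DEFAULT_NUMERICS
    r_guess: list[float | None] = [None]

    def resident_eq(x: float) -> Equilibrium:
        eq = solve_equilibrium(p.replace(**{trait: x}), n, r_guess=r_guess[0])
        if eq.extinct:
            raise CSSNotFoundError(
                f"resident extinct at {trait}={x}; shrink the bracket"
            )
        r_guess[0] = eq.R_tilde
        return eq

    def g(x: float) -> float:
        eq = resident_eq(x)
        return _gradient_one(trait, p.replace(**{trait: x}), eq.R_tilde, n)

    ga, gb = g(bracket[0]), g(bracket[1])
    if np.sign(ga) == np.sign(gb):
        raise CSSNotFoundError(
            f"selection gradient of {trait} has no sign change on "
            f"{bracket}: g({bracket[0]})={ga:.4g}, g({bracket[1]})={gb:.4g}",
            gradients=(ga, gb),
        )
    x_star = brentq(g, *bracket, xtol=max(n.root_tol, 1e-12))

    eq = resident_eq(x_star)
    p_star = p.replace(**{trait: x_star})
    grad = _gradient_one(trait, p_star, eq.R_tilde, n)
    sd_mut = _second_derivative(trait, p_star, eq.R_tilde, n)

    # convergence stability and R~ minimization from nearby residents
    k = 100.0 * n.fd_step
    eq_up = solve_equilibrium(p.replace(**{trait: x_star + k}), n, r_guess=eq.R_tilde)
    eq_dn = solve_equilibrium(p.replace(**{trait: x_star - k}), n, r_guess=eq.R_tilde)
    g_up = _gradient_one(trait, p.replace(**{trait: x_star + k}), eq_up.R_tilde, n)
    g_dn = _gradient_one(trait, p.replace(**{trait: x_star - k}), eq_dn.R_tilde, n)
    slope = (g_up - g_dn) / (2.0 * k)
    resource_min = eq_up.R_tilde >= eq.R_tilde and eq_dn.R_tilde >= eq.R_tilde

    return SingularPoint(
        traits={trait: float(x_star)},
        gradient={trait: float(grad)},
        second_derivative={trait: float(sd_mut)},
        evolutionarily_stable=_classify(sd_mut),
        convergence_stable=_classify(slope),
        resource_minimized=bool(resource_min),
        equilibrium=eq,
    )


def _gradient_vector(p: ModelParams, n: NumericsConfig,
                     r_guess: float | None) -> tuple[np.ndarray, Equilibrium]:
    eq = solve_equilibrium(p, n, r_guess=r_guess)
    if eq.extinct:
        raise CSSNotFoundError(f"resident extinct at Q={p.Q}, P={p.P}")
    G = np.array(
        [_gradient_one("Q", p, eq.R_tilde, n), _gradient_one("P", p, eq.R_tilde, n)]
    )
    return G, eq


def find_joint_css(
    p: ModelParams,
    n: NumericsConfig | None = None,
    start: tuple[float, float] = (1.1, 1.1),
    max_iter: int = 40,
    step_cap: float = 0.1,
) -> SingularPoint:
    """Simultaneous root of both selection gradients over (Q, P).

    Damped Newton iteration with forward-difference Jacobian (step
    1e-3 in trait units), each evaluation re-solving the resident
    equilibrium.  Converges when the trait step falls below 1e-6; the
    result is re-verified with a fresh equilibrium solve and the
    gradient checked against ``n.gradient_tol``.
    """
    if n is None:
        n = _DEFAULT_NUMERICS
    x = np.array(start, dtype=float)
    r_guess = None
    jac_h = 1e-3
    G, eq = _gradient_vector(p.replace(Q=x[0], P=x[1]), n, r_guess)
    r_guess = eq.R_tilde
    converged = False
    for _ in range(max_iter):
        J = np.empty((2, 2))
        for j, tr in enumerate(("Q", "P")):
            xp = x.copy()
            xp[j] += jac_h
            Gp, _ = _gradient_vector(p.replace(Q=xp[0], P=xp[1]), n, r_guess)
            J[:, j] = (Gp - G) / jac_h
        try:
            step = np.linalg.solve(J, -G)
        except np.linalg.LinAlgError as err:
            raise CSSNotFoundError(f"singular Jacobian at Q={x[0]}, P={x[1]}") from err
        step = np.clip(step, -step_cap, step_cap)

        # damped update: backtrack while the gradient norm grows
        norm0 = float(np.linalg.norm(G))
        lam = 1.0
        for _ in range(5):
            x_new = x + lam * step
            G_new, eq_new = _gradient_vector(
                p.replace(Q=x_new[0], P=x_new[1]), n, r_guess
            )
            if np.linalg.norm(G_new) < max(norm0, n.gradient_tol) * 2.0:
                break
            lam *= 0.5
        x, G, eq = x_new, G_new, eq_new
        r_guess = eq.R_tilde
        if float(np.max(np.abs(lam * step))) < 1e-6:
            converged = True
            break
    if not converged:
        raise CSSNotFoundError(
            f"joint CSS iteration did not converge from start {start}; "
            f"last point Q={x[0]:.6f}, P={x[1]:.6f}, |G|={np.linalg.norm(G):.3g}"
        )

    # root-finding hygiene: fresh verification solve
    p_star = p.replace(Q=float(x[0]), P=float(x[1]))
    G_fin, eq_fin = _gradient_vector(p_star, n, None)
    if float(np.max(np.abs(G_fin))) > 10.0 * n.gradient_tol:
        warnings.warn(
            f"joint CSS verification gradient {G_fin} exceeds tolerance "
            f"{n.gradient_tol}",
            stacklevel=2,
        )
    sd = {
        tr: _second_derivative(tr, p_star, eq_fin.R_tilde, n) for tr in ("Q", "P")
    }
    ev = {tr: _classify(v) for tr, v in sd.items()}
    ev_flag = (
        None if any(v is None for v in ev.values()) else all(ev.values())
    )
    return SingularPoint(
        traits={"Q": float(x[0]), "P": float(x[1])},
        gradient={"Q": float(G_fin[0]), "P": float(G_fin[1])},
        second_derivative={k: float(v) for k, v in sd.items()},
        evolutionarily_stable=ev_flag,
        convergence_stable=None,  # 2-D attractivity not asserted; see docs
        resource_minimized=None,
        equilibrium=eq_fin,
    )


def evolutionary_isocline(
    evolving: str,
    fixed_grid: Sequence[float],
    p: ModelParams,
    n: NumericsConfig | None = None,
    bracket: tuple[float, float] = _DEFAULT_BRACKET,
    bracket_width: float = 0.08,
) -> IsoclineCurve:
    """CSS value of ``evolving`` along a grid of the other exponent.

    Continuation: each grid point warm-starts its search bracket from
    the previous CSS value, falling back to the full bracket when the
    narrow one fails.
    """
    if n is None:
        n = _DEFAULT_NUMERICS
    fixed = "P" if evolving == "Q" else "Q"
    rows = []
    prev: float | None = None
    for v in fixed_grid:
        pv = p.replace(**{fixed: float(v)})
        sp = None
        if prev is not None:
            try:
                sp = find_css(evolving, pv, n,
                              bracket=(prev - bracket_width, prev + bracket_width))
            except CSSNotFoundError:
                sp = None
        if sp is None:
            sp = find_css(evolving, pv, n, bracket=bracket)
        prev = sp.traits[evolving]
        rows.append(
            {
                fixed: float(v),
                f"{evolving}_css": prev,
                "gradient": sp.gradient[evolving],
                "R_tilde": sp.equilibrium.R_tilde,
                "is_css": sp.is_css,
            }
        )
    return IsoclineCurve(evolving=evolving, fixed=fixed, table=pd.DataFrame(rows))


def css_sweep(
    parameter: str,
    grid: Sequence[float],
    p: ModelParams,
    n: NumericsConfig | None = None,
    start: tuple[float, float] = (1.1, 1.1),
) -> SweepTable:
    """Joint-CSS continuation along a model-parameter grid.

    At each grid point the joint CSS of (Q, P) is re-solved
    (warm-started from the neighbor) and the equilibrium population
    outputs at the CSS are recorded.  For the companion runs with
    frozen exponents use :func:`debpop.equilibrium.ecological_sweep`
    on a parameter set whose Q and P are fixed at a reference CSS.
    """
    if n is None:
        n = _DEFAULT_NUMERICS
    rows = []
    x0 = tuple(start)
    for v in grid:
        pv = p.replace(**{parameter: float(v)})
        try:
            sp = find_joint_css(pv, n, start=x0)
        except CSSNotFoundError:
            sp = find_joint_css(pv, n, start=(1.0, 1.0))
        x0 = (sp.traits["Q"], sp.traits["P"])
        eq = sp.equilibrium
        rows.append(
            {
                parameter: float(v),
                "Q_css": sp.traits["Q"],
                "P_css": sp.traits["P"],
                "css_common": sp.common_value,
                "css_difference": sp.traits["Q"] - sp.traits["P"],
                **eq.as_row(),
            }
        )
    return SweepTable(parameter=parameter, table=pd.DataFrame(rows))


def reproduction_scaling_check(
    point: SingularPoint | Equilibrium,
    n: NumericsConfig | None = None,
    n_grid: int = 200,
    step_allocation: bool = False,
) -> float:
    """Fitted power-law exponent of reproductive mass flux over adult sizes.

    At the (CSS) equilibrium, regresses log(s_b * b(R~, s)) on log(s)
    over the realized adult size range.  An exponent above one means
    reproductive output scales hyperallometrically with body mass.
    With ``step_allocation=True`` the smooth allocation function is
    replaced by a step (all adult production to reproduction), a
    diagnostic variant for which the exponent equals the production
    scaling exactly.
    """
    eq = point.equilibrium if isinstance(point, SingularPoint) else point
    p = eq.params
    s_hi = min(eq.asymptotic_size, p.s_m * (1.0 - 1e-9))
    span = s_hi - p.s_j
    s = np.linspace(p.s_j + 0.02 * span, p.s_j + 0.98 * span, n_grid)
    if step_allocation:
        flux = np.asarray(rates.omega_plus(eq.R_tilde, s, p))
    else:
        flux = p.s_b * np.asarray(rates.fecundity_rate(eq.R_tilde, s, p))
    if np.any(flux <= 0):
        raise ValueError("nonpositive reproductive flux on the adult range")
    slope = np.polyfit(np.log(s), np.log(flux), 1)[0]
    return float(slope)
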