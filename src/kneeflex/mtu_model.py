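"""Isometric Hill-type muscle-tendon unit.

A muscle-tendon unit (MTU) is a contractile fiber (active Gaussian
force-length curve plus an exponential passive curve) in series with an
elastic tendon, optionally pennated at a constant-thickness angle.  For a
given musculotendon length and activation, the fiber length is found by
enforcing force equilibrium between the fiber (projected along the tendon
line) and the tendon.  All simulations are isometric, so no force-velocity
relation is modelled.

Normalized curve conventions
----------------------------
* Active force-length: ``exp(-(l_norm - 1)^2 / gamma)``, maximal (=1) at the
  optimal fiber length, symmetric about it.  ``gamma`` is the Gaussian shape
  factor (default 0.20).
* Passive force-length: zero at or below the optimal length, exponential toe
  rising to 1 at a fiber strain of ``PASSIVE_STRAIN_LIMIT`` above optimal.
* Tendon force-strain: zero for slack tendon, exponential toe joined
  C1-continuously to a linear region, exactly 1 at the nominal strain
  ``eps_t0`` (default 4.9%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError, SolverError

__all__ = [
    "MuscleTendonParams",
    "MTUState",
    "active_force_length",
    "passive_force_length",
    "tendon_force_strain",
    "pennation_angle",
    "solve_isometric_equilibrium",
    "active_fiber_force_at",
    "total_fiber_force_at",
]

#: Fiber strain above optimal length at which the passive curve reaches 1.
PASSIVE_STRAIN_LIMIT = 0.6
#: Exponential shape of the passive toe region.
PASSIVE_SHAPE = 4.0
#: Fraction of ``eps_t0`` at which the tendon toe region ends.
TENDON_TOE_FRACTION = 2.0 / 3.0
#: Exponential shape of the tendon toe region.
TENDON_TOE_SHAPE = 3.0

#: Default equilibrium tolerance, as a fraction of maximal isometric force.
EQUILIBRIUM_TOL = 1e-8


@dataclass(frozen=True)
class MuscleTendonParams:
    """Hill-type parameters of one muscle-tendon unit.

    Parameters
    ----------
    name : str
        Muscle identifier.
    f_max : float
        Maximal isometric force, N.
    lf_o : float
        Optimal fiber length, m.
    lt_s : float
        Tendon slack length, m.
    alpha_o : float
        Pennation angle at the optimal fiber length, rad.  Zero for
        parallel-fibered muscles (semitendinosus, gracilis, sartorius).
    gamma : float
        Gaussian shape factor of the active force-length curve.
    eps_t0 : float
        Tendon strain at maximal isometric force.
    is_flexor : bool
        Role flag: knee flexor (agonist) vs extensor (antagonist).
    """

    name: str
    f_max: float
    lf_o: float
    lt_s: float
    alpha_o: float = 0.0
    gamma: float = 0.20
    eps_t0: float = 0.049
    is_flexor: bool = True

    def __post_init__(self) -> None:
        if not (self.f_max > 0):
            raise ParameterError(f"{self.name}: f_max must be positive")
        if not (self.lf_o > 0):
            raise ParameterError(f"{self.name}: lf_o must be positive")
        if not (self.lt_s > 0):
            raise ParameterError(f"{self.name}: lt_s must be positive")
        if not (0.0 <= self.alpha_o < math.pi / 2):
            raise ParameterError(f"{self.name}: alpha_o must lie in [0, pi/2)")
        if not (self.gamma > 0):
            raise ParameterError(f"{self.name}: gamma must be positive")
        if not (self.eps_t0 > 0):
            raise ParameterError(f"{self.name}: eps_t0 must be positive")


@dataclass(frozen=True)
class MTUState:
    """Solved isometric equilibrium of one muscle-tendon unit.

    Forces are in newtons; ``f_active`` and ``f_passive`` are the fiber force
    components projected along the tendon line, so ``f_active + f_passive``
    equals ``f_tendon`` up to ``residual``.
    """

    activation: float
    l_mtu: float
    l_fiber: float
    l_tendon: float
    f_active: float
    f_passive: float
    f_tendon: float
    residual: float
    pennation: float = 0.0
    tendon_strain: float = 0.0


def active_force_length(l_norm, gamma: float = 0.20):
    """Normalized active force at normalized fiber length ``l_norm``.

    Gaussian ``exp(-(l_norm - 1)^2 / gamma)``: 1 at the optimum, symmetric
    about it.  Accepts scalars or arrays.
    """
    l_arr = np.asarray(l_norm, dtype=float)
    if np.any(l_arr <= 0):
        raise ParameterError("normalized fiber length must be positive")
    if not (gamma > 0):
        raise ParameterError("gamma must be positive")
    out = np.exp(-((l_arr - 1.0) ** 2) / gamma)
    return out if out.ndim else float(out)


def passive_force_length(l_norm, strain_limit: float = PASSIVE_STRAIN_LIMIT,
                         shape: float = PASSIVE_SHAPE):
    """Normalized passive fiber force.

    Zero at or below the optimal length; exponential toe
    ``(exp(k*(l-1)/strain_limit) - 1) / (exp(k) - 1)`` above it, reaching 1
    at ``l_norm = 1 + strain_limit``.
    """
    l_arr = np.asarray(l_norm, dtype=float)
    if np.any(l_arr <= 0):
        raise ParameterError("normalized fiber length must be positive")
    x = np.clip(l_arr - 1.0, 0.0, None) / strain_limit
    out = np.expm1(shape * x) / math.expm1(shape)
    return out if out.ndim else float(out)


def _tendon_constants(eps_t0: float):
    """Toe-end strain, linear slope and toe-end force of the tendon curve.

    The linear branch is anchored exactly at (eps_t0, 1); the toe branch is
    an exponential scaled to meet the linear branch with matching value and
    slope at ``TENDON_TOE_FRACTION * eps_t0``.
    """
    eps_toe = TENDON_TOE_FRACTION * eps_t0
    k = TENDON_TOE_SHAPE
    # slope continuity: m = f_toe * k * e^k / (expm1(k) * eps_toe)
    # value at eps_t0:  f_toe + m * (eps_t0 - eps_toe) = 1
    c = k * math.exp(k) / (math.expm1(k) * eps_toe)
    m = c / (1.0 + c * (eps_t0 - eps_toe))
    f_toe = 1.0 - m * (eps_t0 - eps_toe)
    return eps_toe, m, f_toe


def tendon_force_strain(eps, eps_t0: float = 0.049):
    """Normalized tendon force at strain ``eps``.

    Zero for a slack tendon (``eps <= 0``), strictly increasing for positive
    strain, and exactly 1 at ``eps = eps_t0``.  Negative strain clamps to
    zero force.
    """
    if not (eps_t0 > 0):
        raise ParameterError("eps_t0 must be positive")
    eps_arr = np.asarray(eps, dtype=float)
    eps_toe, m, f_toe = _tendon_constants(eps_t0)
    k = TENDON_TOE_SHAPE
    with np.errstate(over="ignore"):
        toe = f_toe * np.expm1(k * eps_arr / eps_toe) / math.expm1(k)
    linear = np.where(eps_arr >= eps_t0,
                      1.0 + m * (eps_arr - eps_t0),
                      f_toe + m * (eps_arr - eps_toe))
    out = np.where(eps_arr <= 0.0, 0.0, np.where(eps_arr <= eps_toe, toe, linear))
    return out if out.ndim else float(out)


def pennation_angle(l_fiber, params: MuscleTendonParams):
    """Pennation angle at fiber length ``l_fiber`` (constant-thickness model).

    The muscle's thickness ``lf_o * sin(alpha_o)`` is conserved, so
    ``alpha = asin(lf_o * sin(alpha_o) / l_fiber)``, clipped just below 90
    degrees.  Returns 0 for parallel-fibered muscles.
    """
    l_arr = np.asarray(l_fiber, dtype=float)
    if np.any(l_arr <= 0):
        raise ParameterError("fiber length must be positive")
    if params.alpha_o == 0.0:
        out = np.zeros_like(l_arr)
        return out if out.ndim else 0.0
    s = np.minimum(1.0 - 1e-9, params.lf_o * math.sin(params.alpha_o) / l_arr)
    out = np.arcsin(s)
    return out if out.ndim else float(out)


def _state_from_projection(params: MuscleTendonParams, l_mtu: float,
                           a: float, p: float) -> MTUState:
    h = params.lf_o * math.sin(params.alpha_o)
    l_fiber = math.hypot(p, h)
    cos_a = p / l_fiber
    l_norm = l_fiber / params.lf_o
    l_tendon = l_mtu - p
    eps = l_tendon / params.lt_s - 1.0
    fa = a * active_force_length(l_norm, params.gamma) * params.f_max * cos_a
    fp = passive_force_length(l_norm) * params.f_max * cos_a
    ft = tendon_force_strain(eps, params.eps_t0) * params.f_max
    return MTUState(activation=a, l_mtu=l_mtu, l_fiber=l_fiber,
                    l_tendon=l_tendon, f_active=fa, f_passive=fp,
                    f_tendon=ft, residual=(fa + fp) - ft,
                    pennation=math.acos(min(1.0, cos_a)), tendon_strain=eps)


def solve_isometric_equilibrium(params: MuscleTendonParams, l_mtu: float,
                                a: float, tol: float | None = None) -> MTUState:
    """Solve the fiber-tendon force balance at fixed musculotendon length.

    Finds the fiber length at which the fiber force projected along the
    tendon equals the tendon force.  The unknown is the fiber projection
    ``p = l_fiber * cos(alpha)``; geometric closure
    ``l_fiber * cos(alpha) + l_tendon = l_mtu`` then holds exactly by
    construction.  Bracketed scalar root finding (Brent), deterministic.

    Raises
    ------
    ParameterError
        If the activation is outside [0, 1] or the length non-positive.
    SolverError
        If the residual does not change sign on the search bracket.
    """
    if not (0.0 <= a <= 1.0):
        raise ParameterError("activation must lie in [0, 1]")
    if not (l_mtu > 0):
        raise ParameterError("musculotendon length must be positive")
    if tol is None:
        tol = EQUILIBRIUM_TOL * params.f_max

    h = params.lf_o * math.sin(params.alpha_o)

    def residual_norm(p: float) -> float:
        l_fiber = math.hypot(p, h)
        cos_a = p / l_fiber
        l_norm = l_fiber / params.lf_o
        eps = (l_mtu - p) / params.lt_s - 1.0
        fa = a * math.exp(-((l_norm - 1.0) ** 2) / params.gamma)
        fp = passive_force_length(l_norm)
        if not (math.isfinite(fa) and math.isfinite(fp)):
            raise ParameterError(f"{params.name}: NaN in force-length curves")
        return (fa + fp) * cos_a - tendon_force_strain(eps, params.eps_t0)

    # Slack shortcut: with zero activation and a fiber at or below optimal
    # length the unique zero-force state puts the tendon exactly at slack.
    p_slack = l_mtu - params.lt_s
    if a == 0.0 and p_slack > 0:
        l_fiber = math.hypot(p_slack, h)
        if l_fiber <= params.lf_o:
            return _state_from_projection(params, l_mtu, a, p_slack)

    p_lo = min(1e-4 * params.lf_o, 0.5 * l_mtu)
    p_hi = l_mtu * (1.0 - 1e-12)
    r_lo = residual_norm(p_lo)
    r_hi = residual_norm(p_hi)
    if r_lo == 0.0:
        p_star = p_lo
    elif r_hi == 0.0:
        p_star = p_hi
    elif r_lo * r_hi > 0:
        raise SolverError(
            f"{params.name}: no sign change in equilibrium residual on "
            f"[{p_lo:.6g}, {p_hi:.6g}] m (residuals {r_lo:.3g}, {r_hi:.3g}; "
            f"l_mtu={l_mtu:.6g}, a={a})")
    else:
        p_star = brentq(residual_norm, p_lo, p_hi, xtol=1e-15, maxiter=300)

    state = _state_from_projection(params, l_mtu, a, p_star)
    # Brent converges to machine precision in the root; the residual can
    # only stay proportionally large for near-rigid tendons, so the hard
    # failure bound is loose and the 1e-8*F_max contract is a test property.
    if abs(state.residual) > 1e-3 * params.f_max:
        raise SolverError(
            f"{params.name}: equilibrium residual {state.residual:.3g} N "
            f"exceeds 1e-3*F_max")
    return state


def active_fiber_force_at(params: MuscleTendonParams, l_mtu: float,
                          a: float) -> float:
    """Active fiber force along the tendon line at equilibrium, N.

    This is the moment-generating force used for joint moments: the passive
    fiber component participates in the equilibrium solve but is excluded
    here, mirroring the experimental baseline subtraction that removes
    passive contributions.
    """
    return solve_isometric_equilibrium(params, l_mtu, a).f_active


def total_fiber_force_at(params: MuscleTendonParams, l_mtu: float,
                         a: float) -> float:
    """Total (active + passive) fiber force along the tendon line, N."""
    state = solve_isometric_equilibrium(params, l_mtu, a)
    return state.f_active + state.f_passive


def with_f_max(params: MuscleTendonParams, f_max: float) -> MuscleTendonParams:
    """Copy of ``params`` with a new maximal isometric force."""
    return replace(params, f_max=f_max)
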