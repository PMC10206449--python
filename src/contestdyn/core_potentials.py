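"""Effective interaction potentials for dyadic animal contests.

A contestant pair interacts through directed pair potentials of the form

    V(x) = -alpha * exp(-beta * x**2) - delta * ln(x)

combining a short-range attractive Gaussian well (escalation) with a
logarithmic repulsion (de-escalation / avoidance).  The sum of the two
directed potentials is the relative *contest potential*; its local maximum
``x_cap`` (the contest-onset distance) and local minimum ``x_cup`` (the
bound fighting state) are available in closed form through the two real
branches of the Lambert W function.  A localized resource enters as a
radially symmetric logarithmic trap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import lambertw

__all__ = [
    "CRITICAL_RATIO",
    "MIN_SEPARATION",
    "InteractionParams",
    "ContestPotentialSpec",
    "PotentialExtrema",
    "ResourceField",
    "pair_potential",
    "pair_force",
    "contest_potential",
    "contest_force",
    "find_extrema",
    "extrema_arrays",
    "resource_potential",
    "resource_force",
    "total_force",
]

#: Attraction/repulsion ratio A/Delta below which the contest potential has
#: no stationary points (the well and the barrier merge and vanish).  The
#: stationarity condition u*exp(-u) = Delta/(2A) with u = beta*x**2 has real
#: solutions iff Delta/(2A) <= 1/e, i.e. A/Delta >= e/2.
CRITICAL_RATIO: float = math.e / 2.0

#: Lower clamp applied to separations before evaluating pair quantities.
#: The logarithmic repulsion diverges at contact; below this distance the
#: interaction is already overwhelmingly repulsive.
MIN_SEPARATION: float = 1e-4


def _require_positive_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("separation x must be strictly positive")
    return x


@dataclass(frozen=True)
class InteractionParams:
    """Directed interaction coefficients of one contestant toward its rival.

    ``alpha`` sets the strength of effective attraction (motivation to
    escalate), ``delta`` the strength of effective repulsion (how
    intimidating the rival is perceived to be).  ``beta`` controls the
    range of the attractive well and ``x0`` is the length scale used to
    non-dimensionalize separations; both are shared by all contestants of
    a system and default to 1.
    """

    alpha: float
    delta: float
    beta: float = 1.0
    x0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "delta", "beta", "x0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be non-negative")
        if self.beta <= 0 or self.x0 <= 0:
            raise ValueError("beta and x0 must be strictly positive")


@dataclass(frozen=True)
class ContestPotentialSpec:
    """Coefficient sums of the relative contest potential.

    ``A = alpha_ji + alpha_ij`` and ``Delta = delta_ji + delta_ij`` for a
    pair whose directed potentials share ``beta`` (and ``x0``).
    """

    A: float
    Delta: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.A < 0 or self.Delta < 0:
            raise ValueError("A and Delta must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be strictly positive")

    @classmethod
    def from_pair(
        cls, params_to_i: InteractionParams, params_to_j: InteractionParams
    ) -> "ContestPotentialSpec":
        """Combine the two directed parameter sets of a contestant pair."""
        if not math.isclose(params_to_i.beta, params_to_j.beta):
            raise ValueError("contestants must share beta")
        if not math.isclose(params_to_i.x0, params_to_j.x0):
            raise ValueError("contestants must share x0")
        return cls(
            A=params_to_i.alpha + params_to_j.alpha,
            Delta=params_to_i.delta + params_to_j.delta,
            beta=params_to_i.beta,
        )

    @property
    def ratio(self) -> float:
        """A/Delta, compared against :data:`CRITICAL_RATIO`."""
        if self.Delta == 0.0:
            return math.inf
        return self.A / self.Delta


@dataclass(frozen=True)
class PotentialExtrema:
    """Stationary points of a contest potential.

    ``x_cap`` is the local maximum (contest-onset distance), ``x_cup`` the
    local minimum (bound state).  When ``exists`` is False the potential is
    monotone (no transient bound state) and both locations are NaN, except
    in the pure-Gaussian degenerate case ``Delta == 0`` where ``x_cup`` is
    reported at the well location 0 for reference.
    """

    exists: bool
    x_cap: float = math.nan
    x_cup: float = math.nan


@dataclass(frozen=True)
class ResourceField:
    """Radially symmetric logarithmic resource trap V(r) = p*ln(r + epsilon).

    ``p`` sets the attractiveness of the resource, ``epsilon`` regularizes
    the divergence at the resource itself, located at ``center``.
    """

    p: float = 4.0
    epsilon: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.p <= 0 or self.epsilon <= 0:
            raise ValueError("p and epsilon must be strictly positive")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


# ---------------------------------------------------------------------------
# Pair and contest potentials / forces
# ---------------------------------------------------------------------------

def pair_potential(x, params: InteractionParams):
    """Directed pair potential V(x) = -alpha*exp(-beta*x^2) - delta*ln(x)."""
    x = _require_positive_x(x)
    v = -params.alpha * np.exp(-params.beta * x**2) - params.delta * np.log(x)
    return v if v.ndim else float(v)


def pair_force(x, params: InteractionParams):
    """Directed pair force F(x) = -dV/dx.

    Positive values are repulsive (push the separation up), negative
    values attractive.
    """
    x = _require_positive_x(x)
    f = params.delta / x - 2.0 * params.alpha * params.beta * x * np.exp(
        -params.beta * x**2
    )
    return f if f.ndim else float(f)


def contest_potential(x, spec: ContestPotentialSpec):
    """Relative contest potential: sum of the two directed pair potentials."""
    x = _require_positive_x(x)
    v = -spec.A * np.exp(-spec.beta * x**2) - spec.Delta * np.log(x)
    return v if v.ndim else float(v)


def contest_force(x, spec: ContestPotentialSpec):
    """Relative contest force F = -dV_contest/dx (positive = separating)."""
    x = _require_positive_x(x)
    f = spec.Delta / x - 2.0 * spec.A * spec.beta * x * np.exp(-spec.beta * x**2)
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# Extrema of the contest potential
# ---------------------------------------------------------------------------

def find_extrema(spec: ContestPotentialSpec) -> PotentialExtrema:
    """Locate the stationary points of the contest potential analytically.

    Setting dV/dx = 0 and substituting u = beta*x**2 gives
    ``u * exp(-u) = Delta / (2A)``, solved by the two real Lambert W
    branches: ``u0 = -W0(-c)`` (the minimum, ``x_cup``) and
    ``u1 = -W_{-1}(-c)`` (the maximum, ``x_cap``).  Solutions exist iff
    ``c = Delta/(2A) <= 1/e``, i.e. ``A/Delta >= e/2``; at equality both
    extrema merge at ``u = 1`` (an inflection, zero well depth).
    """
    if spec.A == 0.0:
        # purely repulsive (or zero) potential: monotone, no bound state
        return PotentialExtrema(exists=False)
    if spec.Delta == 0.0:
        # pure Gaussian well: minimum sits at contact, no barrier, hence no
        # finite contest-onset distance
        return PotentialExtrema(exists=False, x_cup=0.0)
    c = spec.Delta / (2.0 * spec.A)
    if c > 1.0 / math.e:
        return PotentialExtrema(exists=False)
    u0 = -float(np.real(lambertw(-c, k=0)))
    u1 = -float(np.real(lambertw(-c, k=-1)))
    if not (math.isfinite(u0) and math.isfinite(u1)):
        # branch point c = 1/e: both extrema merge at u = 1
        u0 = u1 = 1.0
    x_cup = math.sqrt(u0 / spec.beta)
    x_cap = math.sqrt(u1 / spec.beta)
    return PotentialExtrema(exists=True, x_cap=x_cap, x_cup=x_cup)


def extrema_arrays(A, Delta, beta=1.0):
    """Vectorized :func:`find_extrema` over coefficient-sum arrays.

    Returns ``(exists, x_cap, x_cup)`` arrays; non-existing entries are NaN.
    Used by the simulator when costs make the coefficients time-dependent.
    """
    A = np.asarray(A, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    exists = np.zeros(A.shape, dtype=bool)
    x_cap = np.full(A.shape, np.nan)
    x_cup = np.full(A.shape, np.nan)
    ok = (A > 0) & (Delta > 0)
    c = np.where(ok, Delta / np.where(ok, 2.0 * A, 1.0), np.inf)
    ok &= c <= 1.0 / math.e
    if np.any(ok):
        u0 = -np.real(lambertw(-c[ok], k=0))
        u1 = -np.real(lambertw(-c[ok], k=-1))
        bad = ~(np.isfinite(u0) & np.isfinite(u1))  # branch point c = 1/e
        u0[bad] = 1.0
        u1[bad] = 1.0
        x_cup[ok] = np.sqrt(u0 / beta)
        x_cap[ok] = np.sqrt(u1 / beta)
        exists[ok] = True
    return exists, x_cap, x_cup


# ---------------------------------------------------------------------------
# Resource potential / force
# ---------------------------------------------------------------------------

def resource_potential(r, fld: ResourceField):
    """Resource potential V(r) = p*ln(r + epsilon) at distance r >= 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    v = fld.p * np.log(r + fld.epsilon)
    return v if v.ndim else float(v)


def resource_force(position, fld: ResourceField):
    """2-D force exerted by the resource on a contestant at ``position``.

    Points toward the resource center with magnitude p/(r + epsilon); the
    zero vector exactly at the center (symmetric limit).
    """
    pos = np.asarray(position, dtype=float)
    vec = fld.center_array - pos
    r = np.linalg.norm(vec, axis=-1, keepdims=True)
    mag = fld.p / (r + fld.epsilon)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r > 0, vec / np.where(r > 0, r, 1.0), 0.0)
    return unit * mag


# ---------------------------------------------------------------------------
# Total force with attention switch
# ---------------------------------------------------------------------------

def total_force(
    position_i,
    position_j,
    params_to_i: InteractionParams,
    fld: ResourceField,
    extrema: PotentialExtrema,
) -> np.ndarray:
    """Total effective force on contestant i.

    The directed pair force (along the i-j axis) always acts.  The resource
    force is added only while the pair is outside contest range
    (``x_ij >= x_cap``), or everywhere when the contest potential has no
    stationary points — the attention switch.  Separations are clamped at
    :data:`MIN_SEPARATION` so coincident positions never raise.
    """
    ri = np.asarray(position_i, dtype=float)
    rj = np.asarray(position_j, dtype=float)
    d = ri - rj
    dist = float(np.linalg.norm(d))
    x = max(dist / params_to_i.x0, MIN_SEPARATION)
    if dist > 0:
        xhat = d / dist
    else:
        xhat = np.array([1.0, 0.0])
    f = pair_force(x, params_to_i) / params_to_i.x0 * xhat
    attend_resource = (not extrema.exists) or (x >= extrema.x_cap)
    if attend_resource:
        f = f + resource_force(ri, fld)
    return f
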