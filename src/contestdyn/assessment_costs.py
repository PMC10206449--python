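"""Assessment strategies and fighting costs.

Each contestant carries a dimensionless effective size ``m`` — its resource
holding potential (RHP) relative to a population reference.  An assessment
function maps the pair (m_self, m_rival) to the directed interaction
coefficients:

    alpha = alpha0 * m_self**s  * (m_self/m_rival)**sQ
    delta = delta0 * m_rival**r * (m_rival/m_self)**rQ

The exponents select the strategy: pure self-assessment uses only the
absolute own size (s > 0), pure mutual assessment only the size ratio
(sQ, rQ > 0) and is therefore scale-invariant.

Fighting costs shrink the effective sizes with the accumulated contest time
t_sigma:

    m_i(t) = mu_i / (1 + (K_self + K_ij * mu_j/mu_i) * t)

so the larger contestant inflicts costs faster but incurs them slower.
When the accrued costs push the summed attraction/repulsion ratio of the
contest potential below e/2, the bounding well vanishes and the contest
terminates: the smallest such t_sigma is the cost-driven duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core_potentials import CRITICAL_RATIO, ContestPotentialSpec, InteractionParams

__all__ = [
    "AssessmentSpec",
    "ContestantProfile",
    "CostModel",
    "EffectiveSizeState",
    "assess",
    "pair_params",
    "contest_spec_at",
    "effective_sizes",
    "asymptotic_size_ratio",
    "cost_driven_duration",
]


@dataclass(frozen=True)
class AssessmentSpec:
    """Exponents and scales of the assessment function."""

    alpha0: float = 7.0
    delta0: float = 3.0
    s: float = 0.0
    r: float = 0.0
    sQ: float = 0.0
    rQ: float = 0.0
    beta: float = 1.0
    x0: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.delta0 <= 0:
            raise ValueError("alpha0 and delta0 must be strictly positive")
        for name in ("s", "r", "sQ", "rQ"):
            if getattr(self, name) < 0:
                raise ValueError(f"exponent {name} must be non-negative")
        if self.beta <= 0 or self.x0 <= 0:
            raise ValueError("beta and x0 must be strictly positive")

    @classmethod
    def pure_self(cls, s: float = 1.0, alpha0: float = 7.0, delta0: float = 3.0,
                  **kw) -> "AssessmentSpec":
        """Absolute self-assessment: only one's own size matters."""
        return cls(alpha0=alpha0, delta0=delta0, s=s, **kw)

    @classmethod
    def pure_mutual(cls, sQ: float = 1.0, rQ: float = 2.0, alpha0: float = 7.0,
                    delta0: float = 3.0, **kw) -> "AssessmentSpec":
        """Relative (mutual) assessment: only the size ratio matters."""
        return cls(alpha0=alpha0, delta0=delta0, sQ=sQ, rQ=rQ, **kw)


@dataclass(frozen=True)
class ContestantProfile:
    """A contestant's label and initial effective size mu (> 0)."""

    id: str
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be strictly positive")


@dataclass(frozen=True)
class CostModel:
    """Cost accrual rates (per unit contest time); (0, 0) is the no-cost limit."""

    K_self: float = 0.0
    K_ij: float = 0.0

    def __post_init__(self) -> None:
        if self.K_self < 0 or self.K_ij < 0:
            raise ValueError("cost rates must be non-negative")

    @property
    def is_zero(self) -> bool:
        return self.K_self == 0.0 and self.K_ij == 0.0


@dataclass(frozen=True)
class EffectiveSizeState:
    """Current effective sizes after t_sigma of accumulated contest time."""

    m_i: float
    m_j: float
    t_sigma: float


def assess(spec: AssessmentSpec, m_self, m_rival) -> InteractionParams:
    """Interaction parameters felt by a contestant of size ``m_self``.

    Returns the directed (rival -> self) :class:`InteractionParams`; the
    opponent's parameters are obtained by swapping the two arguments.
    Accepts scalars only; see :func:`assess_arrays` for the vectorized form.
    """
    if m_self <= 0 or m_rival <= 0:
        raise ValueError("effective sizes must be strictly positive")
    alpha = spec.alpha0 * m_self**spec.s * (m_self / m_rival) ** spec.sQ
    delta = spec.delta0 * m_rival**spec.r * (m_rival / m_self) ** spec.rQ
    return InteractionParams(alpha=alpha, delta=delta, beta=spec.beta, x0=spec.x0)


def assess_arrays(spec: AssessmentSpec, m_self, m_rival):
    """Vectorized assessment: returns ``(alpha, delta)`` arrays."""
    m_self = np.asarray(m_self, dtype=float)
    m_rival = np.asarray(m_rival, dtype=float)
    alpha = spec.alpha0 * m_self**spec.s * (m_self / m_rival) ** spec.sQ
    delta = spec.delta0 * m_rival**spec.r * (m_rival / m_self) ** spec.rQ
    return alpha, delta


def pair_params(
    spec: AssessmentSpec, m_i: float, m_j: float
) -> tuple[InteractionParams, InteractionParams]:
    """Both directed parameter sets ``(params_to_i, params_to_j)``."""
    return assess(spec, m_i, m_j), assess(spec, m_j, m_i)


def contest_spec_at(
    spec: AssessmentSpec, m_i: float, m_j: float
) -> ContestPotentialSpec:
    """Combined contest-potential coefficients at the given sizes."""
    return ContestPotentialSpec.from_pair(*pair_params(spec, m_i, m_j))


def effective_sizes(
    profiles: tuple[ContestantProfile, ContestantProfile],
    cost: CostModel,
    t_sigma: float,
) -> EffectiveSizeState:
    """Effective sizes after ``t_sigma`` of accumulated contest time.

    Costs accrue continuously: self-inflicted at rate K_self and
    rival-inflicted at rate K_ij scaled by the initial size ratio, so the
    larger contestant inflicts costs faster but incurs them slower.
    """
    if t_sigma < 0:
        raise ValueError("t_sigma must be non-negative")
    mu_i, mu_j = profiles[0].mu, profiles[1].mu
    m_i = mu_i / (1.0 + (cost.K_self + cost.K_ij * mu_j / mu_i) * t_sigma)
    m_j = mu_j / (1.0 + (cost.K_self + cost.K_ij * mu_i / mu_j) * t_sigma)
    return EffectiveSizeState(m_i=m_i, m_j=m_j, t_sigma=t_sigma)


def size_arrays(
    profiles: tuple[ContestantProfile, ContestantProfile],
    cost: CostModel,
    t_sigma,
):
    """Vectorized effective sizes over an array of t_sigma values."""
    t = np.asarray(t_sigma, dtype=float)
    mu_i, mu_j = profiles[0].mu, profiles[1].mu
    m_i = mu_i / (1.0 + (cost.K_self + cost.K_ij * mu_j / mu_i) * t)
    m_j = mu_j / (1.0 + (cost.K_self + cost.K_ij * mu_i / mu_j) * t)
    return m_i, m_j


def asymptotic_size_ratio(
    profiles: tuple[ContestantProfile, ContestantProfile], cost: CostModel
) -> float:
    """The limit of m_i/m_j as t_sigma -> infinity.

    Both sizes decay like 1/t, so their ratio approaches
    ``mu_i*(K_self + K_ij*mu_i/mu_j) / (mu_j*(K_self + K_ij*mu_j/mu_i))``.
    Undefined in the exact no-cost limit.
    """
    if cost.is_zero:
        raise ValueError("asymptotic size ratio is undefined for zero cost rates")
    mu_i, mu_j = profiles[0].mu, profiles[1].mu
    num = mu_i * (cost.K_self + cost.K_ij * mu_i / mu_j)
    den = mu_j * (cost.K_self + cost.K_ij * mu_j / mu_i)
    return num / den


def _coefficient_ratio(
    spec: AssessmentSpec,
    profiles: tuple[ContestantProfile, ContestantProfile],
    cost: CostModel,
    t_sigma: float,
) -> float:
    """A(t)/Delta(t) of the contest potential at accumulated time t_sigma."""
    state = effective_sizes(profiles, cost, t_sigma)
    a_i, d_i = assess_arrays(spec, state.m_i, state.m_j)
    a_j, d_j = assess_arrays(spec, state.m_j, state.m_i)
    return float((a_i + a_j) / (d_i + d_j))


def cost_driven_duration(
    spec: AssessmentSpec,
    profiles: tuple[ContestantProfile, ContestantProfile],
    cost: CostModel,
    rtol: float = 1e-12,
) -> float | None:
    """Accumulated contest time at which the bounding well vanishes.

    Finds the smallest ``t_sigma`` where the assessed coefficient-sum
    ratio ``A/Delta`` first reaches the critical value e/2, by geometric
    bracketing followed by Brent root-finding on the monotone-decreasing
    ratio.  Returns 0.0 when no well exists at the outset (the contest
    never forms) and ``None`` when the ratio approaches its finite
    asymptote without ever reaching e/2 (termination stays noise-driven).
    """
    r0 = _coefficient_ratio(spec, profiles, cost, 0.0)
    if r0 <= CRITICAL_RATIO:
        return 0.0
    if cost.is_zero:
        return None

    f = lambda t: _coefficient_ratio(spec, profiles, cost, t) - CRITICAL_RATIO

    t_hi = 1.0
    prev = r0
    while t_hi < 1e12:
        cur = _coefficient_ratio(spec, profiles, cost, t_hi)
        if cur <= CRITICAL_RATIO:
            return float(brentq(f, 0.0, t_hi, xtol=1e-12, rtol=1e-15))
        # ratio still above critical; stop once it has stopped moving
        if abs(cur - prev) <= rtol * abs(cur):
            return None
        prev = cur
        t_hi *= 2.0
    return None
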