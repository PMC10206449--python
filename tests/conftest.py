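"""Shared fixtures: canonical configurations and independent oracles."""

import numpy as np
import pytest

from contestdyn import (
    AssessmentSpec,
    ContestantProfile,
    CostModel,
    DynamicsConfig,
    ResourceField,
)


@pytest.fixture(scope="session")
def field():
    return ResourceField(p=4.0, epsilon=1.0)


@pytest.fixture(scope="session")
def matched_profiles():
    return (ContestantProfile("i", 1.0), ContestantProfile("j", 1.0))


@pytest.fixture(scope="session")
def symmetric_assessment():
    """Size-independent assessment giving every contestant (alpha, delta) = (7, 3)."""
    return AssessmentSpec(alpha0=7.0, delta0=3.0)


@pytest.fixture(scope="session")
def no_cost():
    return CostModel()


@pytest.fixture(scope="session")
def canonical_dynamics():
    return DynamicsConfig(eta=1.0, D=0.5, dt=1e-3, max_time=500.0)


def bisect_extrema(A, Delta, beta=1.0, tol=1e-12):
    """Brute-force stationary points of the contest potential.

    Scans the contest force on a fine grid for sign changes and refines
    each by bisection.  Independent of the Lambert-W closed form it is
    used to check.  Returns (x_cup, x_cap) or None when no interior sign
    change exists.
    """

    def force(x):
        return Delta / x - 2.0 * A * beta * x * np.exp(-beta * x**2)

    grid = np.linspace(1e-3, 10.0, 40001)
    f = force(grid)
    sign_changes = np.nonzero(np.sign(f[:-1]) != np.sign(f[1:]))[0]
    roots = []
    for idx in sign_changes:
        lo, hi = grid[idx], grid[idx + 1]
        flo = force(lo)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            fm = force(mid)
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
            if hi - lo < tol:
                break
        roots.append(0.5 * (lo + hi))
    if len(roots) < 2:
        return None
    return min(roots), max(roots)


@pytest.fixture(scope="session")
def extrema_oracle():
    return bisect_extrema


def has_stationary_points(A, Delta, beta=1.0):
    """Existence test by direct minimization of the contest force.

    Stationary points exist iff the force dips below zero somewhere; the
    dip is located by Brent minimization refined from a coarse grid,
    which resolves its disappearance far more sharply than sign-change
    scanning.  Independent of the Lambert-W analysis.
    """
    from scipy.optimize import minimize_scalar

    def force(x):
        return Delta / x - 2.0 * A * beta * x * np.exp(-beta * x**2)

    grid = np.linspace(0.05, 5.0, 2001)
    i = int(np.argmin(force(grid)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(force, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return min(res.fun, float(np.min(force(grid)))) < 0.0


def critical_ratio_by_bisection(beta=1.0, tol=1e-10):
    """Locate the A/Delta ratio where the stationary points vanish,
    using only the force-minimization existence oracle."""
    lo, hi = 1.0, 3.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_stationary_points(mid, 1.0, beta):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def critical_ratio_oracle():
    return critical_ratio_by_bisection
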