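"""Recovering effective interaction potentials from contest trajectories.

The extraction follows the empirical-measurement recipe: (1) bin the
pairwise separation velocity ``dx_ij/dt`` of consecutive frame pairs by
the midpoint separation to obtain the averaged relative velocity profile
``v_rel(x)`` (positive = separating, effective repulsion); (2) integrate
``-v_rel`` cumulatively over the populated bins to obtain the observed
relative potential ``V_rel`` (the mobility eta is absorbed, the additive
constant arbitrary); (3) least-squares fit the contest-potential form
``-A exp(-beta x^2) - Delta ln x + offset`` within a range dominated by
the pair interaction rather than the residual resource attraction.  For
RHP-matched contestants the fitted coefficient sums split evenly between
the two directed potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .core_potentials import InteractionParams
from .contest_simulator import Trajectory

__all__ = [
    "VelocityProfile",
    "RelativePotentialCurve",
    "PotentialFit",
    "relative_velocity_profile",
    "integrate_profile",
    "fit_contest_potential",
    "split_symmetric",
    "extract_potentials",
]

DEFAULT_BIN_WIDTH = 0.05
DEFAULT_FIT_RANGE = (0.3, 1.4)


@dataclass(frozen=True)
class VelocityProfile:
    """Binned mean relative radial velocity between the contestants.

    ``D_rel_hat`` is the diffusion coefficient of the separation
    coordinate estimated from the within-bin velocity variance of the
    same data (None when the profile was built without variance
    information, e.g. by hand).  It feeds the geometric-drift correction
    in :func:`integrate_profile`.
    """

    bin_edges: np.ndarray
    v_rel: np.ndarray   # NaN on unpopulated bins
    counts: np.ndarray
    D_rel_hat: float | None = None
    x_mean: np.ndarray | None = None  # mean separation per populated bin
    var_v: np.ndarray | None = None   # variance of the binned mean velocity

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def abscissae(self) -> np.ndarray:
        """Separation values the binned velocities refer to.

        The binned mean velocity estimates the drift at the bin's
        occupancy-weighted mean separation, not at its geometric center;
        where the occupancy density varies steeply (the repulsive wall,
        the well) the distinction is a first-order bias.  Falls back to
        centers for profiles built without occupancy information.
        """
        if self.x_mean is None:
            return self.centers
        return np.where(np.isfinite(self.x_mean), self.x_mean, self.centers)

    @property
    def populated(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class RelativePotentialCurve:
    """Observed relative potential on the profile's populated support.

    Defined up to an additive constant; ``interpolated`` flags bins whose
    velocity was filled by linear interpolation across an interior gap.
    """

    x: np.ndarray
    V_rel: np.ndarray
    eta_absorbed: bool = True
    interpolated: np.ndarray | None = None
    sigma: np.ndarray | None = None  # propagated 1-sigma uncertainty per point


@dataclass(frozen=True)
class PotentialFit:
    """Bounded least-squares fit of the contest-potential form to V_rel."""

    A_hat: float
    Delta_hat: float
    beta_hat: float
    offset: float
    fit_range: tuple[float, float]
    rms_residual: float
    n_points: int


def relative_velocity_profile(
    trajectories, bin_width: float = DEFAULT_BIN_WIDTH
) -> VelocityProfile:
    """Averaged relative velocity vs separation, pooled over trajectories.

    Each consecutive frame pair contributes ``(x[k+1]-x[k]) / (t[k+1]-t[k])``
    to the bin containing the separation at the pair's first frame.
    Conditioning on the starting separation makes the binned mean an
    unbiased estimate of the drift; conditioning on the midpoint would
    add a density-gradient term that cancels the drift wherever the
    bound state is quasi-equilibrated.  Whatever trajectories are passed
    get pooled; restricting to comparable (RHP-matched, same-setup)
    contests is the caller's responsibility.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be strictly positive")
    starts, vels, dts = [], [], []
    for traj in trajectories:
        x = traj.x_ij if isinstance(traj, Trajectory) else np.asarray(traj["x_ij"])
        t = traj.t if isinstance(traj, Trajectory) else np.asarray(traj["t"])
        if len(x) < 2:
            continue
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("frame times must be strictly increasing")
        vels.append(np.diff(x) / dt)
        starts.append(x[:-1])
        dts.append(dt)
    if not starts:
        raise ValueError("need at least one trajectory with >= 2 frames")
    starts = np.concatenate(starts)
    vels = np.concatenate(vels)
    dts = np.concatenate(dts)

    n_bins = max(1, int(math.ceil(starts.max() / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.clip(np.floor(starts / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vels, minlength=n_bins)
    x_sums = np.bincount(idx, weights=starts, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        v_rel = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        x_mean = np.where(counts > 0, x_sums / np.maximum(counts, 1), np.nan)

    # Diffusion of the separation coordinate from the within-bin velocity
    # variance: Var(v | bin) ~= 2*D_rel/dt for small dt.
    resid = vels - v_rel[idx]
    total = float(np.sum(0.5 * resid**2 * dts))
    D_rel_hat = total / len(vels) if len(vels) > 1 else None
    # variance of each bin's mean velocity (noise-dominated, so the global
    # diffusion estimate divided by the bin's sampling applies everywhere)
    var_v = None
    if D_rel_hat is not None:
        mean_dt = float(np.mean(dts))
        with np.errstate(divide="ignore"):
            var_v = np.where(
                counts > 0, 2.0 * D_rel_hat / mean_dt / np.maximum(counts, 1), np.nan
            )
    return VelocityProfile(
        bin_edges=edges, v_rel=v_rel, counts=counts,
        D_rel_hat=D_rel_hat, x_mean=x_mean, var_v=var_v,
    )


def integrate_profile(
    profile: VelocityProfile, correct_geometric_drift: bool = True
) -> RelativePotentialCurve:
    """Cumulative trapezoidal integration of -v_rel over the populated bins.

    Integration starts at the first populated bin (the potential is only
    ever defined up to a constant).  Interior gaps are bridged by linear
    interpolation of v_rel and flagged.

    The separation of a diffusing planar pair drifts outward by
    ``D_rel/x`` even in the absence of any force (the Bessel term of the
    radial coordinate); left in, this term masquerades as extra
    logarithmic repulsion in the recovered potential.  When the profile
    carries a data-driven diffusion estimate it is subtracted before
    integrating; profiles built without variance information integrate
    the raw v_rel.
    """
    pop = np.nonzero(profile.populated)[0]
    if len(pop) < 2:
        raise ValueError("profile needs at least 2 populated bins")
    lo, hi = pop[0], pop[-1]
    centers = profile.abscissae[lo : hi + 1]
    v = profile.v_rel[lo : hi + 1].copy()
    gap = ~np.isfinite(v)
    if gap.any():
        v[gap] = np.interp(centers[gap], centers[~gap], v[~gap])
    if correct_geometric_drift and profile.D_rel_hat is not None:
        v = v - profile.D_rel_hat / centers
    V = -cumulative_trapezoid(v, centers, initial=0.0)

    # propagate the per-bin sampling variance through the trapezoid sums
    # (diagonal terms; the resulting sigma downweights the sparsely
    # sampled tail of the curve in the subsequent fit)
    sigma = None
    if profile.var_v is not None:
        var = profile.var_v[lo : hi + 1].copy()
        bad = ~np.isfinite(var)
        if bad.any():
            var[bad] = np.interp(centers[bad], centers[~bad], var[~bad])
        h = np.diff(centers)
        coeff = np.zeros_like(v)
        var_V = np.empty_like(v)
        var_V[0] = 0.0
        for k in range(1, len(v)):
            coeff[k - 1] += 0.5 * h[k - 1]
            coeff[k] += 0.5 * h[k - 1]
            var_V[k] = float(np.sum(coeff[: k + 1] ** 2 * var[: k + 1]))
        sigma = np.sqrt(var_V)

    return RelativePotentialCurve(
        x=centers, V_rel=V, eta_absorbed=True, interpolated=gap, sigma=sigma
    )


def fit_contest_potential(
    curve: RelativePotentialCurve,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    fix_beta: float | None = 1.0,
) -> PotentialFit:
    """Fit ``-A exp(-beta x^2) - Delta ln(x) + offset`` to the observed curve.

    A and Delta are bounded below by zero; beta is fixed (default 1)
    unless ``fix_beta=None`` frees it.  Curves carrying propagated
    uncertainties are fitted with inverse-variance weights, which
    downweights the sparsely sampled part of the support.  Raises with
    diagnostics on non-convergence.
    """
    lo, hi = fit_range
    mask = (curve.x >= lo) & (curve.x <= hi) & np.isfinite(curve.V_rel)
    x, y = curve.x[mask], curve.V_rel[mask]
    if len(x) < 4:
        raise ValueError(
            f"fit range [{lo}, {hi}] contains only {len(x)} points; need >= 4"
        )
    sigma = None
    if curve.sigma is not None:
        sigma = curve.sigma[mask].copy()
        floor = max(float(sigma.max()) * 1e-3, 1e-12)
        sigma = np.maximum(sigma, floor)

    if fix_beta is not None:
        model = lambda x, A, Delta, off: -A * np.exp(-fix_beta * x**2) - Delta * np.log(x) + off
        p0 = (1.0, 1.0, 0.0)
        bounds = ([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf])
    else:
        model = lambda x, A, Delta, beta, off: -A * np.exp(-beta * x**2) - Delta * np.log(x) + off
        p0 = (1.0, 1.0, 1.0, 0.0)
        bounds = ([0.0, 0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf, np.inf])

    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0, bounds=bounds, sigma=sigma, maxfev=20000
        )
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"contest-potential fit failed to converge on {len(x)} points over "
            f"[{lo}, {hi}]: {err}"
        ) from err

    resid = y - model(x, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if fix_beta is not None:
        A_hat, Delta_hat, off = popt
        beta_hat = float(fix_beta)
    else:
        A_hat, Delta_hat, beta_hat, off = popt
    return PotentialFit(
        A_hat=float(A_hat),
        Delta_hat=float(Delta_hat),
        beta_hat=float(beta_hat),
        offset=float(off),
        fit_range=(float(lo), float(hi)),
        rms_residual=rms,
        n_points=int(len(x)),
    )


def split_symmetric(fit: PotentialFit) -> tuple[InteractionParams, InteractionParams]:
    """Divide a fitted contest potential evenly between the contestants.

    Valid only for contests pooled from RHP-matched contestants, where
    the two directed potentials are identical by symmetry.
    """
    half = InteractionParams(
        alpha=fit.A_hat / 2.0, delta=fit.Delta_hat / 2.0, beta=fit.beta_hat
    )
    return half, half


def auto_fit_range(profile: VelocityProfile, min_separation: float = 1e-4):
    """Heuristic contest-dominated range: from the first populated bin above
    ``min_separation`` to 90% of the first upward zero-crossing of v_rel
    (the change from effective attraction to repulsion marks the onset of
    resource-dominated behaviour)."""
    centers = profile.centers
    pop = profile.populated & (centers > min_separation)
    if not pop.any():
        raise ValueError("profile has no populated bins above min_separation")
    lo = centers[pop][0]
    v = profile.v_rel
    hi = centers[pop][-1]
    idx = np.nonzero(pop)[0]
    for a, b in zip(idx[:-1], idx[1:]):
        if np.isfinite(v[a]) and np.isfinite(v[b]) and v[a] < 0.0 <= v[b]:
            hi = 0.9 * centers[b]
            break
    return (float(lo), float(hi))


def extract_potentials(
    trajectories,
    bin_width: float = DEFAULT_BIN_WIDTH,
    fit_range: tuple[float, float] | None = DEFAULT_FIT_RANGE,
    fix_beta: float | None = 1.0,
):
    """Full pipeline: profile -> curve -> fit.

    Returns ``(profile, curve, fit)``.  ``fit_range=None`` selects the
    heuristic automatic range.
    """
    profile = relative_velocity_profile(trajectories, bin_width=bin_width)
    curve = integrate_profile(profile)
    if fit_range is None:
        fit_range = auto_fit_range(profile)
    fit = fit_contest_potential(curve, fit_range=fit_range, fix_beta=fix_beta)
    return profile, curve, fit
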