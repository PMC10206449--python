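"""Overdamped Langevin simulation of dyadic contests over a resource.

Both contestants are treated as Brownian particles in the plane.  Each
Euler-Maruyama step displaces a contestant by ``eta * F * dt`` plus
isotropic Gaussian noise of per-coordinate variance ``2*D*dt``, where the
total force F combines the directed pair force with the resource
attraction, subject to the attention switch: the resource acts only while
the pair separation is at or beyond the contest-onset distance ``x_cap``.

A contest episode runs while ``x_ij < x_cap``.  Accumulated contest time
``t_sigma`` advances only during episodes and persists across them; under
fighting costs it shrinks the effective sizes, which can make the bounding
well of the contest potential vanish mid-episode (cost-driven
termination).  After an episode, the first contestant to come within the
capture radius of the resource while not in contest wins.

The module exposes a single-contest front end (:func:`run_simulation`,
full trajectory recording) and a vectorized ensemble engine
(:func:`simulate_ensemble`) that the observables layer uses for
duration, chase and win-probability experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_potentials import (
    MIN_SEPARATION,
    ContestPotentialSpec,
    InteractionParams,
    PotentialExtrema,
    ResourceField,
    extrema_arrays,
    find_extrema,
    total_force,
)
from .assessment_costs import (
    AssessmentSpec,
    ContestantProfile,
    CostModel,
    assess_arrays,
    size_arrays,
)

__all__ = [
    "DynamicsConfig",
    "ContestEpisode",
    "OutcomeRecord",
    "Trajectory",
    "EnsembleResult",
    "step",
    "run_simulation",
    "simulate_ensemble",
    "simulate_trajectories",
    "fair_start_setup",
    "end_angle",
]

TRAJECTORY_COLUMNS = [
    "t", "xi", "yi", "xj", "yj", "x_ij", "m_i", "m_j", "in_contest", "episode_id",
]

#: Per-step drift displacement above which the integration aborts.
_UNSTABLE_DISPLACEMENT = 1.0
#: Per-step drift displacement above which a one-time warning is emitted.
_WARN_DISPLACEMENT = 0.1


@dataclass(frozen=True)
class DynamicsConfig:
    """Integration and bookkeeping parameters of the Langevin dynamics.

    ``eta`` is the mobility (velocity per unit force), ``D`` the
    single-contestant diffusion coefficient.  ``capture_radius`` is the
    distance to the resource below which a contestant (while not in
    contest) claims it.  ``sample_stride`` thins trajectory recording to
    every so many integration steps.
    """

    eta: float = 1.0
    D: float = 0.5
    dt: float = 1e-3
    max_time: float = 500.0
    capture_radius: float = 0.2
    min_separation: float = MIN_SEPARATION
    seed: int | None = None
    sample_stride: int = 1

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be strictly positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.max_time <= 0:
            raise ValueError("max_time must be strictly positive")
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be strictly positive")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be strictly positive")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass(frozen=True)
class ContestEpisode:
    """One contiguous stretch of time with the pair inside contest range."""

    onset_time: float
    end_time: float
    cause: str  # "noise_escape" | "cost_driven" | "horizon"

    @property
    def duration(self) -> float:
        return self.end_time - self.onset_time


@dataclass(frozen=True)
class OutcomeRecord:
    """Final outcome of one simulated contest.

    ``winner`` is a contestant id, or None when the horizon was reached
    with no capture.  ``theta_end`` is the signed end angle (degrees) at
    the final contest end; NaN when no episode occurred.
    """

    winner: str | None
    capture_time: float | None
    theta_end: float
    total_t_sigma: float


@dataclass
class Trajectory:
    """Recorded frames of one simulation as a DataFrame.

    Columns: t, xi, yi, xj, yj, x_ij, m_i, m_j, in_contest (0/1),
    episode_id (-1 outside contests).
    """

    frames: pd.DataFrame

    def write_csv(self, path) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.frames.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        missing = [c for c in ("t", "xi", "yi", "xj", "yj") if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {missing}")
        if "x_ij" not in df.columns:
            df["x_ij"] = np.hypot(df.xi - df.xj, df.yi - df.yj)
        return cls(frames=df)

    @property
    def x_ij(self) -> np.ndarray:
        return self.frames["x_ij"].to_numpy()

    @property
    def t(self) -> np.ndarray:
        return self.frames["t"].to_numpy()


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def end_angle(position_i, position_j, fld: ResourceField) -> float:
    """Signed angle theta (degrees) quantifying positional advantage.

    The angle between the unit vector from contestant j to contestant i
    and the unit vector from the contestants' midpoint to the resource
    center.  |theta| < 90 degrees holds exactly when i is strictly closer
    to the resource than j.
    """
    ri = np.asarray(position_i, dtype=float)
    rj = np.asarray(position_j, dtype=float)
    mid = 0.5 * (ri + rj)
    to_res = fld.center_array - mid
    if np.linalg.norm(to_res) == 0.0:
        raise ValueError("midpoint coincides with the resource center; "
                         "end angle undefined")
    axis = ri - rj
    if np.linalg.norm(axis) == 0.0:
        raise ValueError("coincident contestants; end angle undefined")
    dot = float(axis @ to_res)
    cross = float(axis[0] * to_res[1] - axis[1] * to_res[0])
    return math.degrees(math.atan2(cross, dot))


def _end_angle_arrays(pos: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Vectorized end angle for positions of shape (n, 2, 2); NaN when degenerate."""
    mid = 0.5 * (pos[:, 0] + pos[:, 1])
    to_res = center[None, :] - mid
    axis = pos[:, 0] - pos[:, 1]
    dot = np.einsum("ij,ij->i", axis, to_res)
    cross = axis[:, 0] * to_res[:, 1] - axis[:, 1] * to_res[:, 0]
    theta = np.degrees(np.arctan2(cross, dot))
    bad = (np.einsum("ij,ij->i", to_res, to_res) == 0.0) | (
        np.einsum("ij,ij->i", axis, axis) == 0.0
    )
    theta[bad] = np.nan
    return theta


def fair_start_setup(
    fld: ResourceField,
    spec: ContestPotentialSpec | PotentialExtrema,
    r0: float | None = None,
    separation: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial positions with no positional advantage for either contestant.

    Both contestants sit on a circle of radius ``r0`` about the resource,
    symmetric about an axis through the center, with initial separation
    exactly equal to the contest-onset distance ``x_cap`` (override with
    ``separation``).  ``r0`` defaults to ``x_cap`` (an equilateral
    triangle with the resource).
    """
    extrema = spec if isinstance(spec, PotentialExtrema) else find_extrema(spec)
    if separation is None:
        if not extrema.exists:
            raise ValueError("contest potential has no onset distance; "
                             "pass separation explicitly")
        separation = extrema.x_cap
    if r0 is None:
        r0 = separation
    if r0 < separation / 2.0:
        raise ValueError(
            f"r0 = {r0} cannot realize separation {separation}: need r0 >= separation/2"
        )
    psi = math.asin(separation / (2.0 * r0))
    c = fld.center_array
    pos_i = c + r0 * np.array([math.cos(psi), math.sin(psi)])
    pos_j = c + r0 * np.array([math.cos(psi), -math.sin(psi)])
    return pos_i, pos_j


# ---------------------------------------------------------------------------
# Single Euler-Maruyama step (reference implementation)
# ---------------------------------------------------------------------------

def step(
    position_i,
    position_j,
    params_to_i: InteractionParams,
    params_to_j: InteractionParams,
    fld: ResourceField,
    dynamics: DynamicsConfig,
    rng: np.random.Generator,
    extrema: PotentialExtrema | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler-Maruyama update of both contestants.

    Displacement per contestant: ``eta * F_total * dt`` plus independent
    Gaussian noise of per-coordinate variance ``2*D*dt``.
    """
    if extrema is None:
        extrema = find_extrema(ContestPotentialSpec.from_pair(params_to_i, params_to_j))
    fi = total_force(position_i, position_j, params_to_i, fld, extrema)
    fj = total_force(position_j, position_i, params_to_j, fld, extrema)
    sigma = math.sqrt(2.0 * dynamics.D * dynamics.dt)
    noise = sigma * rng.standard_normal((2, 2))
    new_i = np.asarray(position_i, float) + dynamics.eta * fi * dynamics.dt + noise[0]
    new_j = np.asarray(position_j, float) + dynamics.eta * fj * dynamics.dt + noise[1]
    return new_i, new_j


# ---------------------------------------------------------------------------
# Parameter schedule (interaction coefficients vs accumulated contest time)
# ---------------------------------------------------------------------------

class _ParamSchedule:
    """Interaction coefficients and extrema as a function of the number of
    in-contest steps k (t_sigma = k*dt).

    With zero cost rates the schedule is a single constant entry; with
    costs it is tabulated over every possible k up to the horizon, since
    t_sigma only ever advances in exact dt increments.
    """

    def __init__(
        self,
        spec: AssessmentSpec,
        profiles: tuple[ContestantProfile, ContestantProfile],
        cost: CostModel,
        dyn: DynamicsConfig,
    ):
        if cost.is_zero:
            t_sig = np.zeros(1)
        else:
            n_steps = int(round(dyn.max_time / dyn.dt)) + 1
            t_sig = np.arange(n_steps) * dyn.dt
        m_i, m_j = size_arrays(profiles, cost, t_sig)
        a_ji, d_ji = assess_arrays(spec, m_i, m_j)
        a_ij, d_ij = assess_arrays(spec, m_j, m_i)
        self.m_i, self.m_j = m_i, m_j
        self.a_ji, self.d_ji = a_ji, d_ji
        self.a_ij, self.d_ij = a_ij, d_ij
        self.exists, self.x_cap, self.x_cup = extrema_arrays(
            a_ji + a_ij, d_ji + d_ij, spec.beta
        )
        self.constant = cost.is_zero
        self.beta = spec.beta
        self.x0 = spec.x0

    def at(self, k: np.ndarray):
        idx = np.zeros_like(k) if self.constant else k
        return (
            self.a_ji[idx], self.d_ji[idx], self.a_ij[idx], self.d_ij[idx],
            self.exists[idx], self.x_cap[idx],
            self.m_i[idx], self.m_j[idx],
        )


# ---------------------------------------------------------------------------
# Vectorized ensemble engine
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Per-contest summary arrays of an ensemble simulation.

    ``winner_idx`` is 0 (contestant i), 1 (contestant j) or -1
    (undecided); ``first_cause`` uses the episode cause vocabulary, with
    "none" for contests that never formed.
    """

    n: int
    profiles: tuple[ContestantProfile, ContestantProfile]
    first_duration: np.ndarray
    first_cause: np.ndarray
    n_episodes: np.ndarray
    winner_idx: np.ndarray
    capture_time: np.ndarray
    theta_end: np.ndarray
    total_t_sigma: np.ndarray
    episodes: list[list[ContestEpisode]]
    chase_corr_sum: np.ndarray | None = None
    chase_corr_n: np.ndarray | None = None
    trajectories: list[Trajectory] | None = None

    @property
    def winner_ids(self) -> np.ndarray:
        ids = np.array([self.profiles[0].id, self.profiles[1].id, None], dtype=object)
        return ids[self.winner_idx]

    def outcome_records(self) -> list[OutcomeRecord]:
        out = []
        for w, ct, th, ts in zip(
            self.winner_idx, self.capture_time, self.theta_end, self.total_t_sigma
        ):
            out.append(
                OutcomeRecord(
                    winner=self.profiles[int(w)].id if w >= 0 else None,
                    capture_time=float(ct) if np.isfinite(ct) else None,
                    theta_end=float(th),
                    total_t_sigma=float(ts),
                )
            )
        return out


def simulate_ensemble(
    profiles: tuple[ContestantProfile, ContestantProfile],
    assessment: AssessmentSpec,
    cost: CostModel,
    fld: ResourceField,
    dynamics: DynamicsConfig,
    n: int = 1,
    initial_positions=None,
    stop: str = "outcome",
    record: bool = False,
    chase_stride: int | None = None,
    rng: np.random.Generator | None = None,
    engine: str = "auto",
) -> EnsembleResult:
    """Simulate ``n`` independent contests with shared configuration.

    ``initial_positions`` is broadcastable to shape (n, 2, 2)
    [contest, contestant, coordinate]; the default places contestant i at
    (-4, 0) and j at (4, 0) relative to the resource center.  ``stop``
    selects when each contest retires: "outcome" runs until a winner is
    decided (or horizon), "first_episode" until the first episode ends.
    ``chase_stride`` enables online accumulation of the chase correlator
    over in-contest windows of that many steps.

    ``engine`` selects the stepping implementation: "numpy" is the
    reference vectorized loop (required for ``record=True``), "compiled"
    a numba kernel with identical semantics but its own noise stream;
    "auto" picks the compiled kernel whenever recording is off.
    """
    if stop not in ("outcome", "first_episode"):
        raise ValueError("stop must be 'outcome' or 'first_episode'")
    if engine not in ("auto", "numpy", "compiled"):
        raise ValueError("engine must be 'auto', 'numpy' or 'compiled'")
    if rng is None:
        rng = np.random.default_rng(dynamics.seed)

    c = fld.center_array
    if initial_positions is None:
        initial_positions = np.array([[c + (-4.0, 0.0), c + (4.0, 0.0)]])
    pos = np.broadcast_to(np.asarray(initial_positions, float), (n, 2, 2)).copy()

    sched = _ParamSchedule(assessment, profiles, cost, dynamics)

    if engine == "auto":
        engine = "numpy" if record else "compiled"
    if engine == "compiled":
        if record:
            raise ValueError("trajectory recording requires the numpy engine")
        return _run_compiled(
            pos, profiles, sched, fld, dynamics, stop, chase_stride, rng
        )
    dt, eta, x0 = dynamics.dt, dynamics.eta, sched.x0
    sigma = math.sqrt(2.0 * dynamics.D * dt)
    min_sep = dynamics.min_separation
    n_steps = int(round(dynamics.max_time / dt))

    # per-contest state
    k = np.zeros(n, dtype=np.int64)             # in-contest step count
    in_contest = np.zeros(n, dtype=bool)
    n_episodes = np.zeros(n, dtype=np.int64)
    onset_t = np.full(n, np.nan)
    first_duration = np.full(n, np.nan)
    first_cause = np.full(n, "none", dtype=object)
    winner_idx = np.full(n, -1, dtype=np.int64)
    capture_time = np.full(n, np.nan)
    theta_end = np.full(n, np.nan)
    done = np.zeros(n, dtype=bool)
    episodes: list[list[ContestEpisode]] = [[] for _ in range(n)]

    do_chase = chase_stride is not None
    if do_chase:
        corr_sum = np.zeros(n)
        corr_cnt = np.zeros(n, dtype=np.int64)
        win_start = np.zeros((n, 2))
        win_axis = np.zeros((n, 2))
        win_len = np.zeros(n, dtype=np.int64)

    frames: list[list[tuple]] | None = [[] for _ in range(n)] if record else None

    warned_drift = False
    for s in range(n_steps + 1):
        t = s * dt
        active = ~done
        if not active.any():
            break

        a_ji, d_ji, a_ij, d_ij, exists, x_cap, m_i, m_j = sched.at(k)

        d_vec = pos[:, 0] - pos[:, 1]
        dist = np.sqrt(np.einsum("ij,ij->i", d_vec, d_vec))
        safe = np.where(dist > 0.0, dist, 1.0)
        xhat = d_vec / safe[:, None]
        xhat[dist == 0.0] = (1.0, 0.0)
        x = np.maximum(dist / x0, min_sep)

        now_in = exists & (x < x_cap) & active

        onset = now_in & ~in_contest
        if onset.any():
            onset_t[onset] = t
        escape = in_contest & ~now_in & active
        if escape.any():
            cause = np.where(exists[escape], "noise_escape", "cost_driven")
            idxs = np.nonzero(escape)[0]
            th = _end_angle_arrays(pos[idxs], c)
            for jj, ii in enumerate(idxs):
                ep = ContestEpisode(float(onset_t[ii]), t, str(cause[jj]))
                episodes[ii].append(ep)
                theta_end[ii] = th[jj]
                if n_episodes[ii] == 0:
                    first_duration[ii] = ep.duration
                    first_cause[ii] = ep.cause
            n_episodes[escape] += 1
            if stop == "first_episode":
                done[escape] = True
                active = ~done

        if do_chase:
            mid = 0.5 * (pos[:, 0] + pos[:, 1])
            if onset.any():
                win_start[onset] = mid[onset]
                win_len[onset] = 0
                larger_is_i = m_i >= m_j
                ax = np.where(larger_is_i[:, None], -xhat, xhat)  # larger -> smaller
                win_axis[onset] = ax[onset]
            cont = now_in & ~onset
            win_len[cont] += 1
            ready = cont & (win_len >= chase_stride)
            if ready.any():
                disp = mid[ready] - win_start[ready]
                norm = np.sqrt(np.einsum("ij,ij->i", disp, disp))
                ok = norm > 0.0
                dots = np.einsum(
                    "ij,ij->i", disp[ok] / norm[ok][:, None], win_axis[ready][ok]
                )
                idxs = np.nonzero(ready)[0]
                np.add.at(corr_sum, idxs[ok], dots)
                np.add.at(corr_cnt, idxs[ok], 1)
                win_start[ready] = mid[ready]
                win_len[ready] = 0
                larger_is_i = m_i >= m_j
                ax = np.where(larger_is_i[:, None], -xhat, xhat)
                win_axis[ready] = ax[ready]

        in_contest = now_in

        # capture check: resource claimed only while not in contest and
        # only after at least one completed episode
        if stop == "outcome":
            eligible = active & ~in_contest & (n_episodes >= 1)
            if eligible.any():
                di = np.linalg.norm(pos[:, 0] - c, axis=1)
                dj = np.linalg.norm(pos[:, 1] - c, axis=1)
                cap = eligible & (np.minimum(di, dj) < dynamics.capture_radius)
                if cap.any():
                    winner_idx[cap] = np.where(di[cap] < dj[cap], 0, 1)
                    capture_time[cap] = t
                    done[cap] = True
                    active = ~done

        if record and s % dynamics.sample_stride == 0:
            for ii in np.nonzero(active)[0]:
                ep_id = n_episodes[ii] if in_contest[ii] else -1
                frames[ii].append(
                    (t, pos[ii, 0, 0], pos[ii, 0, 1], pos[ii, 1, 0], pos[ii, 1, 1],
                     x[ii], m_i[ii], m_j[ii], int(in_contest[ii]), int(ep_id))
                )

        if s == n_steps:
            break

        # accrue contest time for the step about to be taken
        k[in_contest & active] += 1

        # forces
        g = np.exp(-sched.beta * x**2)
        pair_i = d_ji / x - 2.0 * a_ji * sched.beta * x * g
        pair_j = d_ij / x - 2.0 * a_ij * sched.beta * x * g
        F = np.empty_like(pos)
        F[:, 0] = (pair_i / x0)[:, None] * xhat
        F[:, 1] = (pair_j / x0)[:, None] * -xhat
        attend = ~exists | (x >= x_cap)
        if attend.any():
            for contestant in (0, 1):
                vec = c[None, :] - pos[:, contestant]
                r = np.sqrt(np.einsum("ij,ij->i", vec, vec))
                mag = fld.p / (r + fld.epsilon)
                safe_r = np.where(r > 0.0, r, 1.0)
                F[:, contestant] += (
                    attend[:, None] * (mag / safe_r)[:, None] * vec * (r > 0)[:, None]
                )

        drift = eta * dt * F
        max_disp = float(np.max(np.abs(drift[active]))) if active.any() else 0.0
        if max_disp > _UNSTABLE_DISPLACEMENT:
            raise RuntimeError(
                f"unstable integration step at t={t:.6g}: drift displacement "
                f"{max_disp:.3g} exceeds {_UNSTABLE_DISPLACEMENT}; reduce dt"
            )
        if max_disp > _WARN_DISPLACEMENT and not warned_drift:
            warnings.warn(
                f"large drift displacement {max_disp:.3g} per step at t={t:.6g}; "
                "consider a smaller dt",
                stacklevel=2,
            )
            warned_drift = True

        noise = sigma * rng.standard_normal((n, 2, 2))
        pos += (drift + noise) * active[:, None, None]

    # close episodes still open at the horizon
    open_ep = in_contest & ~done
    if open_ep.any():
        t_end = n_steps * dt
        idxs = np.nonzero(open_ep)[0]
        th = _end_angle_arrays(pos[idxs], c)
        for jj, ii in enumerate(idxs):
            ep = ContestEpisode(float(onset_t[ii]), t_end, "horizon")
            episodes[ii].append(ep)
            theta_end[ii] = th[jj]
            if n_episodes[ii] == 0:
                first_duration[ii] = ep.duration
                first_cause[ii] = "horizon"
        n_episodes[open_ep] += 1

    trajectories = None
    if record:
        trajectories = [
            Trajectory(pd.DataFrame(f, columns=TRAJECTORY_COLUMNS)) for f in frames
        ]

    return EnsembleResult(
        n=n,
        profiles=profiles,
        first_duration=first_duration,
        first_cause=first_cause,
        n_episodes=n_episodes,
        winner_idx=winner_idx,
        capture_time=capture_time,
        theta_end=theta_end,
        total_t_sigma=k * dt,
        episodes=episodes,
        chase_corr_sum=corr_sum if do_chase else None,
        chase_corr_n=corr_cnt if do_chase else None,
        trajectories=trajectories,
    )


def _run_compiled(
    pos: np.ndarray,
    profiles: tuple[ContestantProfile, ContestantProfile],
    sched: _ParamSchedule,
    fld: ResourceField,
    dynamics: DynamicsConfig,
    stop: str,
    chase_stride: int | None,
    rng: np.random.Generator,
) -> EnsembleResult:
    """Dispatch to the numba kernel and assemble an EnsembleResult.

    The kernel tracks only the first episode per contest; the per-contest
    episode lists therefore contain at most that one episode.
    """
    from ._engine import CAUSE_NAMES, run_kernel

    n = pos.shape[0]
    c = fld.center_array
    seed = int(rng.integers(2**31))
    (first_onset, first_end, first_cause, n_episodes, winner_idx, capture_time,
     theta_end, k, corr_sum, corr_cnt, error_flag, error_t) = run_kernel(
        pos,
        sched.a_ji, sched.d_ji, sched.a_ij, sched.d_ij,
        sched.exists, np.nan_to_num(sched.x_cap, nan=-1.0),
        sched.m_i, sched.m_j,
        sched.constant,
        sched.beta, sched.x0,
        dynamics.dt, dynamics.eta,
        math.sqrt(2.0 * dynamics.D * dynamics.dt),
        dynamics.min_separation,
        int(round(dynamics.max_time / dynamics.dt)),
        fld.p, fld.epsilon, float(c[0]), float(c[1]),
        dynamics.capture_radius,
        stop == "first_episode",
        0 if chase_stride is None else int(chase_stride),
        seed,
    )
    if error_flag:
        raise RuntimeError(
            f"unstable integration step at t={error_t:.6g}: drift displacement "
            f"exceeds {_UNSTABLE_DISPLACEMENT}; reduce dt"
        )
    episodes: list[list[ContestEpisode]] = []
    first_duration = np.full(n, np.nan)
    cause_names = np.full(n, "none", dtype=object)
    for w in range(n):
        if first_cause[w] != 0:
            ep = ContestEpisode(
                float(first_onset[w]), float(first_end[w]),
                CAUSE_NAMES[first_cause[w]],
            )
            episodes.append([ep])
            first_duration[w] = ep.duration
            cause_names[w] = ep.cause
        else:
            episodes.append([])
    do_chase = chase_stride is not None
    return EnsembleResult(
        n=n,
        profiles=profiles,
        first_duration=first_duration,
        first_cause=cause_names,
        n_episodes=n_episodes,
        winner_idx=winner_idx,
        capture_time=capture_time,
        theta_end=theta_end,
        total_t_sigma=k * dynamics.dt,
        episodes=episodes,
        chase_corr_sum=corr_sum if do_chase else None,
        chase_corr_n=corr_cnt if do_chase else None,
        trajectories=None,
    )


# ---------------------------------------------------------------------------
# Front ends
# ---------------------------------------------------------------------------

def run_simulation(
    profiles: tuple[ContestantProfile, ContestantProfile],
    assessment: AssessmentSpec,
    cost: CostModel,
    fld: ResourceField,
    dynamics: DynamicsConfig,
    initial_positions=None,
    rng: np.random.Generator | None = None,
) -> tuple[Trajectory, list[ContestEpisode], OutcomeRecord]:
    """Simulate a single contest and return its full recorded history."""
    res = simulate_ensemble(
        profiles, assessment, cost, fld, dynamics,
        n=1, initial_positions=initial_positions,
        stop="outcome", record=True, rng=rng,
    )
    return res.trajectories[0], res.episodes[0], res.outcome_records()[0]


def simulate_trajectories(
    n: int,
    profiles: tuple[ContestantProfile, ContestantProfile],
    assessment: AssessmentSpec,
    cost: CostModel,
    fld: ResourceField,
    dynamics: DynamicsConfig,
    initial_positions=None,
    rng: np.random.Generator | None = None,
) -> list[Trajectory]:
    """Record ``n`` full contest trajectories (the extraction pipeline's input)."""
    res = simulate_ensemble(
        profiles, assessment, cost, fld, dynamics,
        n=n, initial_positions=initial_positions,
        stop="outcome", record=True, rng=rng,
    )
    return res.trajectories
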