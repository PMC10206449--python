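"""Derived contest observables and ensemble experiments.

Connects the potential landscape to measurable contest statistics:

* the contest bounding energy ``U = V_contest(x_cap) - V_contest(x_cup)``,
  the well depth trapping the transient bound state;
* the Kramers-type mean noise-driven duration ``t_c = Pi * exp(U/T_eff)``
  with effective temperature ``T_eff = 2*D*eta`` (the relative coordinate
  diffuses with twice the single-contestant coefficient);
* the inter-contestant force asymmetry ``dF(x)`` that drives chase
  dynamics, and the chase correlator measured from trajectories;
* win / positional-advantage probabilities of fair-start contests;
* the duration-trend experiment comparing empirical mean durations with
  the noise-driven and cost-driven theory across size grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_potentials import (
    ContestPotentialSpec,
    InteractionParams,
    ResourceField,
    contest_potential,
    find_extrema,
    pair_force,
)
from .assessment_costs import (
    AssessmentSpec,
    ContestantProfile,
    CostModel,
    contest_spec_at,
    cost_driven_duration,
    pair_params,
)
from .contest_simulator import (
    DynamicsConfig,
    OutcomeRecord,
    Trajectory,
    fair_start_setup,
    simulate_ensemble,
)

__all__ = [
    "DurationTheory",
    "ChaseStats",
    "WinProbability",
    "bounding_energy",
    "bounding_energy_spec",
    "effective_temperature",
    "theoretical_duration",
    "relative_duration",
    "force_asymmetry",
    "chase_correlator",
    "win_probability",
    "closer_probability",
    "duration_trend_experiment",
    "kramers_scaling",
    "chase_sweep",
    "fair_contest_experiment",
]


# ---------------------------------------------------------------------------
# Bounding energy and theoretical durations
# ---------------------------------------------------------------------------

def bounding_energy_spec(spec: ContestPotentialSpec) -> float:
    """Well depth of a contest potential; 0.0 when no well exists."""
    ex = find_extrema(spec)
    if not ex.exists:
        return 0.0
    return float(
        contest_potential(ex.x_cap, spec) - contest_potential(ex.x_cup, spec)
    )


def bounding_energy(
    params_to_i: InteractionParams, params_to_j: InteractionParams
) -> float:
    """Contest bounding energy U from the two directed parameter sets.

    U = V_contest(x_cap) - V_contest(x_cup) >= 0; invariant under
    exchanging the contestants.  Returns 0.0 when the combined potential
    has no stationary points (the contest cannot form).
    """
    return bounding_energy_spec(ContestPotentialSpec.from_pair(params_to_i, params_to_j))


def effective_temperature(dynamics: DynamicsConfig) -> float:
    """T_eff = 2*D*eta of the relative contest coordinate."""
    return 2.0 * dynamics.D * dynamics.eta


def theoretical_duration(U: float, Pi: float = 1.0, T_eff: float = 1.0) -> float:
    """Kramers-type mean noise-driven contest duration Pi * exp(U/T_eff)."""
    if T_eff <= 0:
        raise ValueError("T_eff must be strictly positive")
    return Pi * math.exp(U / T_eff)


def relative_duration(
    U: float,
    U_star: float,
    Pi: float = 1.0,
    Pi_star: float = 1.0,
    T_eff: float = 1.0,
) -> float:
    """Duration relative to the reference (size-matched, m = 1) contest."""
    return (Pi / Pi_star) * math.exp((U - U_star) / T_eff)


@dataclass(frozen=True)
class DurationTheory:
    """Theoretical duration bundle for one pair of effective sizes."""

    U: float
    T_eff: float
    Pi: float
    t_c: float
    t_c_star: float
    tau_c: float
    t_cost: float | None = None
    tau_cost: float | None = None

    @classmethod
    def from_sizes(
        cls,
        assessment: AssessmentSpec,
        m_i: float,
        m_j: float,
        dynamics: DynamicsConfig | None = None,
        Pi: float = 1.0,
        cost: CostModel | None = None,
    ) -> "DurationTheory":
        dyn = dynamics or DynamicsConfig()
        T_eff = effective_temperature(dyn)
        U = bounding_energy_spec(contest_spec_at(assessment, m_i, m_j))
        U_star = bounding_energy_spec(contest_spec_at(assessment, 1.0, 1.0))
        t_c = theoretical_duration(U, Pi, T_eff)
        t_c_star = theoretical_duration(U_star, Pi, T_eff)
        t_cost = tau_cost = None
        if cost is not None and not cost.is_zero:
            profiles = (ContestantProfile("i", m_i), ContestantProfile("j", m_j))
            t_cost = cost_driven_duration(assessment, profiles, cost)
            if t_cost is not None:
                tau_cost = t_cost / t_c_star
        return cls(
            U=U, T_eff=T_eff, Pi=Pi, t_c=t_c, t_c_star=t_c_star,
            tau_c=t_c / t_c_star, t_cost=t_cost, tau_cost=tau_cost,
        )


# ---------------------------------------------------------------------------
# Force asymmetry and chase statistics
# ---------------------------------------------------------------------------

def force_asymmetry(
    x, params_to_i: InteractionParams, params_to_j: InteractionParams
):
    """Asymmetry dF(x) = F_{i->j}(x) - F_{j->i}(x) between the directed forces.

    Zero for symmetric pairs; its magnitude near the well minimum sets the
    extent of chase dynamics during the contest.
    """
    return pair_force(x, params_to_j) - pair_force(x, params_to_i)


@dataclass(frozen=True)
class ChaseStats:
    """Temporal mean of the chase correlator with its standard error."""

    correlator: float
    sem: float
    n_frames: int


def chase_correlator(trajectory: Trajectory, stride: int = 10) -> ChaseStats:
    """Chase correlator of one recorded trajectory.

    Over in-contest frames only, the midpoint displacement direction over
    windows of ``stride`` frames is dotted with the unit chase axis at the
    window start.  The chase axis points from the larger contestant toward
    the smaller, so perfect pursuit of the smaller by the larger yields
    +1.  Windows with zero midpoint displacement are skipped.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    df = trajectory.frames
    dots: list[float] = []
    for _, ep in df[df["episode_id"] >= 0].groupby("episode_id"):
        n = len(ep)
        if n < stride + 1:
            continue
        xi = ep[["xi", "yi"]].to_numpy()
        xj = ep[["xj", "yj"]].to_numpy()
        mid = 0.5 * (xi + xj)
        m_i = ep["m_i"].to_numpy()
        m_j = ep["m_j"].to_numpy()
        for w0 in range(0, n - stride, stride):
            w1 = w0 + stride
            disp = mid[w1] - mid[w0]
            norm = np.linalg.norm(disp)
            if norm == 0.0:
                continue
            axis = xj[w0] - xi[w0] if m_i[w0] >= m_j[w0] else xi[w0] - xj[w0]
            axis_norm = np.linalg.norm(axis)
            if axis_norm == 0.0:
                continue
            dots.append(float(disp @ axis) / (norm * axis_norm))
    if len(dots) < 1:
        raise ValueError("trajectory has too few in-contest frames at this stride")
    arr = np.asarray(dots)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else math.nan
    return ChaseStats(correlator=float(arr.mean()), sem=sem, n_frames=len(arr))


# ---------------------------------------------------------------------------
# Outcome statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WinProbability:
    """Win-rate estimate with an exact (Clopper-Pearson) confidence interval."""

    p: float
    ci_low: float
    ci_high: float
    n_decided: int
    n_wins: int


def win_probability(
    outcomes: list[OutcomeRecord], focal: str, confidence: float = 0.95
) -> WinProbability:
    """Fraction of decided contests won by the focal contestant."""
    decided = [o for o in outcomes if o.winner is not None]
    if not decided:
        raise ValueError("no decided outcomes")
    wins = sum(1 for o in decided if o.winner == focal)
    test = stats.binomtest(wins, len(decided))
    ci = test.proportion_ci(confidence_level=confidence, method="exact")
    return WinProbability(
        p=wins / len(decided),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_decided=len(decided),
        n_wins=wins,
    )


def closer_probability(outcomes: list[OutcomeRecord]) -> float:
    """P(|theta_end| < 90 deg): contestant i ends the contest closer to the
    resource."""
    thetas = np.array([o.theta_end for o in outcomes], dtype=float)
    thetas = thetas[np.isfinite(thetas)]
    if len(thetas) == 0:
        raise ValueError("no outcomes with a defined end angle")
    return float(np.mean(np.abs(thetas) < 90.0))


# ---------------------------------------------------------------------------
# Ensemble experiments
# ---------------------------------------------------------------------------

def _duration_batch(
    assessment: AssessmentSpec,
    mu_i: float,
    mu_j: float,
    cost: CostModel,
    fld: ResourceField,
    dynamics: DynamicsConfig,
    n: int,
    rng: np.random.Generator,
    chase_stride: int | None = None,
):
    """First-episode durations for one size pair, starting in the bound state.

    Contests are initialized fair-start at separation ``x_cup`` (the well
    minimum), so the first episode duration is the first-passage time out
    of the bound state — the model's contest duration.
    """
    profiles = (ContestantProfile("i", mu_i), ContestantProfile("j", mu_j))
    spec = contest_spec_at(assessment, mu_i, mu_j)
    ex = find_extrema(spec)
    if not ex.exists:
        return None
    pos_i, pos_j = fair_start_setup(fld, ex, r0=ex.x_cap, separation=ex.x_cup)
    return simulate_ensemble(
        profiles, assessment, cost, fld, dynamics,
        n=n,
        initial_positions=np.array([[pos_i, pos_j]]),
        stop="first_episode",
        chase_stride=chase_stride,
        rng=rng,
    )


def duration_trend_experiment(
    assessment: AssessmentSpec,
    size_grid,
    cost: CostModel,
    n: int,
    dynamics: DynamicsConfig,
    fld: ResourceField | None = None,
    protocols=("matched", "smaller_varies", "larger_varies"),
    Pi: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean first-episode durations over the three size protocols.

    Protocols fix the rival size: "matched" (mu_j = mu_i), "smaller_varies"
    (mu_j = 1.2, the focal contestant is the smaller), "larger_varies"
    (mu_j = 0.8, the focal contestant is the larger).  Returns one row per
    (protocol, mu_i): empirical mean +- SEM alongside the bounding-energy
    theory (noise-driven t_c, cost-driven t_cost where applicable).
    """
    fld = fld or ResourceField()
    rival = {"matched": None, "smaller_varies": 1.2, "larger_varies": 0.8}
    rows = []
    cond = 0
    for protocol in protocols:
        if protocol not in rival:
            raise ValueError(f"unknown protocol {protocol!r}")
        for mu_i in size_grid:
            mu_j = mu_i if rival[protocol] is None else rival[protocol]
            rng = np.random.default_rng([seed, cond])
            cond += 1
            res = _duration_batch(
                assessment, mu_i, mu_j, cost, fld, dynamics, n, rng
            )
            theory = DurationTheory.from_sizes(
                assessment, mu_i, mu_j, dynamics, Pi=Pi, cost=cost
            )
            if res is None:
                mean = sem = math.nan
            else:
                durs = res.first_duration[np.isfinite(res.first_duration)]
                mean = float(durs.mean()) if len(durs) else math.nan
                sem = (
                    float(durs.std(ddof=1) / math.sqrt(len(durs)))
                    if len(durs) > 1
                    else math.nan
                )
            rows.append(
                {
                    "protocol": protocol,
                    "mu_i": mu_i,
                    "mu_j": mu_j,
                    "n": n,
                    "mean_duration": mean,
                    "sem": sem,
                    "U": theory.U,
                    "t_c_theory": theory.t_c,
                    "tau_c_theory": theory.tau_c,
                    "t_cost_theory": theory.t_cost,
                    "tau_cost_theory": theory.tau_cost,
                }
            )
    return pd.DataFrame(rows)


def kramers_scaling(
    alphas,
    delta: float,
    n: int,
    dynamics: DynamicsConfig,
    fld: ResourceField | None = None,
    seed: int = 0,
):
    """Mean escape time vs bounding energy across symmetric no-cost specs.

    For each attraction strength alpha (shared by both contestants, with
    repulsion ``delta``), simulates ``n`` bound-state escapes and regresses
    ln(mean duration) on U.  The Kramers picture predicts slope 1/T_eff.
    Returns ``(table, fit)`` with ``fit`` a scipy linregress result.
    """
    fld = fld or ResourceField()
    cost = CostModel()
    rows = []
    for idx, alpha in enumerate(alphas):
        assessment = AssessmentSpec(alpha0=alpha, delta0=delta)
        rng = np.random.default_rng([seed, idx])
        res = _duration_batch(assessment, 1.0, 1.0, cost, fld, dynamics, n, rng)
        if res is None:
            raise ValueError(f"alpha = {alpha}: contest potential has no well")
        U = bounding_energy_spec(contest_spec_at(assessment, 1.0, 1.0))
        durs = res.first_duration[np.isfinite(res.first_duration)]
        rows.append(
            {
                "alpha": alpha,
                "U": U,
                "n": len(durs),
                "mean_duration": float(durs.mean()),
                "sem": float(durs.std(ddof=1) / math.sqrt(len(durs))),
            }
        )
    table = pd.DataFrame(rows)
    fit = stats.linregress(table["U"], np.log(table["mean_duration"]))
    return table, fit


def chase_sweep(
    assessment: AssessmentSpec,
    ratios,
    n: int,
    dynamics: DynamicsConfig,
    fld: ResourceField | None = None,
    stride: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Chase correlator vs effective size ratio (contestant i the larger).

    One row per ratio: pooled correlator over all in-contest windows, its
    SEM, and the theoretical force asymmetry dF(x_cup) at the initial
    sizes for concordance checks.
    """
    fld = fld or ResourceField()
    cost = CostModel()
    rows = []
    for idx, q in enumerate(ratios):
        mu_i, mu_j = float(q), 1.0
        rng = np.random.default_rng([seed, idx])
        res = _duration_batch(
            assessment, mu_i, mu_j, cost, fld, dynamics, n, rng,
            chase_stride=stride,
        )
        if res is None:
            raise ValueError(f"ratio {q}: contest potential has no well")
        total = int(res.chase_corr_n.sum())
        if total == 0:
            raise ValueError(f"ratio {q}: no chase windows accumulated")
        per = res.chase_corr_sum[res.chase_corr_n > 0] / res.chase_corr_n[
            res.chase_corr_n > 0
        ]
        corr = float(res.chase_corr_sum.sum() / total)
        sem = float(per.std(ddof=1) / math.sqrt(len(per))) if len(per) > 1 else math.nan
        p_i, p_j = pair_params(assessment, mu_i, mu_j)
        ex = find_extrema(ContestPotentialSpec.from_pair(p_i, p_j))
        rows.append(
            {
                "ratio": q,
                "correlator": corr,
                "sem": sem,
                "n_windows": total,
                "dF_at_xcup": float(force_asymmetry(ex.x_cup, p_i, p_j)),
            }
        )
    return pd.DataFrame(rows)


def fair_contest_experiment(
    assessment: AssessmentSpec,
    ratios,
    n: int,
    dynamics: DynamicsConfig,
    fld: ResourceField | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fair-start contests to outcome: win and positional-advantage rates.

    Contestant i carries the size ratio (mu_i = ratio, mu_j = 1); both
    start on a circle around the resource separated by exactly the onset
    distance x_cap.  One row per ratio with the win probability of i, its
    confidence interval, and P(|theta| < 90 deg).
    """
    fld = fld or ResourceField()
    cost = CostModel()
    rows = []
    for idx, q in enumerate(ratios):
        mu_i, mu_j = float(q), 1.0
        profiles = (ContestantProfile("i", mu_i), ContestantProfile("j", mu_j))
        spec = contest_spec_at(assessment, mu_i, mu_j)
        ex = find_extrema(spec)
        if not ex.exists:
            raise ValueError(f"ratio {q}: contest potential has no onset distance")
        pos_i, pos_j = fair_start_setup(fld, ex)
        rng = np.random.default_rng([seed, idx])
        res = simulate_ensemble(
            profiles, assessment, cost, fld, dynamics,
            n=n,
            initial_positions=np.array([[pos_i, pos_j]]),
            stop="outcome",
            rng=rng,
        )
        outcomes = res.outcome_records()
        wp = win_probability(outcomes, focal="i")
        rows.append(
            {
                "ratio": q,
                "p_win": wp.p,
                "ci_low": wp.ci_low,
                "ci_high": wp.ci_high,
                "n_decided": wp.n_decided,
                "p_closer": closer_probability(outcomes),
            }
        )
    return pd.DataFrame(rows)
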