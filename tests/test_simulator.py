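"""Langevin stepping, episode bookkeeping, fair starts and end angles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from contestdyn import (
    AssessmentSpec,
    ContestantProfile,
    ContestPotentialSpec,
    CostModel,
    DynamicsConfig,
    InteractionParams,
    ResourceField,
    Trajectory,
    end_angle,
    fair_start_setup,
    find_extrema,
    run_simulation,
    simulate_ensemble,
    step,
)
from contestdyn.core_potentials import extrema_arrays
from contestdyn.assessment_costs import assess_arrays, size_arrays

FLD = ResourceField(p=4.0, epsilon=1.0)
SYMMETRIC = AssessmentSpec(alpha0=7.0, delta0=3.0)
MATCHED = (ContestantProfile("i", 1.0), ContestantProfile("j", 1.0))


class TestStep:
    def test_deterministic_drift_toward_resource(self):
        """With D = 0 and no rival interaction, one step moves the
        contestant p/(r+eps)*eta*dt toward the center."""
        dyn = DynamicsConfig(D=0.0, dt=1e-3)
        rng = np.random.default_rng(0)
        off = InteractionParams(0.0, 0.0)
        new_i, _ = step([1.0, 0.0], [100.0, 0.0], off, off, FLD, dyn, rng)
        assert new_i == pytest.approx([1.0 - 0.002, 0.0], abs=1e-12)

    def test_noiseless_pair_relaxes_to_well_minimum(self):
        dyn = DynamicsConfig(D=0.0, dt=1e-3, max_time=5.0)
        init = np.array([[[-0.5, 0.0], [0.5, 0.0]]])
        res = simulate_ensemble(
            MATCHED, SYMMETRIC, CostModel(), FLD, dyn,
            n=1, initial_positions=init, record=True,
        )
        x_cup = find_extrema(ContestPotentialSpec(14.0, 6.0)).x_cup
        assert res.trajectories[0].x_ij[-1] == pytest.approx(x_cup, abs=1e-4)
        # no noise => no escape: the single episode runs to the horizon
        assert res.episodes[0][0].cause == "horizon"

    def test_free_diffusion_msd(self):
        """Mean squared displacement of force-free walkers equals 4*D*t
        within three standard errors."""
        dyn = DynamicsConfig(D=0.5, dt=1e-3, max_time=0.2, seed=7)
        off = AssessmentSpec(alpha0=1e-12, delta0=1e-12)
        weak = ResourceField(p=1e-12, epsilon=1.0)
        far = np.array([[[0.0, 0.0], [1e6, 0.0]]])
        res = simulate_ensemble(
            (ContestantProfile("i", 1.0), ContestantProfile("j", 1.0)),
            off, CostModel(), weak, dyn,
            n=1000, initial_positions=far, record=True,
            engine="numpy",
        )
        disp2 = []
        for traj, start in zip(res.trajectories, far[0][None].repeat(1000, 0)):
            last = traj.frames.iloc[-1]
            disp2.append((last.xi - 0.0) ** 2 + (last.yi - 0.0) ** 2)
            disp2.append((last.xj - 1e6) ** 2 + (last.yj - 0.0) ** 2)
        disp2 = np.asarray(disp2)
        t_final = res.trajectories[0].t[-1]
        expected = 4.0 * 0.5 * t_final
        sem = disp2.std(ddof=1) / math.sqrt(len(disp2))
        assert abs(disp2.mean() - expected) < 3.0 * sem

    def test_unstable_step_aborts_with_diagnostic(self):
        wild = AssessmentSpec(alpha0=1e6, delta0=1e6)
        dyn = DynamicsConfig(D=0.0, dt=0.5, max_time=2.0)
        init = np.array([[[-0.05, 0.0], [0.05, 0.0]]])
        with pytest.raises(RuntimeError, match="unstable"):
            simulate_ensemble(
                MATCHED, wild, CostModel(), FLD, dyn,
                n=1, initial_positions=init, engine="numpy",
            )

    def test_marginal_step_size_warns(self):
        dyn = DynamicsConfig(D=0.0, dt=0.05, max_time=1.0)
        init = np.array([[[-0.5, 0.0], [0.5, 0.0]]])
        with pytest.warns(UserWarning, match="drift displacement"):
            simulate_ensemble(
                MATCHED, SYMMETRIC, CostModel(), FLD, dyn,
                n=1, initial_positions=init, engine="numpy",
            )


class TestReproducibilityAndConsistency:
    def test_identical_seed_gives_bit_identical_trajectories(self):
        dyn = DynamicsConfig(D=0.5, dt=1e-3, max_time=2.0, seed=123)
        a = run_simulation(MATCHED, SYMMETRIC, CostModel(), FLD, dyn)
        b = run_simulation(MATCHED, SYMMETRIC, CostModel(), FLD, dyn)
        pd.testing.assert_frame_equal(a[0].frames, b[0].frames)
        assert a[1] == b[1]
        import dataclasses

        np.testing.assert_equal(  # nan-aware field comparison
            dataclasses.asdict(a[2]), dataclasses.asdict(b[2])
        )

    def test_compiled_engine_reproducible_and_matches_numpy_when_deterministic(self):
        dyn = DynamicsConfig(D=0.0, dt=1e-3, max_time=4.0, seed=5)
        init = np.array([[[-0.6, 0.3], [0.7, -0.2]]])
        kwargs = dict(n=1, initial_positions=init, stop="first_episode")
        r_np = simulate_ensemble(MATCHED, SYMMETRIC, CostModel(), FLD, dyn,
                                 engine="numpy", **kwargs)
        r_nb = simulate_ensemble(MATCHED, SYMMETRIC, CostModel(), FLD, dyn,
                                 engine="compiled", **kwargs)
        assert r_np.first_duration == pytest.approx(r_nb.first_duration, nan_ok=True)
        assert list(r_np.first_cause) == list(r_nb.first_cause)
        np.testing.assert_allclose(r_np.theta_end, r_nb.theta_end)
        np.testing.assert_array_equal(r_np.total_t_sigma, r_nb.total_t_sigma)

    def test_in_contest_flag_matches_recomputation_from_frames(self):
        """The stored flag must equal x_ij < x_cap(t_sigma) recomputed from
        the stored separations and the cost schedule."""
        cost = CostModel(K_self=0.2, K_ij=0.0)
        dyn = DynamicsConfig(D=0.5, dt=1e-3, max_time=30.0, seed=17)
        prof = MATCHED
        ass = AssessmentSpec.pure_self()
        traj, episodes, outcome = run_simulation(prof, ass, cost, FLD, dyn)
        df = traj.frames
        # rebuild t_sigma per frame from the flags, then the schedule
        t_sigma = np.concatenate(
            [[0.0], np.cumsum(df.in_contest.to_numpy()[:-1]) * dyn.dt]
        )
        m_i, m_j = size_arrays(prof, cost, t_sigma)
        a_ji, d_ji = assess_arrays(ass, m_i, m_j)
        a_ij, d_ij = assess_arrays(ass, m_j, m_i)
        exists, x_cap, _ = extrema_arrays(a_ji + a_ij, d_ji + d_ij, ass.beta)
        expected = exists & (df.x_ij.to_numpy() < x_cap)
        assert np.array_equal(expected, df.in_contest.to_numpy().astype(bool))
        assert np.allclose(m_i, df.m_i.to_numpy(), rtol=1e-12)

    def test_frame_times_strictly_increase(self):
        dyn = DynamicsConfig(D=0.5, dt=1e-3, max_time=1.0, seed=2, sample_stride=7)
        traj, _, _ = run_simulation(MATCHED, SYMMETRIC, CostModel(), FLD, dyn)
        assert np.all(np.diff(traj.t) > 0)


class TestEpisodesAndCosts:
    def test_cost_driven_episode_terminates_near_theory(self):
        """With heavy self-costs the first episode ends by well collapse at
        a simulated time within 10% of the analytic cost-driven duration."""
        from contestdyn import cost_driven_duration

        cost = CostModel(K_self=0.2, K_ij=0.0)
        ass = AssessmentSpec.pure_self()
        t_cost = cost_driven_duration(ass, MATCHED, cost)
        ex = find_extrema(ContestPotentialSpec(14.0, 6.0))
        pos = fair_start_setup(FLD, ex, r0=ex.x_cap, separation=ex.x_cup)
        # weak noise: termination dominated by the accrued costs, so the
        # simulated episode length isolates the well-collapse mechanism
        dyn = DynamicsConfig(D=0.01, dt=1e-3, max_time=100.0)
        res = simulate_ensemble(
            MATCHED, ass, cost, FLD, dyn, n=200,
            initial_positions=np.array([pos]), stop="first_episode",
            rng=np.random.default_rng(31),
        )
        cost_driven = res.first_cause == "cost_driven"
        assert cost_driven.mean() > 0.5  # most runs survive to the collapse
        mean_dur = res.first_duration[cost_driven].mean()
        assert mean_dur == pytest.approx(t_cost, rel=0.10)

    def test_approach_run_produces_contest_near_the_well(self):
        """Canonical setup: attraction to the resource brings the pair into
        contest range; during episodes the separation concentrates near
        the well minimum."""
        dyn = DynamicsConfig(D=0.5, dt=1e-3, max_time=200.0, seed=9)
        traj, episodes, outcome = run_simulation(
            MATCHED, SYMMETRIC, CostModel(), FLD, dyn
        )
        assert len(episodes) >= 1
        in_c = traj.frames.in_contest.to_numpy().astype(bool)
        assert in_c.any()
        x_cup = find_extrema(ContestPotentialSpec(14.0, 6.0)).x_cup
        med = np.median(traj.x_ij[in_c])
        assert abs(med - x_cup) < 0.25

    def test_t_sigma_accrues_only_in_contest(self):
        dyn = DynamicsConfig(D=0.5, dt=1e-3, max_time=50.0, seed=13)
        traj, episodes, outcome = run_simulation(
            MATCHED, SYMMETRIC, CostModel(), FLD, dyn
        )
        frames_in = int(traj.frames.in_contest.sum())
        assert outcome.total_t_sigma == pytest.approx(frames_in * dyn.dt, abs=1e-9)


class TestFairStart:
    EX = find_extrema(ContestPotentialSpec(14.0, 6.0))

    def test_equilateral_default(self):
        pos_i, pos_j = fair_start_setup(FLD, self.EX)
        x_cap = self.EX.x_cap
        assert np.linalg.norm(pos_i) == pytest.approx(x_cap, abs=1e-12)
        assert np.linalg.norm(pos_j) == pytest.approx(x_cap, abs=1e-12)
        assert np.linalg.norm(pos_i - pos_j) == pytest.approx(x_cap, abs=1e-12)

    @pytest.mark.parametrize("r0", [0.8, 1.3, 4.0])
    def test_chord_geometry(self, r0):
        pos_i, pos_j = fair_start_setup(FLD, self.EX, r0=r0)
        assert np.linalg.norm(pos_i - pos_j) == pytest.approx(
            self.EX.x_cap, abs=1e-12
        )
        assert np.linalg.norm(pos_i) == pytest.approx(r0, abs=1e-12)
        assert np.linalg.norm(pos_j) == pytest.approx(r0, abs=1e-12)
        # mirror symmetry about the axis through the center
        assert pos_i[0] == pytest.approx(pos_j[0], abs=1e-12)
        assert pos_i[1] == pytest.approx(-pos_j[1], abs=1e-12)

    def test_too_small_circle_rejected(self):
        with pytest.raises(ValueError, match="r0"):
            fair_start_setup(FLD, self.EX, r0=0.4 * self.EX.x_cap)

    def test_offcenter_resource(self):
        fld = ResourceField(p=4.0, epsilon=1.0, center=(2.0, -1.0))
        pos_i, pos_j = fair_start_setup(fld, self.EX)
        c = np.array([2.0, -1.0])
        assert np.linalg.norm(pos_i - c) == pytest.approx(self.EX.x_cap, abs=1e-12)


class TestEndAngle:
    @pytest.mark.parametrize(
        "ri, rj, expected_abs",
        [
            ((1.0, 0.0), (3.0, 0.0), 0.0),     # i between resource and j
            ((3.0, 0.0), (1.0, 0.0), 180.0),   # roles reversed
            ((1.0, 1.0), (1.0, -1.0), 90.0),   # equidistant
        ],
    )
    def test_collinear_and_boundary_cases(self, ri, rj, expected_abs):
        assert abs(end_angle(ri, rj, FLD)) == pytest.approx(expected_abs, abs=1e-9)

    def test_degenerate_midpoint_rejected(self):
        with pytest.raises(ValueError):
            end_angle([1.0, 0.0], [-1.0, 0.0], FLD)

    @given(
        xi=st.floats(-5, 5), yi=st.floats(-5, 5),
        xj=st.floats(-5, 5), yj=st.floats(-5, 5),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_angle_classifies_who_is_closer(self, xi, yi, xj, yj):
        """|theta| < 90 deg holds exactly when i is strictly closer."""
        ri = np.array([xi, yi])
        rj = np.array([xj, yj])
        mid = 0.5 * (ri + rj)
        if (
            np.linalg.norm(mid) < 1e-9
            or np.linalg.norm(ri - rj) < 1e-9
            or abs(np.linalg.norm(ri) - np.linalg.norm(rj)) < 1e-9
        ):
            return
        theta = end_angle(ri, rj, FLD)
        i_closer = np.linalg.norm(ri) < np.linalg.norm(rj)
        assert (abs(theta) < 90.0) == i_closer


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        dyn = DynamicsConfig(D=0.5, dt=1e-3, max_time=1.0, seed=3, sample_stride=5)
        traj, _, _ = run_simulation(MATCHED, SYMMETRIC, CostModel(), FLD, dyn)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        back = Trajectory.read_csv(path)
        for col in traj.frames.columns:
            np.testing.assert_allclose(
                back.frames[col].to_numpy(dtype=float),
                traj.frames[col].to_numpy(dtype=float),
                rtol=0, atol=1e-12,
            )

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,xi\n0,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            Trajectory.read_csv(path)


def test_invalid_dynamics_rejected():
    with pytest.raises(ValueError):
        DynamicsConfig(dt=0.0)
    with pytest.raises(ValueError):
        DynamicsConfig(D=-0.5)
    with pytest.raises(ValueError):
        DynamicsConfig(sample_stride=0)
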