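"""Compiled inner loop for unrecorded contest ensembles.

Scalar per-walker Euler-Maruyama stepping with episode, capture and chase
bookkeeping, mirroring the semantics of the pure-numpy loop in
``contest_simulator.simulate_ensemble`` (which remains the reference
implementation and the only path that records trajectories).  Cause
codes: 0 none, 1 noise_escape, 2 cost_driven, 3 horizon.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

CAUSE_NONE = 0
CAUSE_NOISE = 1
CAUSE_COST = 2
CAUSE_HORIZON = 3
CAUSE_NAMES = ("none", "noise_escape", "cost_driven", "horizon")


@njit(cache=True)
def _theta_deg(xi0, xi1, xj0, xj1, c0, c1):
    m0 = 0.5 * (xi0 + xj0)
    m1 = 0.5 * (xi1 + xj1)
    t0 = c0 - m0
    t1 = c1 - m1
    a0 = xi0 - xj0
    a1 = xi1 - xj1
    if (t0 == 0.0 and t1 == 0.0) or (a0 == 0.0 and a1 == 0.0):
        return np.nan
    return math.degrees(math.atan2(a0 * t1 - a1 * t0, a0 * t0 + a1 * t1))


@njit(cache=True)
def run_kernel(
    pos,            # (n, 2, 2) initial positions, modified in place
    a_ji, d_ji, a_ij, d_ij, exists, x_cap, m_i_tab, m_j_tab,  # schedule tables
    schedule_constant,  # bool: tables have length 1
    beta, x0,
    dt, eta, sigma, min_sep, n_steps,
    p_res, eps_res, c0, c1, capture_radius,
    stop_first_episode,  # bool
    chase_stride,        # 0 disables chase accumulation
    seed,
):
    n = pos.shape[0]
    np.random.seed(seed)

    k = np.zeros(n, dtype=np.int64)
    in_contest = np.zeros(n, dtype=np.bool_)
    n_episodes = np.zeros(n, dtype=np.int64)
    onset_t = np.full(n, np.nan)
    first_onset = np.full(n, np.nan)
    first_end = np.full(n, np.nan)
    first_cause = np.zeros(n, dtype=np.int64)
    winner_idx = np.full(n, -1, dtype=np.int64)
    capture_time = np.full(n, np.nan)
    theta_end = np.full(n, np.nan)
    done = np.zeros(n, dtype=np.bool_)

    corr_sum = np.zeros(n)
    corr_cnt = np.zeros(n, dtype=np.int64)
    win_s0 = np.zeros(n)
    win_s1 = np.zeros(n)
    win_a0 = np.zeros(n)
    win_a1 = np.zeros(n)
    win_len = np.zeros(n, dtype=np.int64)

    error_flag = 0
    error_t = 0.0

    for s in range(n_steps + 1):
        t = s * dt
        n_active = 0
        for w in range(n):
            if done[w]:
                continue
            n_active += 1
            idx = 0 if schedule_constant else k[w]
            ex = exists[idx]
            xc = x_cap[idx]
            mi = m_i_tab[idx]
            mj = m_j_tab[idx]

            dx0 = pos[w, 0, 0] - pos[w, 1, 0]
            dx1 = pos[w, 0, 1] - pos[w, 1, 1]
            dist = math.sqrt(dx0 * dx0 + dx1 * dx1)
            if dist > 0.0:
                xh0 = dx0 / dist
                xh1 = dx1 / dist
            else:
                xh0 = 1.0
                xh1 = 0.0
            x = dist / x0
            if x < min_sep:
                x = min_sep

            now_in = ex and (x < xc)

            onset = now_in and not in_contest[w]
            if onset:
                onset_t[w] = t
            if in_contest[w] and not now_in:
                # episode ends at t
                cause = CAUSE_NOISE if ex else CAUSE_COST
                theta_end[w] = _theta_deg(
                    pos[w, 0, 0], pos[w, 0, 1], pos[w, 1, 0], pos[w, 1, 1], c0, c1
                )
                if n_episodes[w] == 0:
                    first_onset[w] = onset_t[w]
                    first_end[w] = t
                    first_cause[w] = cause
                n_episodes[w] += 1
                if stop_first_episode:
                    done[w] = True
                    continue

            if chase_stride > 0:
                mid0 = 0.5 * (pos[w, 0, 0] + pos[w, 1, 0])
                mid1 = 0.5 * (pos[w, 0, 1] + pos[w, 1, 1])
                if onset:
                    win_s0[w] = mid0
                    win_s1[w] = mid1
                    win_len[w] = 0
                    if mi >= mj:
                        win_a0[w] = -xh0
                        win_a1[w] = -xh1
                    else:
                        win_a0[w] = xh0
                        win_a1[w] = xh1
                elif now_in:
                    win_len[w] += 1
                    if win_len[w] >= chase_stride:
                        dm0 = mid0 - win_s0[w]
                        dm1 = mid1 - win_s1[w]
                        nrm = math.sqrt(dm0 * dm0 + dm1 * dm1)
                        if nrm > 0.0:
                            corr_sum[w] += (dm0 * win_a0[w] + dm1 * win_a1[w]) / nrm
                            corr_cnt[w] += 1
                        win_s0[w] = mid0
                        win_s1[w] = mid1
                        win_len[w] = 0
                        if mi >= mj:
                            win_a0[w] = -xh0
                            win_a1[w] = -xh1
                        else:
                            win_a0[w] = xh0
                            win_a1[w] = xh1

            in_contest[w] = now_in

            if (not stop_first_episode) and (not now_in) and n_episodes[w] >= 1:
                vi0 = pos[w, 0, 0] - c0
                vi1 = pos[w, 0, 1] - c1
                vj0 = pos[w, 1, 0] - c0
                vj1 = pos[w, 1, 1] - c1
                di = math.sqrt(vi0 * vi0 + vi1 * vi1)
                dj = math.sqrt(vj0 * vj0 + vj1 * vj1)
                if di < capture_radius or dj < capture_radius:
                    winner_idx[w] = 0 if di < dj else 1
                    capture_time[w] = t
                    done[w] = True
                    continue

            if s == n_steps:
                continue

            if now_in:
                k[w] += 1

            g = math.exp(-beta * x * x)
            pair_i = d_ji[idx] / x - 2.0 * a_ji[idx] * beta * x * g
            pair_j = d_ij[idx] / x - 2.0 * a_ij[idx] * beta * x * g
            fi0 = pair_i / x0 * xh0
            fi1 = pair_i / x0 * xh1
            fj0 = -pair_j / x0 * xh0
            fj1 = -pair_j / x0 * xh1
            if (not ex) or (x >= xc):
                vi0 = c0 - pos[w, 0, 0]
                vi1 = c1 - pos[w, 0, 1]
                r = math.sqrt(vi0 * vi0 + vi1 * vi1)
                if r > 0.0:
                    mag = p_res / (r + eps_res) / r
                    fi0 += mag * vi0
                    fi1 += mag * vi1
                vj0 = c0 - pos[w, 1, 0]
                vj1 = c1 - pos[w, 1, 1]
                r = math.sqrt(vj0 * vj0 + vj1 * vj1)
                if r > 0.0:
                    mag = p_res / (r + eps_res) / r
                    fj0 += mag * vj0
                    fj1 += mag * vj1

            e = eta * dt
            d0 = e * fi0
            d1 = e * fi1
            d2 = e * fj0
            d3 = e * fj1
            m = max(abs(d0), abs(d1), abs(d2), abs(d3))
            if m > 1.0:
                error_flag = 1
                error_t = t
                done[w] = True
                continue

            pos[w, 0, 0] += d0 + sigma * np.random.standard_normal()
            pos[w, 0, 1] += d1 + sigma * np.random.standard_normal()
            pos[w, 1, 0] += d2 + sigma * np.random.standard_normal()
            pos[w, 1, 1] += d3 + sigma * np.random.standard_normal()

        if n_active == 0 or error_flag != 0:
            break

    # close episodes still open at the horizon
    t_end = n_steps * dt
    for w in range(n):
        if in_contest[w] and not done[w]:
            theta_end[w] = _theta_deg(
                pos[w, 0, 0], pos[w, 0, 1], pos[w, 1, 0], pos[w, 1, 1], c0, c1
            )
            if n_episodes[w] == 0:
                first_onset[w] = onset_t[w]
                first_end[w] = t_end
                first_cause[w] = CAUSE_HORIZON
            n_episodes[w] += 1

    return (
        first_onset, first_end, first_cause, n_episodes, winner_idx,
        capture_time, theta_end, k, corr_sum, corr_cnt, error_flag, error_t,
    )
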