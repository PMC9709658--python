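"""Compiled inner loop of the contest phase.

The per-round logic lives here as a single numba kernel so that a full
generation (hundreds of rounds over hundreds of groups) runs in compiled
code.  The kernel mutates the learning-state and bookkeeping arrays in
place; all randomness comes from the numba RNG seeded once per call with a
seed derived from the replicate's stream, so the whole contest phase is
deterministic given that seed.

The semantics mirror the elementary operations of :mod:`domhier.hierarchy`:
observation -> action probability -> choice -> resolution -> rewards ->
actor-critic updates for the participants -> vicarious bystander updates on
fighting rounds -> damage bookkeeping.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _logistic(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return z / (1.0 + z)


@njit(cache=True)
def contest_kernel(q, f, a_th, a_w, beta, gamma0, g0, v,
                   theta_spec, w_spec, theta_gen, w_gen,
                   encounters, aa, wins, aa_rounds, damage,
                   rounds, a0, sigma_obs, sigma_p, c0, wscale, seed):
    np.random.seed(seed)
    G, S = q.shape
    for _t in range(rounds):
        for g in range(G):
            # one unordered pair uniformly at random
            i = np.random.randint(0, S)
            j = np.random.randint(0, S - 1)
            if j >= i:
                j += 1
            qe_i = q[g, i] - c0 * damage[g, i]
            qe_j = q[g, j] - c0 * damage[g, j]

            xi_i = a0 * (qe_i - qe_j)
            xi_j = a0 * (qe_j - qe_i)
            if sigma_obs > 0.0:
                xi_i += np.random.normal(0.0, sigma_obs)
                xi_j += np.random.normal(0.0, sigma_obs)

            f_i, f_j = f[g, i], f[g, j]
            th_i = (1.0 - f_i) * theta_spec[g, i, j] + f_i * theta_gen[g, i]
            th_j = (1.0 - f_j) * theta_spec[g, j, i] + f_j * theta_gen[g, j]
            pA_i = _logistic(th_i + gamma0[g, i] * xi_i)
            pA_j = _logistic(th_j + gamma0[g, j] * xi_j)
            a_i = np.random.random() < pA_i
            a_j = np.random.random() < pA_j

            wh_i = (1.0 - f_i) * w_spec[g, i, j] + f_i * w_gen[g, i] + g0[g, i] * xi_i
            wh_j = (1.0 - f_j) * w_spec[g, j, i] + f_j * w_gen[g, j] + g0[g, j] * xi_j

            fight = a_i and a_j
            r_i = 0.0
            r_j = 0.0
            win_idx = -1
            lose_idx = -1
            if fight:
                i_wins = np.random.random() < _logistic(wscale * (qe_i - qe_j))
                pen = -1.0
                if sigma_p > 0.0:
                    pen = -(1.0 + np.random.normal(0.0, sigma_p))
                if i_wins:
                    win_idx, lose_idx = i, j
                    r_i = v[g, i]
                    r_j = pen
                else:
                    win_idx, lose_idx = j, i
                    r_j = v[g, j]
                    r_i = pen
                aa[g, i, j] += 1
                aa[g, j, i] += 1
                aa_rounds[g, i] += 1
                aa_rounds[g, j] += 1
                wins[g, win_idx, lose_idx] += 1
            elif a_i and not a_j:
                r_i = v[g, i]
                wins[g, i, j] += 1
            elif a_j and not a_i:
                r_j = v[g, j]
                wins[g, j, i] += 1
            encounters[g, i, j] += 1
            encounters[g, j, i] += 1

            # participant actor-critic updates
            d_i = r_i - wh_i
            dth = a_th[g, i] * d_i * ((1.0 if a_i else 0.0) - pA_i)
            dw = a_w[g, i] * d_i
            theta_spec[g, i, j] += (1.0 - f_i) * dth
            theta_gen[g, i] += f_i * dth
            w_spec[g, i, j] += (1.0 - f_i) * dw
            w_gen[g, i] += f_i * dw

            d_j = r_j - wh_j
            dth = a_th[g, j] * d_j * ((1.0 if a_j else 0.0) - pA_j)
            dw = a_w[g, j] * d_j
            theta_spec[g, j, i] += (1.0 - f_j) * dth
            theta_gen[g, j] += f_j * dth
            w_spec[g, j, i] += (1.0 - f_j) * dw
            w_gen[g, j] += f_j * dw

            if fight:
                # bystanders: loser-role update toward the winner (reward -1),
                # winner-role update toward the loser (reward +v_k), rates x beta_k
                qe_w = q[g, win_idx] - c0 * damage[g, win_idx]
                qe_l = q[g, lose_idx] - c0 * damage[g, lose_idx]
                for k in range(S):
                    if k == win_idx or k == lose_idx:
                        continue
                    b_k = beta[g, k]
                    if b_k == 0.0:
                        continue
                    f_k = f[g, k]
                    qe_k = q[g, k] - c0 * damage[g, k]
                    for role in range(2):
                        if role == 0:
                            tgt = win_idx
                            reward = -1.0
                            qe_t = qe_w
                        else:
                            tgt = lose_idx
                            reward = v[g, k]
                            qe_t = qe_l
                        xi_k = a0 * (qe_k - qe_t)
                        if sigma_obs > 0.0:
                            xi_k += np.random.normal(0.0, sigma_obs)
                        th_k = (1.0 - f_k) * theta_spec[g, k, tgt] + f_k * theta_gen[g, k]
                        pA_k = _logistic(th_k + gamma0[g, k] * xi_k)
                        wh_k = (1.0 - f_k) * w_spec[g, k, tgt] + f_k * w_gen[g, k] + g0[g, k] * xi_k
                        d_k = reward - wh_k
                        dth = b_k * a_th[g, k] * d_k * (1.0 - pA_k)
                        dw = b_k * a_w[g, k] * d_k
                        theta_spec[g, k, tgt] += (1.0 - f_k) * dth
                        theta_gen[g, k] += f_k * dth
                        w_spec[g, k, tgt] += (1.0 - f_k) * dw
                        w_gen[g, k] += f_k * dw

                # physical damage to the loser, applied after all learning
                # (observations within the round precede the new damage)
                damage[g, lose_idx] += 1.0
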