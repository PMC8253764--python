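"""Numba kernels for categorical-emission HMM numerics.

All kernels work on integer-encoded observation arrays.  Scaling (Rabiner
per-step normalization) keeps forward/backward stable for sequences far
longer than log-space would require, while the log-likelihood is
accumulated as the sum of log scaling factors.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def forward_loglik(obs, pi, A, B):
    """Scaled forward pass; returns (loglik, fail_pos).

    fail_pos is -1 on success, else the first position where the sequence
    has zero probability under the model.
    """
    T = obs.shape[0]
    S = A.shape[0]
    alpha = np.empty(S)
    ll = 0.0
    for i in range(S):
        alpha[i] = pi[i] * B[i, obs[0]]
    c = alpha.sum()
    if c <= 0.0:
        return NEG_INF, 0
    alpha /= c
    ll += np.log(c)
    nxt = np.empty(S)
    for t in range(1, T):
        o = obs[t]
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[i] * A[i, j]
            nxt[j] = acc * B[j, o]
        c = nxt.sum()
        if c <= 0.0:
            return NEG_INF, t
        for j in range(S):
            alpha[j] = nxt[j] / c
        ll += np.log(c)
    return ll, -1


@njit(cache=True)
def em_step(obs, starts, ends, pi, A, B):
    """One Baum-Welch E+M step over a multi-sequence corpus.

    Returns (loglik_of_current_params, pi_new, A_new, B_new).  Sufficient
    statistics are summed across sequences; rows that receive no expected
    occupancy keep their previous values.
    """
    S = A.shape[0]
    M = B.shape[1]
    n_seq = starts.shape[0]

    pi_acc = np.zeros(S)
    A_num = np.zeros((S, S))
    A_den = np.zeros(S)
    B_num = np.zeros((S, M))
    B_den = np.zeros(S)
    total_ll = 0.0

    for q in range(n_seq):
        o = obs[starts[q]:ends[q]]
        T = o.shape[0]
        alpha = np.empty((T, S))
        beta = np.empty((T, S))
        c = np.empty(T)

        for i in range(S):
            alpha[0, i] = pi[i] * B[i, o[0]]
        c[0] = alpha[0].sum()
        if c[0] <= 0.0:
            return NEG_INF, pi, A, B
        for i in range(S):
            alpha[0, i] /= c[0]
        for t in range(1, T):
            for j in range(S):
                acc = 0.0
                for i in range(S):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * B[j, o[t]]
            c[t] = alpha[t].sum()
            if c[t] <= 0.0:
                return NEG_INF, pi, A, B
            for j in range(S):
                alpha[t, j] /= c[t]
        for t in range(T):
            total_ll += np.log(c[t])

        for i in range(S):
            beta[T - 1, i] = 1.0
        # scaled with the forward constants so alpha*beta is a posterior
        for t in range(T - 2, -1, -1):
            on = o[t + 1]
            for i in range(S):
                acc = 0.0
                for j in range(S):
                    acc += A[i, j] * B[j, on] * beta[t + 1, j]
                beta[t, i] = acc / c[t + 1]

        # accumulate gamma / xi
        for t in range(T):
            ot = o[t]
            for i in range(S):
                g = alpha[t, i] * beta[t, i]
                B_num[i, ot] += g
                B_den[i] += g
                if t == 0:
                    pi_acc[i] += g
                if t < T - 1:
                    A_den[i] += g
        for t in range(T - 1):
            on = o[t + 1]
            for i in range(S):
                for j in range(S):
                    A_num[i, j] += (
                        alpha[t, i] * A[i, j] * B[j, on] * beta[t + 1, j] / c[t + 1]
                    )

    pi_new = np.empty(S)
    tot = pi_acc.sum()
    if tot > 0.0:
        for i in range(S):
            pi_new[i] = pi_acc[i] / tot
    else:
        for i in range(S):
            pi_new[i] = pi[i]

    A_new = np.empty((S, S))
    B_new = np.empty((S, M))
    for i in range(S):
        if A_den[i] > 0.0:
            row = 0.0
            for j in range(S):
                row += A_num[i, j]
            if row > 0.0:
                for j in range(S):
                    A_new[i, j] = A_num[i, j] / row
            else:
                for j in range(S):
                    A_new[i, j] = A[i, j]
        else:
            for j in range(S):
                A_new[i, j] = A[i, j]
        if B_den[i] > 0.0:
            for m in range(M):
                B_new[i, m] = B_num[i, m] / B_den[i]
        else:
            for m in range(M):
                B_new[i, m] = B[i, m]

    return total_ll, pi_new, A_new, B_new


@njit(cache=True)
def viterbi_path(obs, log_pi, log_A, log_B):
    """Max-probability state path; ties broken toward the lower state index.

    Returns (path, log_prob, fail_pos); fail_pos is -1 on success, else the
    first position at which every state has log-probability -inf.
    """
    T = obs.shape[0]
    S = log_A.shape[0]
    delta = np.empty((T, S))
    psi = np.zeros((T, S), dtype=np.int64)
    path = np.empty(T, dtype=np.int64)

    ok = False
    for i in range(S):
        delta[0, i] = log_pi[i] + log_B[i, obs[0]]
        if delta[0, i] > NEG_INF:
            ok = True
    if not ok:
        return path, NEG_INF, 0

    for t in range(1, T):
        o = obs[t]
        ok = False
        for j in range(S):
            best = NEG_INF
            arg = 0
            for i in range(S):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            delta[t, j] = best + log_B[j, o]
            psi[t, j] = arg
            if delta[t, j] > NEG_INF:
                ok = True
        if not ok:
            return path, NEG_INF, t

    best = NEG_INF
    arg = 0
    for i in range(S):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            arg = i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best, -1
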