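"""Numba-compiled inner loops shared by the likelihood, fitting and simulation code.

All kernels operate on flat numpy arrays: choices coded 0 (option A) / 1
(option B), outcomes coded +1 (reward) / -1 (omission).  Values are carried
across trials inside the kernel; callers decide whether session boundaries
reset them by passing per-trial ``session_start`` flags and a ``reset`` flag.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def log_expit(x: float) -> float:
    # log(1/(1+exp(-x))) without overflow on either tail
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True)
def trajectory_loglik_kernel(
    choices,
    rewards,
    session_start,
    eta_pos,
    eta_neg,
    beta,
    fictitious,
    reset,
    v0a,
    v0b,
    out,
):
    """Per-trial log-likelihood of observed choices under an asymmetric
    Rescorla-Wagner model with softmax choice; returns final (v_a, v_b)."""
    va = v0a
    vb = v0b
    n = choices.shape[0]
    for t in range(n):
        if reset and session_start[t]:
            va = v0a
            vb = v0b
        dv = va - vb
        r = rewards[t]
        if choices[t] == 0:
            out[t] = log_expit(beta * dv)
            pe = r - va
            lr = eta_pos if pe >= 0.0 else eta_neg
            va += lr * pe
            if fictitious:
                vb += lr * (-r - vb)
        else:
            out[t] = log_expit(-beta * dv)
            pe = r - vb
            lr = eta_pos if pe >= 0.0 else eta_neg
            vb += lr * pe
            if fictitious:
                va += lr * (-r - va)
    return va, vb


@njit(cache=True)
def cohort_loglik_batch(theta, choices, rewards, offsets, fictitious):
    """Summed log-likelihood for a batch of parameter vectors.

    theta:   (B, S, 3) constrained [eta_pos, eta_neg, beta] per subject
    offsets: (S+1,) slice boundaries of each subject in the flat arrays
    returns: (B,) total log-likelihood over all subjects
    """
    B = theta.shape[0]
    S = theta.shape[1]
    out = np.empty(B)
    for b in range(B):
        tot = 0.0
        for s in range(S):
            ep = theta[b, s, 0]
            en = theta[b, s, 1]
            be = theta[b, s, 2]
            va = 0.0
            vb = 0.0
            for t in range(offsets[s], offsets[s + 1]):
                dv = va - vb
                r = rewards[t]
                if choices[t] == 0:
                    tot += log_expit(be * dv)
                    pe = r - va
                    lr = ep if pe >= 0.0 else en
                    va += lr * pe
                    if fictitious:
                        vb += lr * (-r - vb)
                else:
                    tot += log_expit(-be * dv)
                    pe = r - vb
                    lr = ep if pe >= 0.0 else en
                    vb += lr * pe
                    if fictitious:
                        va += lr * (-r - va)
        out[b] = tot
    return out


@njit(cache=True)
def pointwise_loglik_draws(theta_draws, choices, rewards, offsets, fictitious):
    """Per-draw, per-trial log-likelihood matrix (draws x trials)."""
    D = theta_draws.shape[0]
    S = theta_draws.shape[1]
    n = choices.shape[0]
    out = np.empty((D, n))
    for d in range(D):
        for s in range(S):
            ep = theta_draws[d, s, 0]
            en = theta_draws[d, s, 1]
            be = theta_draws[d, s, 2]
            va = 0.0
            vb = 0.0
            for t in range(offsets[s], offsets[s + 1]):
                dv = va - vb
                r = rewards[t]
                if choices[t] == 0:
                    out[d, t] = log_expit(be * dv)
                    pe = r - va
                    lr = ep if pe >= 0.0 else en
                    va += lr * pe
                    if fictitious:
                        vb += lr * (-r - vb)
                else:
                    out[d, t] = log_expit(-be * dv)
                    pe = r - vb
                    lr = ep if pe >= 0.0 else en
                    vb += lr * pe
                    if fictitious:
                        va += lr * (-r - va)
    return out


@njit(cache=True)
def simulate_subject_kernel(
    eta_pos,
    eta_neg,
    beta,
    fictitious,
    reset,
    high0,
    trials_per_session,
    reversal_trial,
    p_high,
    p_low,
    u_choice,
    u_reward,
    v0a,
    v0b,
    choices_out,
    rewarded_out,
    high_out,
):
    """Simulate one agent over ``len(high0)`` sessions of the reversal task.

    high0:   per-session initial high-probability side (0/1)
    u_*:     pre-drawn uniforms, one per trial, consumed in order
    Outputs are written in place; returns final (v_a, v_b).
    """
    va = v0a
    vb = v0b
    n_sessions = high0.shape[0]
    t = 0
    for sess in range(n_sessions):
        if reset:
            va = v0a
            vb = v0b
        high = high0[sess]
        for k in range(trials_per_session):
            if k == reversal_trial:
                high = 1 - high
            p_a = 1.0 / (1.0 + np.exp(-beta * (va - vb)))
            c = 0 if u_choice[t] < p_a else 1
            p_r = p_high if c == high else p_low
            rew = u_reward[t] < p_r
            r = 1.0 if rew else -1.0
            choices_out[t] = c
            rewarded_out[t] = rew
            high_out[t] = high
            if c == 0:
                pe = r - va
                lr = eta_pos if pe >= 0.0 else eta_neg
                va += lr * pe
                if fictitious:
                    vb += lr * (-r - vb)
            else:
                pe = r - vb
                lr = eta_pos if pe >= 0.0 else eta_neg
                vb += lr * pe
                if fictitious:
                    va += lr * (-r - va)
            t += 1
    return va, vb
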