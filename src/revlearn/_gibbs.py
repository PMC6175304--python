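"""Metropolis-within-Gibbs sampler for the hierarchical model, in numba.

Centered parameterization: subject parameters theta[s, k] (unconstrained
scale) are updated one component at a time by adaptive random-walk
Metropolis using only that subject's trial likelihood; the hypermeans are
then drawn exactly from their conditional normal (Normal(0,1) prior), and
the hyper-SDs by a short log-scale Metropolis step against their
HalfNormal(1) prior.  With trial counts in the hundreds-to-thousands the
subject parameters are strongly identified, which is exactly the regime in
which the centered parameterization mixes well.

To break the slow centered-parameterization random walk that appears when a
parameter is weakly identified at the subject level, each sweep ends with an
interweaved non-centered update (ancillarity-sufficiency interweaving): for
each parameter the pair (hypermean, hyper-SD) is proposed jointly while the
standardized subject effects z = (theta - mu) / sigma are held fixed, which
rigidly translates/rescales all subject values and is accepted against the
full group likelihood.

Proposal scales adapt toward their target acceptance during warmup only, so
the kept draws come from a fixed transition kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._kernels import log_expit


@njit(cache=True)
def _subject_loglik(choices, rewards, start, end, ep, en, be, fictitious, skip=-1):
    # ``skip``: flat trial index whose log-likelihood term is omitted from the
    # sum (the value recursion still consumes that trial's choice/outcome);
    # used for exact leave-one-trial-out refits.
    va = 0.0
    vb = 0.0
    tot = 0.0
    for t in range(start, end):
        dv = va - vb
        r = rewards[t]
        if choices[t] == 0:
            if t != skip:
                tot += log_expit(be * dv)
            pe = r - va
            lr = ep if pe >= 0.0 else en
            va += lr * pe
            if fictitious:
                vb += lr * (-r - vb)
        else:
            if t != skip:
                tot += log_expit(-be * dv)
            pe = r - vb
            lr = ep if pe >= 0.0 else en
            vb += lr * pe
            if fictitious:
                va += lr * (-r - va)
    return tot


@njit(cache=True)
def _constrain(theta_row, single_rate, beta_max):
    """Unconstrained K-vector -> (eta_pos, eta_neg, beta)."""
    if single_rate:
        eta = 1.0 / (1.0 + np.exp(-theta_row[0]))
        be = beta_max / (1.0 + np.exp(-theta_row[1]))
        return eta, eta, be
    ep = 1.0 / (1.0 + np.exp(-theta_row[0]))
    en = 1.0 / (1.0 + np.exp(-theta_row[1]))
    be = beta_max / (1.0 + np.exp(-theta_row[2]))
    return ep, en, be


@njit(cache=True)
def run_gibbs_chain(
    choices,
    rewards,
    offsets,
    fictitious,
    single_rate,
    beta_max,
    theta0,
    n_warmup,
    n_keep,
    seed,
    skip=-1,
):
    """One chain; returns (theta draws (n_keep,S,K), mu (n_keep,K),
    sigma (n_keep,K)).  ``skip`` omits one trial's likelihood term (exact
    leave-one-trial-out refitting)."""
    np.random.seed(seed)
    S, K = theta0.shape
    theta = theta0.copy()
    mu = np.zeros(K)
    sigma = np.ones(K)
    for k in range(K):
        mu[k] = theta[:, k].mean()
        sd = theta[:, k].std()
        sigma[k] = sd if sd > 0.2 else 0.2

    ll_cur = np.empty(S)
    for s in range(S):
        ep, en, be = _constrain(theta[s], single_rate, beta_max)
        ll_cur[s] = _subject_loglik(
            choices, rewards, offsets[s], offsets[s + 1], ep, en, be, fictitious, skip
        )

    log_scale = np.full((S, K), np.log(0.15))
    sigma_step = 0.4
    asis_step = np.full(K, np.log(0.2))

    out_theta = np.empty((n_keep, S, K))
    out_mu = np.empty((n_keep, K))
    out_sigma = np.empty((n_keep, K))

    total = n_warmup + n_keep
    prop = np.empty(K)
    for it in range(total):
        adapt = it < n_warmup
        gain = min(0.25, 5.0 / np.sqrt(it + 10.0)) if adapt else 0.0
        # --- subject-level componentwise random-walk Metropolis
        for s in range(S):
            for k in range(K):
                for j in range(K):
                    prop[j] = theta[s, j]
                prop[k] = theta[s, k] + np.exp(log_scale[s, k]) * np.random.normal()
                ep, en, be = _constrain(prop, single_rate, beta_max)
                ll_prop = _subject_loglik(
                    choices, rewards, offsets[s], offsets[s + 1], ep, en, be, fictitious, skip
                )
                dprior = -0.5 * (
                    (prop[k] - mu[k]) ** 2 - (theta[s, k] - mu[k]) ** 2
                ) / (sigma[k] * sigma[k])
                logr = ll_prop - ll_cur[s] + dprior
                accepted = np.log(np.random.random()) < logr
                if accepted:
                    theta[s, k] = prop[k]
                    ll_cur[s] = ll_prop
                if adapt:
                    log_scale[s, k] += gain * ((1.0 if accepted else 0.0) - 0.44)
        # --- hypermeans: exact conditional draw (Normal(0,1) prior)
        for k in range(K):
            s2 = sigma[k] * sigma[k]
            prec = S / s2 + 1.0
            mean = (theta[:, k].sum() / s2) / prec
            mu[k] = mean + np.random.normal() / np.sqrt(prec)
        # --- hyper-SDs: log-scale Metropolis vs HalfNormal(1) prior
        for k in range(K):
            ssq = 0.0
            for s in range(S):
                d = theta[s, k] - mu[k]
                ssq += d * d
            for _ in range(2):
                ls = np.log(sigma[k])
                lsp = ls + sigma_step * np.random.normal()
                sp = np.exp(lsp)
                # prior (halfnormal) + Jacobian + likelihood of theta | mu, sigma
                logr = (-0.5 * sp * sp + lsp) - (-0.5 * sigma[k] * sigma[k] + ls)
                logr += -S * (lsp - ls) - 0.5 * ssq * (1.0 / (sp * sp) - 1.0 / (sigma[k] * sigma[k]))
                if np.log(np.random.random()) < logr:
                    sigma[k] = sp
        # --- interweaved non-centered (mu, sigma) update with z held fixed
        for k in range(K):
            step = np.exp(asis_step[k])
            mu_p = mu[k] + step * np.random.normal()
            lsig_p = np.log(sigma[k]) + step * np.random.normal()
            sig_p = np.exp(lsig_p)
            logr = -0.5 * (mu_p * mu_p - mu[k] * mu[k])
            logr += (-0.5 * sig_p * sig_p + lsig_p) - (
                -0.5 * sigma[k] * sigma[k] + np.log(sigma[k])
            )
            ll_new = np.empty(S)
            theta_new = np.empty(S)
            for s in range(S):
                z = (theta[s, k] - mu[k]) / sigma[k]
                for j in range(K):
                    prop[j] = theta[s, j]
                prop[k] = mu_p + sig_p * z
                theta_new[s] = prop[k]
                ep, en, be = _constrain(prop, single_rate, beta_max)
                ll_new[s] = _subject_loglik(
                    choices, rewards, offsets[s], offsets[s + 1], ep, en, be, fictitious, skip
                )
                logr += ll_new[s] - ll_cur[s]
            accepted = np.log(np.random.random()) < logr
            if accepted:
                mu[k] = mu_p
                sigma[k] = sig_p
                for s in range(S):
                    theta[s, k] = theta_new[s]
                    ll_cur[s] = ll_new[s]
            if adapt:
                asis_step[k] += gain * ((1.0 if accepted else 0.0) - 0.3)
        if it >= n_warmup:
            j = it - n_warmup
            out_theta[j] = theta
            out_mu[j] = mu
            out_sigma[j] = sigma
    return out_theta, out_mu, out_sigma
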