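"""Hierarchical Bayesian estimation of reinforcement-learning parameters.

One hierarchy is fit per group (genotype): on the unconstrained scale each
parameter k has a group hypermean mu_k ~ Normal(0, 1) and hyper-SD
sigma_k ~ HalfNormal(1); subject effects are non-centered,
theta_unc[s, k] = mu_k + sigma_k * z[s, k] with z ~ Normal(0, 1), and are
mapped through monotone logistic transforms onto (0, 1) for learning rates
and (0, beta_max) for the inverse temperature.  The likelihood replays the
softmax/Rescorla-Wagner trajectory over each subject's full trial sequence
(values carried across sessions).

Sampling uses a Metropolis-within-Gibbs scheme (see :mod:`revlearn._gibbs`)
in the centered parameterization: adaptive componentwise random-walk
updates of each subject's parameters against that subject's trial
likelihood, exact conjugate draws of the hypermeans, and short
Metropolis updates of the hyper-SDs.  Several independent chains are run
from overdispersed starts (per-subject penalized maximum-likelihood
estimates plus noise); convergence is summarized by split-R-hat and
effective sample size (arviz).

Group effects are judged by the difference of hypermean draws between two
independently fitted groups, summarized as a highest-density interval
(HDI) and whether it excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from . import transforms as _tr
from ._gibbs import run_gibbs_chain
from ._kernels import cohort_loglik_batch, pointwise_loglik_draws
from .models import Model
from .task import CohortData

__all__ = [
    "McmcSettings",
    "HdiInterval",
    "PosteriorFit",
    "GroupDifference",
    "hdi",
    "fit_group",
    "fit_hierarchical",
    "group_difference",
]


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings.

    ``chains`` independent chains each run ``warmup`` adaptation sweeps
    (discarded) followed by ``steps`` kept sweeps; draws used for summaries
    and pointwise log-likelihoods are thinned evenly to at most
    ``draws_target`` total across chains.
    """

    chains: int = 4
    warmup: int = 1000
    steps: int = 1000
    draws_target: int = 2000
    rhat_threshold: float = 1.05
    beta_max: float = _tr.BETA_MAX


@dataclass(frozen=True)
class HdiInterval:
    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def hdi(draws, mass: float = 0.95) -> HdiInterval:
    """Shortest interval containing ``ceil(mass * n)`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k >= n:
        return HdiInterval(float(x[0]), float(x[-1]), mass)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HdiInterval(float(x[i]), float(x[i + k - 1]), mass)


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics of one group's hierarchical fit."""

    model: Model
    group: str
    subject_ids: list[str]
    param_names: tuple[str, ...]
    hyper_mean: dict[str, np.ndarray]  # unconstrained-scale draws, (D,)
    hyper_sd: dict[str, np.ndarray]  # (D,)
    subject_draws: np.ndarray  # (D, S, K) constrained
    pointwise_loglik: np.ndarray  # (D, total trials)
    trial_index: pd.DataFrame  # subject_id/session/trial per column
    diagnostics: pd.DataFrame  # quantity, rhat, ess
    converged: bool
    seed: int
    settings: McmcSettings = field(default_factory=McmcSettings)

    @property
    def n_draws(self) -> int:
        return self.subject_draws.shape[0]

    def hypermean_constrained(self, param: str) -> np.ndarray:
        """Hypermean draws mapped to the natural scale of ``param``."""
        tf = _tr.default_transforms(self.settings.beta_max)[param]
        return np.asarray(tf.forward(self.hyper_mean[param]))

    def subject_posterior_means(self) -> pd.DataFrame:
        """Posterior means of constrained individual parameters, one row per
        subject (the point parameters used for posterior simulation)."""
        means = self.subject_draws.mean(axis=0)  # (S, K)
        rows = []
        for s, sid in enumerate(self.subject_ids):
            d = dict(zip(self.param_names, means[s]))
            if self.model.single_rate:
                d = {"eta_pos": d["eta"], "eta_neg": d["eta"], "beta": d["beta"]}
            rows.append({"subject_id": sid, "group": self.group, **d})
        return pd.DataFrame(rows)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name in self.param_names:
            for kind, draws in (
                (f"mu_{name}", self.hyper_mean[name]),
                (f"sigma_{name}", self.hyper_sd[name]),
                (f"{name}_group", self.hypermean_constrained(name)),
            ):
                iv = hdi(draws, mass)
                rows.append(
                    {
                        "quantity": kind,
                        "mean": float(np.mean(draws)),
                        "sd": float(np.std(draws)),
                        "hdi_low": iv.lower,
                        "hdi_high": iv.upper,
                    }
                )
        out = pd.DataFrame(rows)
        return out.merge(self.diagnostics, on="quantity", how="left")


def _model_theta(model: Model, theta_unc: np.ndarray, beta_max: float) -> np.ndarray:
    """Map unconstrained subject parameters (..., K) to the (..., 3)
    constrained [eta_pos, eta_neg, beta] block the kernels consume."""
    c = expit(theta_unc)
    out = np.empty(theta_unc.shape[:-1] + (3,))
    if model.single_rate:
        out[..., 0] = c[..., 0]
        out[..., 1] = c[..., 0]
        out[..., 2] = beta_max * c[..., 1]
    else:
        out[..., 0] = c[..., 0]
        out[..., 1] = c[..., 1]
        out[..., 2] = beta_max * c[..., 2]
    return out


class _GroupData:
    """Flattened per-group trial arrays plus MLE-based chain initialization."""

    def __init__(self, model: Model, cohort: CohortData, group: str, beta_max: float):
        self.model = model
        self.beta_max = beta_max
        self.subject_ids = cohort.subject_ids(group)
        if not self.subject_ids:
            raise ValueError(f"no subjects in group {group!r}")
        arrs = [cohort.subject_arrays(s) for s in self.subject_ids]
        lengths = [len(a[0]) for a in arrs]
        if any(n == 0 for n in lengths):
            raise ValueError("every subject needs at least one trial")
        self.choices = np.concatenate([a[0] for a in arrs])
        self.rewards = np.concatenate([a[1] for a in arrs])
        self.offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        self.S = len(self.subject_ids)
        self.K = len(model.param_names)
        idx_frames = []
        for sid in self.subject_ids:
            df = cohort.subject_trials(sid).sort_values(["session", "trial"])
            idx_frames.append(df[["subject_id", "session", "trial"]])
        self.trial_index = pd.concat(idx_frames, ignore_index=True)

    def subject_mle(self, s: int) -> np.ndarray:
        """Weakly penalized ML estimate of one subject's unconstrained
        parameters; used only to initialize the chains."""
        sl = slice(self.offsets[s], self.offsets[s + 1])
        choices = np.ascontiguousarray(self.choices[sl])
        rewards = np.ascontiguousarray(self.rewards[sl])
        offs = np.array([0, len(choices)], dtype=np.int64)

        def neg(x):
            theta = _model_theta(self.model, x[None, None, :], self.beta_max)
            ll = cohort_loglik_batch(theta, choices, rewards, offs, self.model.fictitious)
            return -ll[0] + 0.125 * np.sum(x**2)

        res = minimize(neg, np.zeros(self.K), method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-3})
        return res.x


def fit_group(
    model: Model,
    cohort: CohortData,
    group: str,
    settings: McmcSettings = McmcSettings(),
    seed: int = 0,
    skip_trial: int | None = None,
) -> PosteriorFit:
    """Fit one group's hierarchy and return posterior draws, pointwise
    log-likelihoods and convergence diagnostics.

    ``skip_trial`` (an index into the group's concatenated trial sequence,
    see ``PosteriorFit.trial_index``) omits that trial's likelihood term
    while keeping the value recursion intact — the exact leave-one-trial-out
    refit used to validate PSIS-LOO.
    """
    data = _GroupData(model, cohort, group, settings.beta_max)
    S, K = data.S, data.K
    names = model.param_names
    mles = np.array([data.subject_mle(s) for s in range(S)])  # (S, K)

    C = settings.chains
    theta_ch = np.empty((C, settings.steps, S, K))
    mu_ch = np.empty((C, settings.steps, K))
    sigma_ch = np.empty((C, settings.steps, K))
    for c in range(C):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(c,))
        rng = np.random.default_rng(ss)
        theta0 = mles + 0.25 * rng.standard_normal((S, K))  # overdispersed starts
        chain_seed = int(ss.generate_state(1)[0] % (2**31 - 1)) + 1
        th, mu, sg = run_gibbs_chain(
            data.choices,
            data.rewards,
            data.offsets,
            model.fictitious,
            model.single_rate,
            settings.beta_max,
            theta0,
            settings.warmup,
            settings.steps,
            chain_seed,
            -1 if skip_trial is None else int(skip_trial),
        )
        theta_ch[c], mu_ch[c], sigma_ch[c] = th, mu, sg

    # convergence diagnostics on the hyperparameters, across chains
    diag_rows = []
    converged = True
    import arviz as az

    posterior = {}
    for k, name in enumerate(names):
        posterior[f"mu_{name}"] = mu_ch[:, :, k]
        posterior[f"sigma_{name}"] = sigma_ch[:, :, k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=posterior)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    for q in posterior:
        diag_rows.append(
            {"quantity": q, "rhat": float(rhat[q].values), "ess": float(ess[q].values)}
        )
    max_rhat = max(r["rhat"] for r in diag_rows)
    if max_rhat > settings.rhat_threshold:
        converged = False
        warnings.warn(
            f"fit of group {group!r} (model {int(model)}): max split-R-hat "
            f"{max_rhat:.3f} exceeds {settings.rhat_threshold}",
            RuntimeWarning,
            stacklevel=2,
        )
    diagnostics = pd.DataFrame(diag_rows, columns=["quantity", "rhat", "ess"])

    # thin each chain evenly to at most draws_target retained draws in total
    per_chain = max(1, settings.draws_target // C)
    idx = np.unique(np.linspace(0, settings.steps - 1, min(settings.steps, per_chain)).astype(int))
    theta_unc = theta_ch[:, idx].reshape(-1, S, K)
    mu_flat = mu_ch[:, idx].reshape(-1, K)
    sigma_flat = sigma_ch[:, idx].reshape(-1, K)

    hyper_mean = {name: np.ascontiguousarray(mu_flat[:, k]) for k, name in enumerate(names)}
    hyper_sd = {name: np.ascontiguousarray(sigma_flat[:, k]) for k, name in enumerate(names)}
    theta = _model_theta(model, theta_unc, settings.beta_max)  # (D, S, 3) constrained
    pointwise = pointwise_loglik_draws(
        theta, data.choices, data.rewards, data.offsets, model.fictitious
    )
    if model.single_rate:
        subject_draws = theta[:, :, [0, 2]]  # (eta, beta)
    else:
        subject_draws = theta

    return PosteriorFit(
        model=model,
        group=group,
        subject_ids=data.subject_ids,
        param_names=names,
        hyper_mean=hyper_mean,
        hyper_sd=hyper_sd,
        subject_draws=subject_draws,
        pointwise_loglik=pointwise,
        trial_index=data.trial_index,
        diagnostics=diagnostics,
        converged=converged,
        seed=seed,
        settings=settings,
    )


def fit_hierarchical(
    model: Model,
    cohort: CohortData,
    settings: McmcSettings = McmcSettings(),
    seed: int = 0,
) -> dict[str, PosteriorFit]:
    """Fit each group in the cohort separately (one hierarchy per group, as
    when comparing mutant and control hyperposteriors)."""
    groups = cohort.groups
    if not groups:
        raise ValueError("cohort has no groups")
    fits = {}
    for i, g in enumerate(sorted(groups)):
        fits[g] = fit_group(model, cohort, g, settings, seed=seed + 1000 * i)
    return fits


@dataclass(frozen=True)
class GroupDifference:
    param: str
    draws: np.ndarray
    interval: HdiInterval
    excludes_zero: bool


def group_difference(
    fit_a: PosteriorFit,
    fit_b: PosteriorFit,
    param: str,
    mass: float = 0.95,
    scale: str = "constrained",
) -> GroupDifference:
    """Difference of hypermean draws (fit_a - fit_b, typically mutant minus
    control), paired by draw index across the two independent fits.

    ``scale='constrained'`` differences the group-level parameter on its
    natural scale (as plotted in hyperposterior density comparisons);
    ``'unconstrained'`` differences the raw hypermeans.
    """
    if fit_a.model is not fit_b.model:
        raise ValueError("fits must be of the same model")
    if scale == "constrained":
        a = fit_a.hypermean_constrained(param)
        b = fit_b.hypermean_constrained(param)
    elif scale == "unconstrained":
        a = fit_a.hyper_mean[param]
        b = fit_b.hyper_mean[param]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    m = min(len(a), len(b))
    d = a[:m] - b[:m]
    iv = hdi(d, mass)
    return GroupDifference(param, d, iv, excludes_zero=not iv.contains(0.0))
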