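"""Probabilistic reversal-learning task simulator and synthetic cohorts.

The task: two nose-poke ports, one rewarded with high probability (default
80%) and one with low (default 20%); the assignment is drawn at random at
the start of each session and reversed after a fixed trial (default 60 of
120).  Subjects run a fixed number of sessions (default 15, i.e. 1800
trials).  Every trial yields a choice; omissions and trial timing are not
modeled.

Synthetic cohorts emulate a genotype comparison: each group has a
hierarchical (normal on the unconstrained scale) distribution of agent
parameters; group effects are expressed as hypermean shifts, by default in
the inverse temperature only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import transforms as _tr
from ._kernels import simulate_subject_kernel
from .models import CODE_OPTION, OPTION_CODE, AgentParams, Model, ValueState

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "GroupSpec",
    "CohortData",
    "default_group_specs",
    "run_session",
    "generate_cohort",
    "write_event_log",
    "read_event_log",
]

EVENT_LOG_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "trial",
    "high_side",
    "choice",
    "rewarded",
]


@dataclass(frozen=True)
class TaskConfig:
    """Schedule of the reversal task."""

    p_high: float = 0.8
    p_low: float = 0.2
    trials_per_session: int = 120
    reversal_trial: int = 60
    n_sessions: int = 15

    def __post_init__(self) -> None:
        # p_low == p_high is tolerated as a degenerate schedule (useful in tests)
        if not (0.0 <= self.p_low <= self.p_high <= 1.0):
            raise ValueError("require 0 <= p_low <= p_high <= 1")
        if not (0 < self.reversal_trial < self.trials_per_session):
            raise ValueError("require 0 < reversal_trial < trials_per_session")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one subject; the atomic unit of real and simulated data."""

    subject_id: str
    session: int  # 1-based
    trial: int  # 1-based within session
    high_side: str  # option currently carrying p_high
    choice: str
    rewarded: bool

    @property
    def reward_code(self) -> int:
        return 1 if self.rewarded else -1


@dataclass(frozen=True)
class GroupSpec:
    """Hyperdistribution of one group's agent parameters.

    ``hyper_mean`` / ``hyper_sd`` are keyed by the model's parameter names
    and live on the *unconstrained* scale; subject parameters are drawn as
    ``mean + sd * z`` and mapped through the default transforms.
    """

    name: str
    n_subjects: int
    hyper_mean: Mapping[str, float]
    hyper_sd: Mapping[str, float]
    model: Model = Model.FICT_RP

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        for k in self.model.param_names:
            if k not in self.hyper_mean or k not in self.hyper_sd:
                raise ValueError(f"missing hyperparameter for {k!r}")
            if not self.hyper_sd[k] >= 0:
                raise ValueError("hyper_sd components must be >= 0")

    @classmethod
    def from_constrained(
        cls,
        name: str,
        n_subjects: int,
        means: Mapping[str, float],
        sds: Mapping[str, float] | float = 0.2,
        model: Model = Model.FICT_RP,
    ) -> "GroupSpec":
        """Build a spec from hypermeans given on the natural (constrained)
        scale, e.g. ``{"eta_pos": 0.4, "eta_neg": 0.1, "beta": 2.0}``;
        ``sds`` are unconstrained-scale spreads."""
        tf = _tr.default_transforms()
        hyper_mean = {k: float(tf[k].inverse(v)) for k, v in means.items()}
        if isinstance(sds, (int, float)):
            sds = {k: float(sds) for k in hyper_mean}
        return cls(name, n_subjects, hyper_mean, dict(sds), model)

    def subject_params(self, rng: np.random.Generator) -> AgentParams:
        tf = _tr.default_transforms()
        constrained = {}
        for k in self.model.param_names:
            z = rng.standard_normal()
            constrained[k] = float(tf[k].forward(self.hyper_mean[k] + self.hyper_sd[k] * z))
        if self.model.single_rate:
            return AgentParams.symmetric(constrained["eta"], constrained["beta"])
        return AgentParams(constrained["eta_pos"], constrained["eta_neg"], constrained["beta"])


@dataclass
class CohortData:
    """Trial-by-trial event log of one or more groups, plus (for synthetic
    cohorts) the generating per-subject parameters."""

    trials: pd.DataFrame
    params: pd.DataFrame | None = None
    specs: Sequence[GroupSpec] = field(default_factory=tuple)
    config: TaskConfig = field(default_factory=TaskConfig)
    master_seed: int | None = None

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.trials["group"]))

    def subject_ids(self, group: str | None = None) -> list[str]:
        df = self.trials if group is None else self.trials[self.trials["group"] == group]
        return list(pd.unique(df["subject_id"]))

    def subject_trials(self, subject_id: str) -> pd.DataFrame:
        return self.trials[self.trials["subject_id"] == subject_id]

    def subject_arrays(self, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(choices 0/1, outcome codes +/-1) in session/trial order."""
        df = self.subject_trials(subject_id).sort_values(["session", "trial"])
        choices = df["choice"].map(OPTION_CODE).to_numpy(dtype=np.int8)
        rewards = np.where(df["rewarded"].to_numpy(dtype=bool), 1.0, -1.0)
        return choices, rewards

    def records(self, subject_id: str) -> list[TrialRecord]:
        df = self.subject_trials(subject_id).sort_values(["session", "trial"])
        return [
            TrialRecord(
                subject_id=r.subject_id,
                session=int(r.session),
                trial=int(r.trial),
                high_side=r.high_side,
                choice=r.choice,
                rewarded=bool(r.rewarded),
            )
            for r in df.itertuples()
        ]


def default_group_specs(
    n_control: int = 8,
    n_mutant: int = 6,
    model: Model = Model.FICT_RP,
    beta_mutant: float = 0.6,
) -> list[GroupSpec]:
    """Default synthetic study conditions: a control/mutant cohort pair whose
    hyperdistributions differ only in the inverse-temperature hypermean.

    The regime (constrained hypermeans eta+ = 0.4, eta- = 0.1; control beta
    0.9 with a deficit to 0.6 in mutants) puts win-stay near 0.65-0.8 and
    lose-shift near 0.5 — the band observed in well-trained mice on this
    schedule — with a beta effect of the size that genotype comparisons
    report as credible.  Hyper-SDs are calibrated so the simulated
    between-animal dispersion of win-stay (~0.04-0.05) and lose-shift
    (~0.07) matches what such cohorts show; eta- is the most variable trait
    because loss-driven learning is the least consistent across animals.
    Pass ``beta_mutant`` to widen or shrink the deficit.
    """
    sds = {"eta_pos": 0.3, "eta_neg": 1.0, "beta": 0.25}
    return [
        GroupSpec.from_constrained(
            "control", n_control, {"eta_pos": 0.4, "eta_neg": 0.1, "beta": 0.9}, sds, model
        ),
        GroupSpec.from_constrained(
            "mutant", n_mutant, {"eta_pos": 0.4, "eta_neg": 0.1, "beta": beta_mutant}, sds, model
        ),
    ]


def _simulate_sessions(
    params: AgentParams,
    model: Model,
    config: TaskConfig,
    values_in: ValueState,
    rng: np.random.Generator,
    n_sessions: int,
    reset_per_session: bool = False,
) -> tuple[pd.DataFrame, ValueState]:
    n = n_sessions * config.trials_per_session
    high0 = rng.integers(0, 2, size=n_sessions).astype(np.int8)
    u_choice = rng.random(n)
    u_reward = rng.random(n)
    choices = np.empty(n, dtype=np.int8)
    rewarded = np.empty(n, dtype=np.bool_)
    high = np.empty(n, dtype=np.int8)
    va, vb = simulate_subject_kernel(
        params.eta_pos,
        params.eta_neg,
        params.beta,
        model.fictitious,
        reset_per_session,
        high0,
        config.trials_per_session,
        config.reversal_trial,
        config.p_high,
        config.p_low,
        u_choice,
        u_reward,
        values_in.v_a,
        values_in.v_b,
        choices,
        rewarded,
        high,
    )
    df = pd.DataFrame(
        {
            "session": np.repeat(np.arange(1, n_sessions + 1), config.trials_per_session),
            "trial": np.tile(np.arange(1, config.trials_per_session + 1), n_sessions),
            "high_side": pd.Series(high).map(CODE_OPTION),
            "choice": pd.Series(choices).map(CODE_OPTION),
            "rewarded": rewarded,
        }
    )
    return df, ValueState(va, vb)


def run_session(
    params: AgentParams,
    model: Model,
    config: TaskConfig,
    values_in: ValueState = ValueState(0.0, 0.0),
    seed: int | np.random.Generator = 0,
    session: int = 1,
    subject_id: str = "s1",
) -> tuple[pd.DataFrame, ValueState]:
    """Simulate a single session; returns the trial table and the final
    values for carry-over into the next session.

    The high-probability side is drawn uniformly at session start and flips
    after ``config.reversal_trial`` trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df, values_out = _simulate_sessions(params, model, config, values_in, rng, 1)
    df["session"] = session
    df.insert(0, "subject_id", subject_id)
    return df, values_out


def generate_cohort(
    specs: Sequence[GroupSpec],
    config: TaskConfig = TaskConfig(),
    master_seed: int = 0,
    reset_per_session: bool = False,
) -> CohortData:
    """Draw subjects from each group's hyperdistribution and simulate full
    multi-session runs (values carried across sessions by default).

    Per-subject random streams are spawned from ``master_seed`` keyed by
    (group index, subject index), so adding a subject or group never
    perturbs the data of existing ones.
    """
    if len(specs) == 0:
        raise ValueError("need at least one group")
    trial_frames = []
    param_rows = []
    for g_idx, spec in enumerate(specs):
        for j in range(spec.n_subjects):
            ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(g_idx, j))
            rng = np.random.default_rng(ss)
            params = spec.subject_params(rng)
            sid = f"{spec.name}_{j + 1:02d}"
            df, _ = _simulate_sessions(
                params,
                spec.model,
                config,
                ValueState(0.0, 0.0),
                rng,
                config.n_sessions,
                reset_per_session,
            )
            df.insert(0, "group", spec.name)
            df.insert(0, "subject_id", sid)
            trial_frames.append(df)
            param_rows.append(
                {
                    "subject_id": sid,
                    "group": spec.name,
                    "eta_pos": params.eta_pos,
                    "eta_neg": params.eta_neg,
                    "beta": params.beta,
                }
            )
    trials = pd.concat(trial_frames, ignore_index=True)
    return CohortData(
        trials=trials,
        params=pd.DataFrame(param_rows),
        specs=tuple(specs),
        config=config,
        master_seed=master_seed,
    )


def write_event_log(cohort: CohortData, path: str | Path) -> None:
    """Write the cohort's trials as a CSV event log (UTF-8, header row,
    1-based session/trial indices, options coded A/B, rewarded coded 0/1)."""
    df = cohort.trials.copy()
    if "group" not in df:
        df["group"] = "all"
    out = df[EVENT_LOG_COLUMNS].copy()
    out["rewarded"] = out["rewarded"].astype(int)
    out.to_csv(path, index=False)


def read_event_log(path: str | Path, config: TaskConfig = TaskConfig()) -> CohortData:
    """Read an event log written by :func:`write_event_log`.

    Malformed rows raise ``ValueError`` naming the offending line number
    (line 1 is the header).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event log missing columns: {missing}")

    def _bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 2  # +1 header, +1 zero-based
            raise ValueError(f"line {line}: {what}")

    _bad(~df["high_side"].isin(["A", "B"]), "high_side must be 'A' or 'B'")
    _bad(~df["choice"].isin(["A", "B"]), "choice must be 'A' or 'B'")
    _bad(~df["rewarded"].isin([0, 1]), "rewarded must be 0 or 1")
    _bad(df["session"] < 1, "session index must be >= 1")
    _bad((df["trial"] < 1) | (df["trial"] > config.trials_per_session),
         f"trial index out of range 1..{config.trials_per_session}")
    df["rewarded"] = df["rewarded"].astype(bool)
    return CohortData(trials=df, params=None, specs=(), config=config)
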