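"""Generative reinforcement-learning models for two-choice reversal learning.

Three nested Rescorla-Wagner variants are implemented, differing in whether
the learning rate is split by the sign of the reward prediction error (PE)
and whether the unchosen option receives a fictitious update toward the
negated outcome:

* ``Model.RP``          - separate rates for positive/negative PE, chosen
                          option only ("model 1").
* ``Model.FICT``        - single learning rate, fictitious update of the
                          unchosen option ("model 2").
* ``Model.FICT_RP``     - separate rates and fictitious updating ("model 3");
                          the most general model, which reduces exactly to the
                          other two.

Outcomes are coded +1 (reward) / -1 (omission).  On each trial the chosen
option's value moves a fraction eta toward the outcome, where eta is
``eta_pos`` if PE >= 0 and ``eta_neg`` otherwise; under fictitious updating
the unchosen option moves toward the negated outcome with the *same* rate
(the sign rule is applied once, to the chosen option's PE).  Choice follows
a softmax (logistic in the value difference) with inverse temperature beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Literal

import numpy as np
from scipy.special import expit

from ._kernels import trajectory_loglik_kernel

__all__ = [
    "Model",
    "AgentParams",
    "ValueState",
    "StepResult",
    "encode_reward",
    "update_values",
    "choice_probability",
    "trajectory_loglik",
]

Option = Literal["A", "B"]


class Model(IntEnum):
    """Identifier of the three nested models."""

    RP = 1        # reward/punishment learning rates, chosen option only
    FICT = 2      # single rate + fictitious update of the unchosen option
    FICT_RP = 3   # separate rates + fictitious update

    @property
    def fictitious(self) -> bool:
        return self in (Model.FICT, Model.FICT_RP)

    @property
    def single_rate(self) -> bool:
        return self is Model.FICT

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.single_rate:
            return ("eta", "beta")
        return ("eta_pos", "eta_neg", "beta")


# options are mapped to array codes 0/1 throughout the package
OPTION_CODE = {"A": 0, "B": 1}
CODE_OPTION = {0: "A", 1: "B"}


@dataclass(frozen=True)
class AgentParams:
    """One agent's parameters: learning rates in [0, 1], beta >= 0."""

    eta_pos: float
    eta_neg: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_pos <= 1.0):
            raise ValueError(f"eta_pos must be in [0, 1], got {self.eta_pos}")
        if not (0.0 <= self.eta_neg <= 1.0):
            raise ValueError(f"eta_neg must be in [0, 1], got {self.eta_neg}")
        if not self.beta >= 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    @classmethod
    def symmetric(cls, eta: float, beta: float) -> "AgentParams":
        """Single-learning-rate parameters (as required by ``Model.FICT``)."""
        return cls(eta_pos=eta, eta_neg=eta, beta=beta)


@dataclass(frozen=True)
class ValueState:
    """Expected values of the two options; stays in [-1, 1] under +/-1 outcomes."""

    v_a: float = 0.0
    v_b: float = 0.0

    def value_of(self, option: Option) -> float:
        return self.v_a if option == "A" else self.v_b


@dataclass(frozen=True)
class StepResult:
    values_after: ValueState
    prediction_error: float
    choice_prob_a: float


def encode_reward(rewarded: bool) -> int:
    """Outcome code: +1 if the trial was rewarded, -1 if reward was omitted."""
    return 1 if rewarded else -1


def _check_params(model: Model, params: AgentParams) -> None:
    if not isinstance(model, Model):
        raise ValueError(f"invalid model id: {model!r}")
    if model.single_rate and params.eta_pos != params.eta_neg:
        raise ValueError(
            "Model.FICT has a single learning rate; eta_pos must equal eta_neg "
            f"(got {params.eta_pos} != {params.eta_neg})"
        )


def choice_probability(state: ValueState, beta: float) -> float:
    """Softmax probability of choosing option A: expit(beta * (V_A - V_B))."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return float(expit(beta * (state.v_a - state.v_b)))


def update_values(
    model: Model,
    state: ValueState,
    chosen: Option,
    reward_code: int,
    params: AgentParams,
) -> StepResult:
    """Apply one trial's value update and report PE and next-choice probability.

    PE is computed against the chosen option's value before the update; its
    sign selects the learning rate (eta_pos for PE >= 0) for *both* the
    chosen-option update and, in the fictitious models, the unchosen-option
    update toward ``-reward_code``.
    """
    _check_params(model, params)
    if chosen not in ("A", "B"):
        raise ValueError(f"chosen must be 'A' or 'B', got {chosen!r}")
    if reward_code not in (-1, 1):
        raise ValueError(f"reward_code must be +/-1, got {reward_code!r}")

    v_c = state.value_of(chosen)
    pe = reward_code - v_c
    lr = params.eta_pos if pe >= 0 else params.eta_neg
    v_c_new = v_c + lr * pe

    other: Option = "B" if chosen == "A" else "A"
    v_uc = state.value_of(other)
    if model.fictitious:
        v_uc_new = v_uc + lr * (-reward_code - v_uc)
    else:
        v_uc_new = v_uc

    if chosen == "A":
        new_state = ValueState(v_a=v_c_new, v_b=v_uc_new)
    else:
        new_state = ValueState(v_a=v_uc_new, v_b=v_c_new)
    return StepResult(
        values_after=new_state,
        prediction_error=pe,
        choice_prob_a=choice_probability(new_state, params.beta),
    )


def _as_arrays(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coerce a trial sequence (TrialRecords or DataFrame) to kernel arrays."""
    import pandas as pd

    if isinstance(trials, pd.DataFrame):
        if "subject_id" in trials and trials["subject_id"].nunique() > 1:
            raise ValueError("trajectory_loglik expects a single subject's trials")
        df = trials
        sess = df["session"].to_numpy()
        tr = df["trial"].to_numpy()
        ordered = np.all(
            (sess[1:] > sess[:-1]) | ((sess[1:] == sess[:-1]) & (tr[1:] > tr[:-1]))
        )
        if not ordered:
            raise ValueError("trials must be ordered by session then trial")
        choices = df["choice"].map(OPTION_CODE).to_numpy(dtype=np.int8)
        rewards = np.where(df["rewarded"].to_numpy(dtype=bool), 1.0, -1.0)
        session = sess
    else:
        recs = list(trials)
        key = [(r.session, r.trial) for r in recs]
        if key != sorted(key):
            raise ValueError("trials must be ordered by session then trial")
        choices = np.array([OPTION_CODE[r.choice] for r in recs], dtype=np.int8)
        rewards = np.array([encode_reward(r.rewarded) for r in recs], dtype=np.float64)
        session = np.array([r.session for r in recs])
    if len(choices) == 0:
        raise ValueError("empty trial sequence")
    session_start = np.empty(len(session), dtype=np.bool_)
    session_start[0] = True
    session_start[1:] = session[1:] != session[:-1]
    return choices, rewards, session_start


def trajectory_loglik(
    model: Model,
    params: AgentParams,
    trials,
    initial_values: ValueState = ValueState(0.0, 0.0),
    reset_per_session: bool = False,
) -> np.ndarray:
    """Per-trial log-likelihood of an observed choice trajectory.

    Element ``t`` is the log softmax probability of the choice actually made
    on trial ``t``, given values accumulated over trials ``0..t-1``.  Values
    carry across session boundaries unless ``reset_per_session`` is set.
    The sum of the returned vector is the trajectory log-likelihood.
    """
    _check_params(model, params)
    choices, rewards, session_start = _as_arrays(trials)
    out = np.empty(len(choices))
    trajectory_loglik_kernel(
        choices,
        rewards,
        session_start,
        params.eta_pos,
        params.eta_neg,
        params.beta,
        model.fictitious,
        reset_per_session,
        initial_values.v_a,
        initial_values.v_b,
        out,
    )
    return out
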