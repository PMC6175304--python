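"""Unit and property tests of the value-update models and trajectory likelihood.

The reference implementation used as an oracle here is a deliberately naive
pure-Python replay of the update and choice rules, kept independent of the
compiled kernels.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import revlearn as rl
from revlearn.models import (
    AgentParams,
    Model,
    ValueState,
    choice_probability,
    encode_reward,
    trajectory_loglik,
    update_values,
)
from conftest import random_trial_frame


def reference_replay(eta_pos, eta_neg, beta, fictitious, choices, rewards):
    """Naive replay of the model: per-trial log-likelihoods and value trace.

    choices: 0/1 codes; rewards: +/-1 codes.
    """
    v = [0.0, 0.0]
    lls, values = [], []
    for c, r in zip(choices, rewards):
        dv = v[0] - v[1] if c == 0 else v[1] - v[0]
        p_chosen = 1.0 / (1.0 + math.exp(-beta * dv))
        lls.append(math.log(p_chosen))
        pe = r - v[c]
        lr = eta_pos if pe >= 0 else eta_neg
        v[c] = v[c] + lr * pe
        if fictitious:
            u = 1 - c
            v[u] = v[u] + lr * (-r - v[u])
        values.append(tuple(v))
    return np.array(lls), values


params_st = st.tuples(
    st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 8.0)
)
seq_st = st.lists(
    st.tuples(st.integers(0, 1), st.sampled_from([-1, 1])), min_size=1, max_size=60
)


def test_encode_reward_codomain():
    assert encode_reward(True) == 1
    assert encode_reward(False) == -1


@pytest.mark.parametrize(
    "model, state, chosen, r, params, expected_v, expected_pe",
    [
        # rewarded choice of A under the full model: fictitious push of B to -0.5
        (Model.FICT_RP, (0.0, 0.0), "A", 1, AgentParams(0.5, 0.5, 1.0), (0.5, -0.5), 1.0),
        # loss under the chosen-only model leaves the unchosen value untouched
        (Model.RP, (0.2, 0.7), "A", -1, AgentParams(0.5, 0.25, 1.0), (-0.1, 0.7), -1.2),
        # zero learning rates change nothing
        (Model.FICT_RP, (0.3, -0.2), "B", 1, AgentParams(0.0, 0.0, 2.0), (0.3, -0.2), 1.2),
    ],
)
def test_update_values_hand_examples(model, state, chosen, r, params, expected_v, expected_pe):
    res = update_values(model, ValueState(*state), chosen, r, params)
    assert res.values_after.v_a == pytest.approx(expected_v[0], abs=1e-15)
    assert res.values_after.v_b == pytest.approx(expected_v[1], abs=1e-15)
    assert res.prediction_error == pytest.approx(expected_pe, abs=1e-15)
    assert 0.0 < res.choice_prob_a < 1.0


def test_update_values_validates_inputs():
    p = AgentParams(0.5, 0.5, 1.0)
    with pytest.raises(ValueError):
        update_values(Model.FICT_RP, ValueState(), "C", 1, p)
    with pytest.raises(ValueError):
        update_values(Model.FICT_RP, ValueState(), "A", 0, p)
    with pytest.raises(ValueError):
        update_values("not-a-model", ValueState(), "A", 1, p)
    with pytest.raises(ValueError):
        update_values(Model.FICT, ValueState(), "A", 1, AgentParams(0.4, 0.1, 1.0))
    with pytest.raises(ValueError):
        AgentParams(1.2, 0.1, 1.0)
    with pytest.raises(ValueError):
        AgentParams(0.5, 0.1, -0.5)


def test_choice_probability_examples():
    assert choice_probability(ValueState(0.37, 0.37), 5.0) == pytest.approx(0.5)
    assert choice_probability(ValueState(0.9, -0.9), 0.0) == pytest.approx(0.5)
    # logistic evaluated at beta * dV = 1
    assert choice_probability(ValueState(1.0, 0.0), 1.0) == pytest.approx(
        1.0 / (1.0 + math.exp(-1.0)), rel=1e-12
    )
    # numerically stable in the saturated regime
    assert choice_probability(ValueState(1.0, -1.0), 500.0) == pytest.approx(1.0)
    assert choice_probability(ValueState(-1.0, 1.0), 500.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        choice_probability(ValueState(), -1.0)


def test_choice_probability_monotonicity():
    dvs = np.linspace(-1.5, 1.5, 21)
    probs = [choice_probability(ValueState(d, 0.0), 2.0) for d in dvs]
    assert np.all(np.diff(probs) > 0)
    betas = np.linspace(0.1, 8.0, 15)
    probs_b = [choice_probability(ValueState(0.4, 0.1), b) for b in betas]
    assert np.all(np.diff(probs_b) > 0)


class TestTrajectoryLoglik:
    def test_uniform_policy_at_zero_beta(self):
        rng = np.random.default_rng(0)
        df = random_trial_frame(rng, 2, 30)
        ll = trajectory_loglik(Model.FICT_RP, AgentParams(0.4, 0.2, 0.0), df)
        assert np.allclose(ll, math.log(0.5), atol=1e-15)
        assert ll.sum() == pytest.approx(60 * math.log(0.5))

    def test_first_trial_is_parameter_free(self):
        rng = np.random.default_rng(1)
        df = random_trial_frame(rng, 1, 1)
        for params in (AgentParams(0.1, 0.9, 7.0), AgentParams(0.9, 0.1, 0.3)):
            ll = trajectory_loglik(Model.FICT_RP, params, df)
            assert ll[0] == pytest.approx(math.log(0.5), abs=1e-15)

    def test_hand_replay_three_trials(self):
        from revlearn.pipeline import load_hand_fixture
        from scipy.special import expit

        df = load_hand_fixture()
        ll = trajectory_loglik(Model.FICT_RP, AgentParams(0.4, 0.2, 2.0), df)
        # independent hand replay: V (0,0) -> (0.4,-0.4) -> (0.12,-0.12)
        expected = [math.log(0.5), math.log(expit(2 * 0.8)), math.log(expit(-2 * 0.24))]
        np.testing.assert_allclose(ll, expected, atol=1e-14)
        assert ll.sum() == pytest.approx(-1.8387227958440275, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(params=params_st, seq=seq_st)
    def test_matches_reference_replay_all_models(self, params, seq):
        ep, en, be = params
        choices = np.array([c for c, _ in seq])
        rewards = np.array([r for _, r in seq])
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject_id": "s",
                "session": 1,
                "trial": np.arange(1, len(seq) + 1),
                "high_side": "A",
                "choice": np.where(choices == 0, "A", "B"),
                "rewarded": rewards == 1,
            }
        )
        for model in (Model.RP, Model.FICT_RP):
            ref, _ = reference_replay(ep, en, be, model.fictitious, choices, rewards)
            got = trajectory_loglik(model, AgentParams(ep, en, be), df)
            np.testing.assert_allclose(got, ref, atol=1e-12)
        ref2, _ = reference_replay(ep, ep, be, True, choices, rewards)
        got2 = trajectory_loglik(Model.FICT, AgentParams.symmetric(ep, be), df)
        np.testing.assert_allclose(got2, ref2, atol=1e-12)

    def test_errors(self):
        import pandas as pd

        p = AgentParams(0.4, 0.2, 1.0)
        with pytest.raises(ValueError):
            trajectory_loglik(Model.FICT_RP, p, pd.DataFrame(
                {"subject_id": [], "session": [], "trial": [], "choice": [], "rewarded": []}
            ))
        bad = pd.DataFrame(
            {
                "subject_id": "s",
                "session": [1, 1],
                "trial": [2, 1],
                "high_side": "A",
                "choice": ["A", "B"],
                "rewarded": [True, False],
            }
        )
        with pytest.raises(ValueError, match="ordered"):
            trajectory_loglik(Model.FICT_RP, p, bad)


class TestModelReductions:
    """The nested-model identities: the general model collapses onto the
    restricted ones when its extra freedom is removed."""

    @settings(deadline=None, max_examples=30)
    @given(eta=st.floats(0.0, 1.0), beta=st.floats(0.0, 8.0), seq=seq_st)
    def test_equal_rates_reduce_to_single_rate_model(self, eta, beta, seq):
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject_id": "s",
                "session": 1,
                "trial": np.arange(1, len(seq) + 1),
                "high_side": "A",
                "choice": ["A" if c == 0 else "B" for c, _ in seq],
                "rewarded": [r == 1 for _, r in seq],
            }
        )
        ll3 = trajectory_loglik(Model.FICT_RP, AgentParams(eta, eta, beta), df)
        ll2 = trajectory_loglik(Model.FICT, AgentParams.symmetric(eta, beta), df)
        np.testing.assert_allclose(ll3, ll2, atol=1e-12)

    def test_disabling_fictitious_recovers_chosen_only_model(self):
        # step-level check against the reference replay, across many sequences
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(5, 40)
            choices = rng.integers(0, 2, n)
            rewards = rng.choice([-1, 1], n)
            ep, en, be = rng.random(), rng.random(), 4 * rng.random()
            ref_no_fict, vals = reference_replay(ep, en, be, False, choices, rewards)
            state = ValueState()
            params = AgentParams(ep, en, be)
            lls = []
            for c, r in zip(choices, rewards):
                opt = "A" if c == 0 else "B"
                p_a = choice_probability(state, be)
                lls.append(math.log(p_a if c == 0 else 1 - p_a))
                state = update_values(Model.RP, state, opt, int(r), params).values_after
            np.testing.assert_allclose(lls, ref_no_fict, atol=1e-12)


class TestValueInvariants:
    @settings(deadline=None, max_examples=40)
    @given(params=params_st, seq=seq_st, v0=st.tuples(st.floats(-1, 1), st.floats(-1, 1)))
    def test_values_stay_bounded(self, params, seq, v0):
        ep, en, be = params
        state = ValueState(*v0)
        p = AgentParams(ep, en, be)
        for c, r in seq:
            state = update_values(
                Model.FICT_RP, state, "A" if c == 0 else "B", r, p
            ).values_after
            assert -1.0 <= state.v_a <= 1.0
            assert -1.0 <= state.v_b <= 1.0

    def test_fictitious_contracts_value_sum(self):
        # chosen moves toward r, unchosen toward -r: the sum shrinks by (1-eta)
        rng = np.random.default_rng(9)
        eta = 0.3
        p = AgentParams.symmetric(eta, 1.0)
        state = ValueState(0.6, 0.1)
        for _ in range(25):
            before = state.v_a + state.v_b
            c = "A" if rng.random() < 0.5 else "B"
            r = int(rng.choice([-1, 1]))
            state = update_values(Model.FICT, state, c, r, p).values_after
            assert state.v_a + state.v_b == pytest.approx((1 - eta) * before, abs=1e-12)
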