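"""Tests of the model-free behavioral statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import revlearn as rl
from revlearn.metrics import (
    moving_average,
    p_correct_by_reversal_trial,
    p_correct_by_session,
    wsls,
    wsls_table,
)


def frame(choices, rewards, high="A", session=None):
    n = len(choices)
    return pd.DataFrame(
        {
            "subject_id": "s1",
            "session": session if session is not None else [1] * n,
            "trial": list(range(1, n + 1)) if session is None else
                     [i + 1 for s in sorted(set(session)) for i in range(session.count(s))],
            "high_side": high if isinstance(high, str) else high,
            "choice": choices,
            "rewarded": rewards,
        }
    )


class TestPCorrectBySession:
    def test_toy_counts(self):
        df = frame(["A", "B", "A", "A"], [True, False, True, False])
        out = p_correct_by_session(df)
        assert out["p_correct"].iloc[0] == pytest.approx(0.75)

    def test_all_correct(self):
        df = frame(["A"] * 6, [True] * 6)
        assert p_correct_by_session(df)["p_correct"].iloc[0] == 1.0

    def test_chance_level_for_random_agent(self):
        cohort = rl.generate_cohort(
            [rl.GroupSpec.from_constrained("g", 4, {"eta_pos": 0.4, "eta_neg": 0.1, "beta": 1e-6}, 0.0)],
            rl.TaskConfig(n_sessions=4),
            master_seed=5,
        )
        out = p_correct_by_session(cohort.trials)
        grand = out["p_correct"].mean()
        n = len(cohort.trials)
        assert abs(grand - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            p_correct_by_session(pd.DataFrame(columns=["subject_id", "session"]))


class TestPCorrectByReversalTrial:
    def test_hand_counted_two_sessions(self):
        # 4-trial sessions, reversal after trial 2; post-reversal trials are 3, 4
        rows = []
        for sess, (c3, c4) in enumerate([("B", "A"), ("B", "B")], start=1):
            rows += [
                ("s1", sess, 1, "A", "A", True),
                ("s1", sess, 2, "A", "A", True),
                ("s1", sess, 3, "B", c3, True),
                ("s1", sess, 4, "B", c4, False),
            ]
        df = pd.DataFrame(
            rows, columns=["subject_id", "session", "trial", "high_side", "choice", "rewarded"]
        )
        out = p_correct_by_reversal_trial(df, reversal_trial=2)
        # index 1: B chosen in both sessions -> 1.0; index 2: once -> 0.5
        assert out[out["trial_after_reversal"] == 1]["p_correct"].iloc[0] == 1.0
        assert out[out["trial_after_reversal"] == 2]["p_correct"].iloc[0] == 0.5

    def test_slow_learner_below_chance_after_reversal(self):
        # an agent that never updates but prefers the pre-reversal side is
        # below chance right after the flip
        cohort = rl.generate_cohort(
            [rl.GroupSpec.from_constrained("g", 12, {"eta_pos": 0.5, "eta_neg": 0.3, "beta": 3.0}, 0.0)],
            rl.TaskConfig(n_sessions=6),
            master_seed=9,
        )
        out = p_correct_by_reversal_trial(cohort.trials, reversal_trial=60)
        early = out[out["trial_after_reversal"] <= 3].groupby("trial_after_reversal")["p_correct"].mean()
        assert (early < 0.5).all()
        assert out["trial_after_reversal"].max() == 60

    def test_perfect_oracle_agent(self):
        df = frame(["A", "A", "B", "B"], [True] * 4, high=["A", "A", "B", "B"])
        out = p_correct_by_reversal_trial(df, reversal_trial=2)
        assert (out["p_correct"] == 1.0).all()


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.array([0.2, 0.9, 0.1, 0.5])
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_constant_series(self):
        assert np.allclose(moving_average([0.7] * 10, 5), 0.7)

    def test_truncated_edges_hand_example(self):
        got = moving_average([0, 0, 1, 1, 1], 3)
        np.testing.assert_allclose(got, [0, 1 / 3, 2 / 3, 1, 1])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1, 2, 3], 4)

    def test_length_preserved(self):
        assert len(moving_average(np.arange(50, dtype=float), 21)) == 50


class TestWsls:
    def test_hand_enumeration(self):
        # pairs: (A+ -> A stay), (A- -> B shift), (B+ -> B stay)
        df = frame(["A", "A", "B", "B"], [True, False, True, False])
        s = wsls(df)
        assert s.win_stay == pytest.approx(1.0)
        assert s.lose_shift == pytest.approx(1.0)
        assert s.n_win == 2 and s.n_lose == 1

    def test_always_repeat_agent(self):
        df = frame(["A"] * 10, [True, False] * 5)
        s = wsls(df)
        assert s.win_stay == 1.0
        assert s.lose_shift == 0.0

    def test_chance_agent(self):
        rng = np.random.default_rng(4)
        n = 4000
        df = frame(
            list(np.where(rng.random(n) < 0.5, "A", "B")),
            list(rng.random(n) < 0.5),
        )
        s = wsls(df)
        assert abs(s.win_stay - 0.5) < 4 * np.sqrt(0.25 / s.n_win)
        assert abs(s.lose_shift - 0.5) < 4 * np.sqrt(0.25 / s.n_lose)

    def test_session_boundary_pairing(self):
        df = frame(
            ["A", "B", "B", "A"], [True, False, True, False], session=[1, 1, 2, 2]
        )
        s = wsls(df)  # within-session: pairs (A+ -> B), (B+ -> A)
        assert s.n_win == 2 and s.n_lose == 0
        assert s.win_stay == 0.0 and s.lose_shift is None
        s2 = wsls(df, within_session=False)  # adds the cross-boundary (B- -> B) pair
        assert s2.n_win == 2 and s2.n_lose == 1
        assert s2.lose_shift == 0.0

    def test_missing_denominator_reported_as_missing(self):
        df = frame(["A", "B", "A"], [True, True, True])
        s = wsls(df)
        assert s.lose_shift is None and s.n_lose == 0

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.tuples(st.sampled_from("AB"), st.booleans(), st.integers(1, 3)),
            min_size=2,
            max_size=50,
        )
    )
    def test_counts_partition_pairs(self, rows):
        rows = sorted(rows, key=lambda r: r[2])
        df = pd.DataFrame(
            {
                "subject_id": "s1",
                "session": [r[2] for r in rows],
                "trial": np.arange(1, len(rows) + 1),
                "high_side": "A",
                "choice": [r[0] for r in rows],
                "rewarded": [r[1] for r in rows],
            }
        )
        s = wsls(df)
        sessions = df["session"].to_numpy()
        expected_pairs = int((sessions[1:] == sessions[:-1]).sum())
        assert s.n_win + s.n_lose == expected_pairs

    def test_wsls_table_groups(self, two_group_cohort):
        t = wsls_table(two_group_cohort.trials)
        assert set(t["group"]) == {"control", "mutant"}
        assert len(t) == len(two_group_cohort.subject_ids())
        assert t["win_stay"].between(0, 1).all()

    def test_win_stay_monotone_in_beta_small_ensemble(self):
        from revlearn.task import _simulate_sessions
        from revlearn.models import AgentParams, Model, ValueState

        means = []
        for b in (0.5, 2.0):
            vals = []
            for j in range(10):
                rng = np.random.default_rng(np.random.SeedSequence(entropy=2, spawn_key=(int(b * 10), j)))
                df, _ = _simulate_sessions(
                    AgentParams(0.4, 0.1, b), Model.FICT_RP, rl.TaskConfig(n_sessions=3),
                    ValueState(0, 0), rng, 3,
                )
                df.insert(0, "subject_id", "a")
                vals.append(wsls(df).win_stay)
            means.append(np.mean(vals))
        assert means[1] > means[0]
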