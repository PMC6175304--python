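"""Model-free behavioral statistics for reversal-learning event logs.

"Correct" always means choosing the side currently carrying the high reward
probability, including the trials immediately after a reversal (where a
well-trained subject is expected to be below chance until it re-learns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WslsSummary",
    "p_correct_by_session",
    "p_correct_by_reversal_trial",
    "moving_average",
    "wsls",
    "wsls_table",
]


@dataclass(frozen=True)
class WslsSummary:
    """Win-stay / lose-shift probabilities and their count denominators.

    win_stay  = stays after a rewarded predecessor / rewarded predecessors
    lose_shift = switches after an unrewarded predecessor / unrewarded ones
    A component with a zero denominator is reported as None (missing).
    """

    win_stay: float | None
    lose_shift: float | None
    n_win: int
    n_lose: int


def p_correct_by_session(trials: pd.DataFrame) -> pd.DataFrame:
    """Fraction of choices of the current high side, per subject and session."""
    if trials.empty:
        raise ValueError("empty trial table")
    df = trials.copy()
    df["correct"] = (df["choice"] == df["high_side"]).astype(float)
    out = (
        df.groupby(["subject_id", "session"], sort=True)["correct"]
        .mean()
        .rename("p_correct")
        .reset_index()
    )
    return out


def p_correct_by_reversal_trial(
    trials: pd.DataFrame, reversal_trial: int = 60
) -> pd.DataFrame:
    """Fraction correct at each post-reversal trial index, averaged over
    sessions, per subject.

    Index 1 is the first trial after the contingency flip (within-session
    trial ``reversal_trial + 1``).
    """
    df = trials[trials["trial"] > reversal_trial].copy()
    if df.empty:
        raise ValueError("no post-reversal trials (check reversal_trial)")
    df["trial_after_reversal"] = df["trial"] - reversal_trial
    df["correct"] = (df["choice"] == df["high_side"]).astype(float)
    out = (
        df.groupby(["subject_id", "trial_after_reversal"], sort=True)["correct"]
        .mean()
        .rename("p_correct")
        .reset_index()
    )
    return out


def moving_average(series, window: int) -> np.ndarray:
    """Centered moving average with truncated (shrinking) windows at the
    edges, so the output has the same length as the input."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _pairs(choices: np.ndarray, rewarded: np.ndarray, session: np.ndarray, within_session: bool):
    """Predecessor/successor pairs; by default the first trial of each
    session has no predecessor."""
    same = choices[1:] == choices[:-1]
    prev_rewarded = rewarded[:-1]
    if within_session:
        keep = session[1:] == session[:-1]
        same, prev_rewarded = same[keep], prev_rewarded[keep]
    return same, prev_rewarded


def wsls(trials: pd.DataFrame, within_session: bool = True) -> WslsSummary:
    """Win-stay / lose-shift summary of a single subject's trial sequence."""
    if "subject_id" in trials and trials["subject_id"].nunique() > 1:
        raise ValueError("wsls expects one subject; use wsls_table for cohorts")
    df = trials.sort_values(["session", "trial"]) if "session" in trials else trials
    if len(df) < 2:
        raise ValueError("need at least 2 trials")
    choices = df["choice"].to_numpy()
    rewarded = df["rewarded"].to_numpy(dtype=bool)
    session = df["session"].to_numpy() if "session" in df else np.ones(len(df))
    same, prev_rewarded = _pairs(choices, rewarded, session, within_session)
    n_win = int(prev_rewarded.sum())
    n_lose = int((~prev_rewarded).sum())
    win_stay = float(same[prev_rewarded].sum() / n_win) if n_win else None
    lose_shift = float((~same[~prev_rewarded]).sum() / n_lose) if n_lose else None
    return WslsSummary(win_stay, lose_shift, n_win, n_lose)


def wsls_table(trials: pd.DataFrame, within_session: bool = True) -> pd.DataFrame:
    """Per-subject WSLS summaries for a cohort event log."""
    rows = []
    for sid, df in trials.groupby("subject_id", sort=True):
        s = wsls(df, within_session=within_session)
        rows.append(
            {
                "subject_id": sid,
                "group": df["group"].iloc[0] if "group" in df else "all",
                "win_stay": s.win_stay,
                "lose_shift": s.lose_shift,
                "n_win": s.n_win,
                "n_lose": s.n_lose,
            }
        )
    return pd.DataFrame(rows)
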