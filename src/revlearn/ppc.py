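"""Posterior-predictive simulation: regenerate agents from fitted individual
posterior means and check that they reproduce model-free choice statistics.

Each fitted subject is replayed as a simulated agent with point parameters
equal to the posterior means of its constrained individual parameters, on a
freshly drawn task schedule of the same length (no access to the subject's
actual choice or outcome history).  The simulated cohort's win-stay /
lose-shift pattern and its group difference are then compared with the real
(or generating) cohort's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import PosteriorFit
from .metrics import wsls_table
from .models import AgentParams, ValueState
from .task import CohortData, TaskConfig, _simulate_sessions

__all__ = ["PpcResult", "simulate_from_fit", "ppc_wsls"]


@dataclass
class PpcResult:
    per_subject: pd.DataFrame  # real vs simulated WSLS and discrepancies
    group_summary: pd.DataFrame  # mean/sd per group x source
    group_tests: pd.DataFrame  # two-sample t per metric on simulated data


def _point_params(fit: PosteriorFit, draw_index: int | None) -> pd.DataFrame:
    if draw_index is None:
        return fit.subject_posterior_means()
    draws = fit.subject_draws[draw_index]  # (S, K) constrained
    rows = []
    for s, sid in enumerate(fit.subject_ids):
        d = dict(zip(fit.param_names, draws[s]))
        if fit.model.single_rate:
            d = {"eta_pos": d["eta"], "eta_neg": d["eta"], "beta": d["beta"]}
        rows.append({"subject_id": sid, "group": fit.group, **d})
    return pd.DataFrame(rows)


def simulate_from_fit(
    fits: "PosteriorFit | dict[str, PosteriorFit]",
    config: TaskConfig = TaskConfig(),
    seed: int = 0,
    draw_index: int | None = None,
) -> CohortData:
    """Simulate one agent per fitted subject for the full trajectory
    (``config.n_sessions * config.trials_per_session`` trials each).

    By default each agent's point parameters are its posterior means;
    passing ``draw_index`` instead replays a single joint posterior draw
    (useful for propagating posterior uncertainty through the check).
    """
    if isinstance(fits, PosteriorFit):
        fits = {fits.group: fits}
    frames = []
    param_rows = []
    for g_idx, group in enumerate(sorted(fits)):
        fit = fits[group]
        means = _point_params(fit, draw_index)
        for j, row in enumerate(means.itertuples()):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(g_idx, j, 7))
            rng = np.random.default_rng(ss)
            params = AgentParams(row.eta_pos, row.eta_neg, row.beta)
            df, _ = _simulate_sessions(
                params, fit.model, config, ValueState(0.0, 0.0), rng, config.n_sessions
            )
            df.insert(0, "group", group)
            df.insert(0, "subject_id", row.subject_id)
            frames.append(df)
            param_rows.append(
                {
                    "subject_id": row.subject_id,
                    "group": group,
                    "eta_pos": params.eta_pos,
                    "eta_neg": params.eta_neg,
                    "beta": params.beta,
                }
            )
    trials = pd.concat(frames, ignore_index=True)
    return CohortData(
        trials=trials, params=pd.DataFrame(param_rows), config=config, master_seed=seed
    )


def ppc_wsls(real: CohortData, simulated: CohortData) -> PpcResult:
    """Compare real and simulated win-stay / lose-shift, per subject and as a
    two-sample (mutant vs control) t test on the simulated cohort."""
    real_t = wsls_table(real.trials).set_index("subject_id")
    sim_t = wsls_table(simulated.trials).set_index("subject_id")
    if set(real_t.index) != set(sim_t.index):
        raise ValueError("real and simulated cohorts have different subject rosters")
    per_subject = real_t.join(sim_t[["win_stay", "lose_shift"]], rsuffix="_sim")
    per_subject["win_stay_err"] = per_subject["win_stay_sim"] - per_subject["win_stay"]
    per_subject["lose_shift_err"] = (
        per_subject["lose_shift_sim"] - per_subject["lose_shift"]
    )
    per_subject = per_subject.reset_index()

    melted = []
    for source, table in (("real", real_t), ("simulated", sim_t)):
        for metric in ("win_stay", "lose_shift"):
            g = table.groupby("group")[metric].agg(["mean", "std", "count"])
            g = g.assign(source=source, metric=metric).reset_index()
            melted.append(g)
    group_summary = pd.concat(melted, ignore_index=True)

    groups = sorted(sim_t["group"].unique())
    test_rows = []
    if len(groups) == 2:
        for source, table in (("real", real_t), ("simulated", sim_t)):
            for metric in ("win_stay", "lose_shift"):
                a = table.loc[table["group"] == groups[0], metric].dropna()
                b = table.loc[table["group"] == groups[1], metric].dropna()
                t, p = stats.ttest_ind(a, b)
                test_rows.append(
                    {
                        "source": source,
                        "metric": metric,
                        "group_a": groups[0],
                        "group_b": groups[1],
                        "mean_diff": float(a.mean() - b.mean()),
                        "t": float(t),
                        "p": float(p),
                        "df": len(a) + len(b) - 2,
                    }
                )
    group_tests = pd.DataFrame(test_rows)
    return PpcResult(per_subject=per_subject, group_summary=group_summary, group_tests=group_tests)
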