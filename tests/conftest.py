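import warnings

import numpy as np
import pytest

import revlearn as rl
from revlearn.inference import McmcSettings, fit_group

# The hierarchical sampler warns when chains are run at reduced budgets;
# individual tests assert on convergence where it matters.
warnings.filterwarnings("ignore", message=".*split-R-hat.*")


@pytest.fixture(scope="session")
def small_cohort() -> rl.CohortData:
    """One 4-subject group, 2 sessions each: enough signal for smoke-level
    inference tests at a few seconds per fit."""
    spec = rl.GroupSpec.from_constrained(
        "g", 4, {"eta_pos": 0.4, "eta_neg": 0.1, "beta": 2.0}, 0.2
    )
    return rl.generate_cohort([spec], rl.TaskConfig(n_sessions=2), master_seed=11)


@pytest.fixture(scope="session")
def quick_settings() -> McmcSettings:
    return McmcSettings(chains=2, warmup=300, steps=300, draws_target=400)


@pytest.fixture(scope="session")
def small_fit(small_cohort, quick_settings) -> rl.PosteriorFit:
    """A single reusable hierarchical fit of the small cohort (model 3)."""
    return fit_group(rl.Model.FICT_RP, small_cohort, "g", quick_settings, seed=1)


@pytest.fixture(scope="session")
def two_group_cohort() -> rl.CohortData:
    """Default control/mutant conditions at 3 sessions for fast group tests."""
    return rl.generate_cohort(
        rl.default_group_specs(n_control=4, n_mutant=4),
        rl.TaskConfig(n_sessions=3),
        master_seed=23,
    )


def random_trial_frame(rng: np.random.Generator, n_sessions: int, trials_per_session: int):
    """Random (schedule-free) choice/outcome sequences for likelihood tests."""
    import pandas as pd

    n = n_sessions * trials_per_session
    return pd.DataFrame(
        {
            "subject_id": "s",
            "session": np.repeat(np.arange(1, n_sessions + 1), trials_per_session),
            "trial": np.tile(np.arange(1, trials_per_session + 1), n_sessions),
            "high_side": "A",
            "choice": np.where(rng.random(n) < 0.5, "A", "B"),
            "rewarded": rng.random(n) < 0.5,
        }
    )
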