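import numpy as np
import pandas as pd
import pytest

from choicelab import cohort, task


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trained_stage():
    return task.stage_from_index(task.TRAINED_STAGE_ID, gain=4.0,
                                 reward_volume=1.5)


@pytest.fixture(scope="session")
def basic_agent():
    return cohort.default_agent("basic")


@pytest.fixture(scope="session")
def full_agent():
    return cohort.default_agent("full")


@pytest.fixture(scope="session")
def basic_trials(basic_agent, trained_stage):
    """Three trained basic-task sessions of one mouse (~2100 trials)."""
    rng = np.random.default_rng(99)
    sess = []
    for day in (1, 2, 3):
        sched = task.build_session_schedule("basic", 700, rng)
        sess.append(cohort.simulate_session(
            basic_agent, trained_stage, sched, rng, variant="basic",
            n_trials=700, session_day=day))
    return pd.concat(sess, ignore_index=True)


@pytest.fixture(scope="session")
def full_trials(full_agent, trained_stage):
    """Three trained full-task sessions of one mouse (~2100 trials)."""
    rng = np.random.default_rng(98)
    sess = []
    for day in (1, 2, 3):
        sched = task.build_session_schedule("full", 700, rng)
        sess.append(cohort.simulate_session(
            full_agent, trained_stage, sched, rng, variant="full",
            n_trials=700, session_day=day))
    return pd.concat(sess, ignore_index=True)


@pytest.fixture(scope="session")
def trained_cohort():
    """7 labs x 8 mice, trained-state sessions only (shared, read-only)."""
    cfg = cohort.CohortConfig(n_labs=7, n_mice_per_lab=8, mode="trained_only")
    return cohort.simulate_cohort(cfg, np.random.default_rng(2024))
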