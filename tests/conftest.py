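"""Shared fixtures: small synthetic sessions and datasets.

Fixtures are session-scoped where generation is expensive; tests must not
mutate them.
"""

import numpy as np
import pytest

from emgdecode.dataset import SyncedTrial, build_dataset, make_folds
from emgdecode.synthetic import ParadigmSpec, SynergySpec, generate_session
from emgdecode.workflows import preprocess_session


@pytest.fixture(scope="session")
def short_paradigm():
    """Short trials (one excursion per motion pair) for fast unit tests."""
    return ParadigmSpec(
        motion_order=("WF", "WE", "P", "S", "HG", "HO"),
        hold_duration=1.5,
        rest_duration=0.5,
        n_trials=5,
    )


@pytest.fixture(scope="session")
def small_session(short_paradigm):
    return generate_session(short_paradigm, SynergySpec(), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_session):
    trials, stats = preprocess_session(small_session)
    return build_dataset(trials)


@pytest.fixture(scope="session")
def small_folds(small_dataset):
    ids = sorted(set(int(t) for t in small_dataset.trial))
    return make_folds(ids, k=5, mode="second", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_synced_trial(T=240, fs=120.0, trial_id=0, seed=0):
    """Random synced trial of length T for windowing tests."""
    r = np.random.default_rng(seed)
    return SyncedTrial(
        envelope=r.uniform(0, 1, size=(T, 32)),
        angles=r.normal(0, 10, size=(T, 3)),
        fs=fs,
        trial_id=trial_id,
    )
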