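"""Shared fixtures: synthetic datasets generated at session scope."""

from __future__ import annotations

import pytest
from hypothesis import settings

from addm.model import ModelParams
from addm.pools import build_pools
from addm.preprocessing import clean_dataset
from addm.synthetic import REFERENCE_PARAMS, SyntheticConfig, generate_trials

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_dataset():
    """Two sessions' worth of trials at the reference aDDM parameters."""
    config = SyntheticConfig(
        true_params=REFERENCE_PARAMS, n_subjects=2, trials_per_subject=336, master_seed=101
    )
    return generate_trials(config)


@pytest.fixture(scope="session")
def cleaned_reference(reference_dataset):
    kept, _ = clean_dataset(reference_dataset)
    return kept


@pytest.fixture(scope="session")
def reference_pools(cleaned_reference):
    return build_pools(cleaned_reference)


@pytest.fixture(scope="session")
def ddm_dataset():
    """Dataset generated at θ = 1 (a standard DDM) on a grid node."""
    config = SyntheticConfig(
        true_params=ModelParams(d=0.005, theta=1.0, sigma=0.05),
        n_subjects=2, trials_per_subject=336, master_seed=202,
    )
    trials = generate_trials(config)
    kept, _ = clean_dataset(trials)
    return kept
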