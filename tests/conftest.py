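"""Shared fixtures.

The session-scoped cohort and experiment reports back the end-to-end checks:
they are expensive (the nested leave-one-subject-out search trains thousands
of forests) and therefore computed once per session.
"""

import numpy as np
import pytest

from swallowdetect import SyntheticConfig, generate_dataset, run_biemg_experiment, run_emg_experiment
from swallowdetect.experiments import ExperimentConfig


@pytest.fixture(scope="session")
def cohort():
    """Ten synthetic subjects under the default study conditions."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def emg_report(cohort):
    return run_emg_experiment(cohort, ExperimentConfig(seed=1))


@pytest.fixture(scope="session")
def biemg_report(cohort):
    return run_biemg_experiment(cohort, ExperimentConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
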