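"""Shared fixtures: generating models and simulated datasets.

The heavyweight simulation-and-refit studies are session-scoped so that the
parameter-recovery, covariate-selection and variability-shrinkage checks all
share one set of replicate fits.
"""

import pytest

from cipropk.cohort import sample_cohort, simulate_dataset
from cipropk.experiments import (
    final_model,
    null_selection_experiment,
    recovery_experiment,
)


@pytest.fixture(scope="session")
def truth_model():
    return final_model()


@pytest.fixture(scope="session")
def sim_dataset(truth_model):
    """One 30-subject, two-occasion dataset simulated from the final model."""
    cohort = sample_cohort(30, seed=11)
    return simulate_dataset(cohort, truth_model, seed=12)


@pytest.fixture(scope="session")
def recovery_study():
    """20 simulate-and-refit replicates under the final covariate model."""
    return recovery_experiment(n_replicates=20, seed=1, n_starts=3)


@pytest.fixture(scope="session")
def null_study():
    """100 replicates of the covariate step on data with no covariate effect."""
    return null_selection_experiment(n_replicates=100, seed=2)
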