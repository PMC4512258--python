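import numpy as np
import pytest

from braim import (
    balanced_design,
    build_design_matrix,
    build_responses,
    default_cohort_specs,
    fit_cohort,
    simulate_cohort,
)
from braim.types import HyperParams


@pytest.fixture(scope="session")
def designs48():
    return balanced_design(6)


@pytest.fixture(scope="session")
def recovery_cohort(designs48):
    """The 500-transcript recovery cohort: 50 imprinted (|parental beta|
    >= 1), 450 null, sigma2=0.25, meas_sd=0.1, seed 1."""
    rng = np.random.default_rng(1)
    specs = default_cohort_specs(
        n_transcripts=500, n_imprinted=50, sigma2_true=0.25, meas_sd=0.1, rng=rng
    )
    records, truth = simulate_cohort(specs, designs48, rng=rng)
    return records, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort, designs48):
    """Default-hyperparameter combined fit of the recovery cohort."""
    records, truth = recovery_cohort
    responses = build_responses(records, designs48)
    dm = build_design_matrix(designs48)
    hyper = HyperParams(seed=1)
    fits = fit_cohort(responses, dm.X, hyper, dm.column_labels)
    return responses, dm, hyper, fits, truth


@pytest.fixture(scope="session")
def small_cohort(designs48):
    """A 6-transcript cohort (2 imprinted) for fast end-to-end tests."""
    rng = np.random.default_rng(7)
    specs = default_cohort_specs(n_transcripts=6, n_imprinted=2, rng=rng)
    records, truth = simulate_cohort(specs, designs48, rng=rng)
    return records, truth
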