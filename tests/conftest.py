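import numpy as np
import pandas as pd
import pytest

from glampi import (
    CohortSpec,
    GlampiParams,
    apply_exclusions,
    generate_cohort,
    standardize_dataset,
)

ZERO_SDS = GlampiParams(k=0, g2=0, beta=0, g3=0, m3=0, sigma=0, nu=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Error-free cohort: optimal parameters, no noise, no spread."""
    spec = CohortSpec.from_preset(
        "elderly",
        5,
        rng_seed=3,
        param_means=GlampiParams(),  # all nominal, sigma = nu = 0
        param_sds=ZERO_SDS,
    )
    trials, _, truth = generate_cohort(spec, include_tracking=False)
    return trials, truth


@pytest.fixture(scope="session")
def elderly_kept():
    """Small preprocessed elderly cohort shared across fitting tests."""
    spec = CohortSpec.from_preset("elderly", 4, rng_seed=5)
    trials, _, truth = generate_cohort(spec, include_tracking=False)
    std = standardize_dataset(trials)
    kept, _ = apply_exclusions(std)
    return kept, truth
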