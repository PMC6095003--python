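import dataclasses

import pytest

from atrophyz.normative import fit_normative_model
from atrophyz.synthetic import (CohortConfig, PhantomConfig,
                                generate_patient_cohort, generate_phantom,
                                generate_reference_cohort,
                                generate_scanner_controls)


@pytest.fixture(scope="session")
def cohort_config():
    return CohortConfig(seed=123)


@pytest.fixture(scope="session")
def reference(cohort_config):
    return generate_reference_cohort(cohort_config)


@pytest.fixture(scope="session")
def controls(cohort_config):
    return generate_scanner_controls(cohort_config)


@pytest.fixture(scope="session")
def patients(cohort_config):
    return generate_patient_cohort(cohort_config)


@pytest.fixture(scope="session")
def model(reference, controls):
    return fit_normative_model(reference, controls)


@pytest.fixture(scope="session")
def big_controls_config(cohort_config):
    # large scanner-control cohorts so control moments are tight
    return dataclasses.replace(cohort_config, seed=321,
                               n_controls_per_scanner=(2000, 2000))


@pytest.fixture(scope="session")
def big_controls(big_controls_config):
    return generate_scanner_controls(big_controls_config)


@pytest.fixture(scope="session")
def model_big_moments(reference, big_controls):
    return fit_normative_model(reference, big_controls)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomConfig(seed=5))


def noise_free_config(seed=7, **overrides):
    """Cohort config with zero residual SD in every region."""
    cfg = CohortConfig(seed=seed, **overrides)
    cfg.regions = {name: dataclasses.replace(p, sd=0.0)
                   for name, p in cfg.regions.items()}
    return cfg
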