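import numpy as np
import pytest

from mrcae import SyntheticSpec, generate_expression, generate_survival


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: matrix, labels and planted driver IDs."""
    spec = SyntheticSpec(seed=11)
    m, labels, drivers = generate_expression(spec)
    return spec, m, labels, drivers


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for fast training-contract tests."""
    spec = SyntheticSpec(
        n_samples=120, n_features=40, n_drivers=5, n_classes=3, seed=3
    )
    m, labels, drivers = generate_expression(spec)
    return spec, m, labels, drivers


@pytest.fixture(scope="session")
def survival_cohort(default_cohort):
    spec, m, labels, drivers = default_cohort
    clinical = generate_survival(spec, m)
    return spec, m, clinical, drivers
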