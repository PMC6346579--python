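import numpy as np
import pytest

from wmh_bullseye import (GeneratorParams, apply_exclusion_cascade,
                          build_label_volume, build_parcellation,
                          derive_phenotypes, generate_registry)


@pytest.fixture(scope="session")
def phantom_labels():
    """Default-geometry phantom at the standard 64^3 grid."""
    return build_label_volume((64, 64, 64))


@pytest.fixture(scope="session")
def phantom_parcellation(phantom_labels):
    return build_parcellation(phantom_labels)


@pytest.fixture(scope="session")
def small_labels():
    """Smaller phantom for cohort-scale simulations."""
    return build_label_volume((48, 48, 48))


@pytest.fixture(scope="session")
def default_cohort():
    """One analyzable default cohort (n = 561) with derived phenotypes."""
    params = GeneratorParams(seed=12345)
    cohort = apply_exclusion_cascade(generate_registry(params), params)
    return derive_phenotypes(cohort), params


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
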