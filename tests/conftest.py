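import numpy as np
import pytest

from shoulderload.datasets import build_sample, get_setup
from shoulderload.preprocessing import preprocess_cohort
from shoulderload.synthetic import generate_cohort, sample_traits


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two participants, short subtrials, moderate noise, no exclusions."""
    return generate_cohort(
        n_participants=2, heterogeneity=0.3, noise_sd=0.1,
        n_exclusions=0, seed=11, duration_scale=0.2,
    )


@pytest.fixture(scope="session")
def tiny_aligned(tiny_cohort):
    return preprocess_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_sparse_samples(tiny_aligned):
    setup = get_setup("sparse")
    return {key: build_sample(trial, setup) for key, trial in tiny_aligned.items()}


@pytest.fixture
def traits():
    return sample_traits(1, heterogeneity=0.3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
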