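import numpy as np
import pytest

import structdyn as sd


def make_cohort(D=4, scenario="puberty_plus_alpha", n=(40, 40), seed=3,
                noise_sd=2.0, confounds=False):
    """Small synthetic cohort without confounds unless requested."""
    truth = sd.make_default_truth(D=D, scenario=scenario)
    kwargs = {} if confounds else {
        "sites": ("s1",), "site_offsets": (0.0,), "ticv_coef": 0.0}
    design = sd.CohortDesign(n_subjects=n, noise_sd=noise_sd, seed=seed, **kwargs)
    return sd.generate_cohort(design, truth)


@pytest.fixture(scope="session")
def small_cohort():
    """4-ROI, 80-subject cohort generated from the puberty+alpha scenario."""
    return make_cohort()


@pytest.fixture(scope="session")
def tiny_cohort():
    """2-ROI, 30-subject input-free cohort for fast fits."""
    return make_cohort(D=2, scenario="no_input", n=(15, 15), seed=7, noise_sd=1.5)


@pytest.fixture(scope="session")
def small_posterior(small_cohort):
    cohort, truth = small_cohort
    post = sd.variational_laplace(truth.spec, cohort)
    return post, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
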