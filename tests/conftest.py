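import numpy as np
import pytest

from omicsfuse import (DiffusionConfig, KernelConfig, SimConfig, make_toy_fixture,
                       simulate_cohort, zscore_features)


@pytest.fixture(scope="session")
def toy():
    """12-sample, 3-subtype deterministic cohort."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def cohort0():
    """Default synthetic cohort at seed 0."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def integrated0(cohort0):
    """Diffused tri-modal similarity for the seed-0 cohort."""
    from omicsfuse import integrate_modalities

    expr, meth, micro, clin, truth = cohort0
    views = [zscore_features(expr), meth, micro]
    w = integrate_modalities(views, KernelConfig(), DiffusionConfig())
    return w, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
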