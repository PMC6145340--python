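import numpy as np
import pytest

from micalung import MicaClusterer, generate_cohort, smokers_only


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, seed 1: features + clinical."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def smokers(cohort):
    matrix, _ = cohort
    return smokers_only(matrix)


@pytest.fixture(scope="session")
def fitted(smokers):
    """The standardize -> PCA -> K-means(k=4) chain fitted on the smokers."""
    return MicaClusterer(random_state=1).fit(smokers.data)


@pytest.fixture(scope="session")
def toy_blobs():
    """Four well-separated Gaussian blobs in 5-D, 30 points per blob."""
    rng = np.random.default_rng(7)
    centers = np.eye(4, 5) * 12.0
    X = np.vstack([c + rng.standard_normal((30, 5)) for c in centers])
    labels = np.repeat(np.arange(4), 30)
    return X, labels
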