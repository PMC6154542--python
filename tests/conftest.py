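import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bandpop as bp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(scores, pops=None, primers=None, ids=None, bands=None, sizes=None):
    """Shorthand BandMatrix constructor for fixtures."""
    scores = np.asarray(scores)
    n, j = scores.shape
    return bp.BandMatrix(
        scores,
        ids or [f"r{i + 1}" for i in range(n)],
        pops or ["P1"] * n,
        bands or [f"b{i + 1}" for i in range(j)],
        primers or ["prA"] * j,
        sizes,
    )


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (4 x 60 individuals, 122 bands) plus truth."""
    return bp.generate(seed=1)


@pytest.fixture(scope="session")
def study_matrix(default_study):
    return default_study[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
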