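import numpy as np
import pytest

from mutualism import models as M


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def all_model_ids():
    return M.list_models()


@pytest.fixture
def weak_facultative_linear():
    """Symmetric facultative Lotka-Volterra-style pair with weak benefits."""
    return M.make_params("case_1_1_1", r1=1, r2=1, s1=1, s2=1,
                         beta12=0.5, beta21=0.5)


@pytest.fixture
def obligate_strong_linear():
    """Symmetric obligate pair with strong benefits: saddle at (0.5, 0.5)."""
    return M.make_params("case_1_1_1", r1=-0.5, r2=-0.5, s1=1, s2=1,
                         beta12=2.0, beta21=2.0)


@pytest.fixture
def golden_ratio_saturating():
    """Symmetric saturating pair whose interior equilibrium is the golden ratio."""
    return M.make_params("case_1_2", r1=1, r2=1, s1=1, s2=1,
                         beta12=1, beta21=1, h12=1, h21=1)
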