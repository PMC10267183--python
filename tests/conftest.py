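import numpy as np
import pytest

from craniogrow.semilandmarks import build_template
from craniogrow.synthetic import default_params, make_template_skull

#: reduced one-sided patch counts for desk-scale sliding tests
SMALL_COUNTS = {"midfacial": 30, "calvarial": 90, "lower_occipital": 20}


@pytest.fixture(scope="session")
def params_clean():
    """Noise-free growth parameters (shared truth for oracle tests)."""
    return default_params(landmark_noise_sd=0.0)


@pytest.fixture(scope="session")
def params_noisy():
    return default_params(landmark_noise_sd=0.5)


@pytest.fixture(scope="session")
def template_skull(params_clean):
    """Reference specimen at subdivision 3 (shared, read-only)."""
    return make_template_skull(3, params_clean)


@pytest.fixture(scope="session")
def small_template(template_skull):
    """Semilandmark template with reduced counts (280 SLMs)."""
    return build_template(template_skull.mesh, template_skull.landmarks,
                          counts=SMALL_COUNTS, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
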