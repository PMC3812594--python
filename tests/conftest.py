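import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ebis.pipeline import features_from_fits, fit_dataset
from ebis.simulate import GeneratorConfig, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic cohort (9 subjects, 720 spectra), fixed seed."""
    return generate_study(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_fits(default_study):
    """Conductance-domain Cole fits of every spectrum in the default cohort."""
    return fit_dataset(default_study.spectra)


@pytest.fixture(scope="session")
def default_vectors(default_fits):
    """Feature vectors (360) paired per hemisphere from the default cohort."""
    return features_from_fits(default_fits)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
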