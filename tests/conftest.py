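import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

from blastofold.geometry import EmbryoShape, GermBandSpec, initialize_tissue
from blastofold.dynamics import ModelParameters


@pytest.fixture(scope="session")
def shape():
    return EmbryoShape()


@pytest.fixture(scope="session")
def params():
    return ModelParameters(seed=0)


@pytest.fixture()
def tissue(shape):
    return initialize_tissue(shape, 100, GermBandSpec(0.0))


@pytest.fixture()
def random_tissue():
    """Small irregular configuration with nonzero preferred curvatures."""
    from blastofold.geometry import DiscretizedTissue
    rng = np.random.default_rng(42)
    base = np.linspace(0.0, 1.0, 12)[:, None] * np.array([1.0, 0.25])
    pos = base + rng.normal(scale=0.03, size=(12, 2))
    return DiscretizedTissue(
        positions=pos,
        rest_length=0.09,
        preferred_curvature=rng.normal(scale=0.5, size=12),
        L0=1.1,
    )
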