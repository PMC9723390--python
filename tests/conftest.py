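import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import osteonlo as o

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Fast 256x256 scene spec used by several suites."""
    return o.SceneSpec(image_height=256, image_width=256, n_fibres=300, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    stack, labels, truth = o.make_scene(small_spec, sample_id="s1", genotype="WT")
    return stack, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
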