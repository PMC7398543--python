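import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_phantom_cfg():
    from patchunet import PhantomConfig

    return PhantomConfig(canvas=64, n_slices=16, seed=7)


@pytest.fixture(scope="session")
def small_phantom_volume(small_phantom_cfg):
    from patchunet import generate_phantom_volume

    return generate_phantom_volume(small_phantom_cfg)


@pytest.fixture(scope="session")
def tiny_unet():
    """A small untrained network usable wherever weights don't matter."""
    from patchunet import ModelSpec, UNet

    return UNet(ModelSpec(patch_size=32, base_filters=4, depth=2), seed=0)
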