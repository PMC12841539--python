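import numpy as np
import pytest

from kernelseg.synthetic import SceneSpec, generate_scene


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def small_scene():
    """A modest adhered-kernel scene shared across tests."""
    spec = SceneSpec(
        image_width=800, image_height=600, n_kernels=15,
        adhesion_probability=0.5, damage_fraction=0.3, rng_seed=11,
    )
    image, gt = generate_scene(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
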