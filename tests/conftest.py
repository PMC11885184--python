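import numpy as np
import pytest

from cytoblob.synthetic import generate_scene, standard_scene_spec


@pytest.fixture(scope="session")
def standard_scene():
    """The default 20-cell synthetic field with its ground truth."""
    return generate_scene(standard_scene_spec())


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(1234))


def gaussian_spot_image(
    size: int = 101,
    center: tuple[float, float] = None,
    sigma: float = 4.0,
    depth: float = 0.6,
    background: float = 1.0,
) -> np.ndarray:
    """Bright field with one dark Gaussian spot (analytic ground truth)."""
    if center is None:
        center = (size // 2, size // 2)
    cy, cx = center
    yy, xx = np.mgrid[0:size, 0:size]
    img = background - depth * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
    )
    return np.clip(img, 0.0, 1.0)
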