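import numpy as np
import pytest

from respiro.core import BinaryMask
from respiro.phantom import generate_scene, render_brightfield
from respiro.preprocess import clahe, percentile_normalize


def disc_mask(side: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic phantom scene with a bubble, reused across tests."""
    scene, truth = generate_scene(
        n_organoids=5, size_range_px=(12, 22), n_bubbles=1, seed=42, canvas_side_px=256
    )
    return scene, truth


@pytest.fixture(scope="session")
def training_pairs():
    """Eight preprocessed 128 px phantom images with truth masks (desk scale)."""
    pairs = []
    for i in range(8):
        scene, truth = generate_scene(
            n_organoids=3, size_range_px=(10, 20), n_bubbles=1,
            seed=100 + i, canvas_side_px=128,
        )
        img = clahe(percentile_normalize(render_brightfield(scene)), 1.0, 32)
        pairs.append((img, truth.foreground))
    return pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_mask(rng, side=64, p=0.2) -> BinaryMask:
    return BinaryMask(rng.random((side, side)) < p)
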