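import numpy as np
import pytest

from vckulm import FrameStack, PhantomConfig, VesselSpec, generate_phantom


def gaussian_blob(shape, x, y, sigma=1.2, amplitude=10.0):
    """Frame with a single Gaussian blob at subpixel (x, y)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


@pytest.fixture
def blob():
    return gaussian_blob


@pytest.fixture(scope="session")
def straight_phantom():
    """Noise/clutter/motion-free phantom: one vertical vessel, 1 px/frame."""
    cfg = PhantomConfig(
        grid_shape=(64, 64), n_frames=60, frame_rate=440.0,
        vessels=[VesselSpec(centerline=[(32.0, 2.0), (32.0, 62.0)],
                            radius=1.5, flow_speed=1.0)],
        bubble_rate=0.06, psf_sigma=1.2, seed=7)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def tracking_phantom():
    """Multi-vessel phantom with noise for tracker comparisons (fixed seed)."""
    vessels = [
        VesselSpec(centerline=[(20.0 + 12 * k, 2.0), (20.0 + 12 * k, 126.0)],
                   radius=1.5, flow_speed=0.8 + 0.2 * k,
                   direction_sign=1 if k % 2 == 0 else -1)
        for k in range(5)
    ]
    cfg = PhantomConfig(grid_shape=(128, 128), n_frames=200, frame_rate=440.0,
                        vessels=vessels, bubble_rate=0.12, psf_sigma=1.2,
                        noise_sigma=0.25, seed=11)
    return generate_phantom(cfg)


@pytest.fixture
def textured_frame():
    from scipy import ndimage
    rng = np.random.default_rng(42)
    return ndimage.gaussian_filter(rng.normal(size=(80, 80)), 1.5) + 2.0
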