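import numpy as np
import pytest

from rootscan.imaging import BinaryMask, RasterImage
from rootscan.synthesis import SimulationConfig, render_image, simulate_architecture


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def quiet_config() -> SimulationConfig:
    """Render configuration with every noise source switched off."""
    return SimulationConfig(
        gradient_amplitude=0.0, texture_sd=0.0, speck_count=0, additive_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def reference_plant(default_config):
    """One deterministic simulated plant used across modules."""
    return simulate_architecture(default_config, genotype="g0", seed=3, plant_id="p0")


@pytest.fixture(scope="session")
def noisy_scene(reference_plant, default_config):
    """Default-noise colour render of the reference plant at 15 DAS."""
    img, truth_mask = render_image(reference_plant, 15.0, default_config, seed=3)
    return img, truth_mask


@pytest.fixture(scope="session")
def quiet_scene(reference_plant, quiet_config):
    """Noise-free grayscale render of the reference plant at 15 DAS."""
    img, truth_mask = render_image(reference_plant, 15.0, quiet_config, seed=3, color=False)
    return img, truth_mask


def rect_mask(h: int = 20, w: int = 40, dpi: float = 300.0, pad: int = 5) -> BinaryMask:
    px = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    px[pad : pad + h, pad : pad + w] = True
    return BinaryMask(px, dpi)


def image_from(arr, dpi: float = 300.0) -> RasterImage:
    return RasterImage(np.asarray(arr, dtype=float), dpi)
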