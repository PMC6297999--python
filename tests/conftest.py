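import numpy as np
import pytest

from seedhalo import Calibration, PlateSpec, generate_plate


def rasterize_disk(radius: int, pad: int = 5) -> np.ndarray:
    """Filled digital disk: pixel centers within `radius` of the middle."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (radius + pad)
    return (xx * xx + yy * yy) <= radius * radius


@pytest.fixture(scope="session")
def unit_cal() -> Calibration:
    return Calibration(pixels_per_mm=1.0)


@pytest.fixture(scope="session")
def clean_plate():
    """One deterministic noiseless diagonal plate with its ground truth."""
    spec = PlateSpec(n_seeds=6, rng_seed=7)
    image, truth = generate_plate(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def jittered_plate():
    spec = PlateSpec(n_seeds=8, sowing="jittered", rng_seed=11)
    image, truth = generate_plate(spec)
    return spec, image, truth
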