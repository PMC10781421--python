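import numpy as np
import pytest

from osteounit import phantoms
from osteounit.relaxation import LoadingProtocol


def make_grating(theta_deg: float, size: int = 256, period: float = 8.0,
                 contrast: float = 100.0) -> np.ndarray:
    """Sinusoidal grating whose stripes lie at ``theta_deg`` (0 deg = image
    x-axis, y-up math convention shared with the analyzers)."""
    row, col = np.mgrid[0:size, 0:size].astype(float)
    th = np.radians(theta_deg)
    phase = -np.sin(th) * col + np.cos(th) * (-row)
    return 128.0 + contrast * np.sin(2.0 * np.pi * phase / period)


@pytest.fixture(scope="session")
def protocol():
    return LoadingProtocol(sample_diameter_mm=6.4, sample_thickness_mm=1.7)


@pytest.fixture(scope="session")
def terrestrial_truth():
    return phantoms.relaxation_preset("terrestrial")


@pytest.fixture(scope="session")
def noiseless_curve(terrestrial_truth):
    curve, _ = phantoms.gen_relaxation_curve(truth=terrestrial_truth,
                                             noise_sd_kPa=0.0, seed=0)
    return curve


@pytest.fixture(scope="session")
def arcade_image():
    img, truth = phantoms.gen_orientation_image(
        (10.0, 40.0, 50.0), (0.0, 45.0, 90.0), concentration=8.0,
        size=512, seed=11)
    return img, truth


@pytest.fixture(scope="session")
def rod_volume():
    vol, truth = phantoms.gen_trabecular_volume(
        (96, 96, 96), kind="rods", strut_thickness_vox=6.0,
        target_bvtv_pct=30.0, seed=0)
    return vol, truth
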