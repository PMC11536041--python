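import numpy as np
import pytest

from acdkit.core import PixelCalibration


@pytest.fixture
def live_cal() -> PixelCalibration:
    """Spinning-disc live-imaging calibration: 130 nm px, 5 frames/s."""
    return PixelCalibration(pixel_size_um=0.13, frame_interval_s=0.2)


@pytest.fixture
def eb3_cal() -> PixelCalibration:
    """EB3 comet recording calibration: 130 nm px, 1.3 s/frame."""
    return PixelCalibration(pixel_size_um=0.13, frame_interval_s=1.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
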