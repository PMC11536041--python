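"""Shared calibrated containers used across analysis stages.

All physical geometry in this package is expressed in micrometres (µm)
unless a name says otherwise (MPS periodicity works in nanometres, nm).
Pixel indices are 0-based; the physical position of index ``i`` along a
line profile is ``i * pixel_size_um`` from the profile origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PixelCalibration", "LineProfile"]


@dataclass(frozen=True)
class PixelCalibration:
    """Physical calibration of an image or image series.

    Parameters
    ----------
    pixel_size_um
        Physical length of one pixel (µm/px). Typical values here:
        0.13 (spinning-disc live imaging), 0.065 (TIRF), 0.02 (STED).
    frame_interval_s
        Time between frames (s). ``None`` for still images.
    """

    pixel_size_um: float
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.frame_interval_s is not None and not (self.frame_interval_s > 0):
            raise ValueError(
                f"frame_interval_s must be > 0 when present, got {self.frame_interval_s}"
            )

    @property
    def pixel_size_nm(self) -> float:
        return self.pixel_size_um * 1000.0


@dataclass
class LineProfile:
    """Calibrated 1-D fluorescence intensity trace along a drawn line.

    ``intensities[0]`` sits at the anatomical anchor named by
    ``origin_label`` (by convention the start of the axon).
    """

    intensities: np.ndarray
    pixel_size_um: float
    origin_label: str = "axon_start"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("a line profile needs at least 2 ordered samples")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("profile intensities must all be finite")
        if np.any(self.intensities < 0):
            raise ValueError("profile intensities must be nonnegative")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")

    def __len__(self) -> int:
        return int(self.intensities.size)

    @property
    def pixel_size_nm(self) -> float:
        return self.pixel_size_um * 1000.0

    @property
    def extent_um(self) -> float:
        """Physical position of the last sample (µm)."""
        return (self.intensities.size - 1) * self.pixel_size_um

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.intensities.size) * self.pixel_size_um
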