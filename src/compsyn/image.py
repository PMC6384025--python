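"""Calibrated 2-D fluorescence rasters.

Every analysis stage operates on maximum-intensity projections represented as
a :class:`CalibratedImage`: a single-channel 2-D intensity raster together
with its physical pixel pitch in micrometres.  Coordinates are row-major,
0-based, origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalibratedImage"]


@dataclass(frozen=True)
class CalibratedImage:
    """One channel of a calibrated fluorescence scene.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite intensities.
    pixel_size_um
        Physical edge length of one pixel in micrometres (> 0).
    channel_name
        Free-form channel label, e.g. ``"vglut1"`` or ``"psd95gfp"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if np.min(px) < 0:
            raise ValueError("pixel intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm² (the quantum of all calibrated areas)."""
        return float(self.pixel_size_um) ** 2

    def field_area_um2(self) -> float:
        """Physical area of the full raster in µm²."""
        return self.pixels.size * self.pixel_area_um2

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Return a copy carrying the same calibration but new pixel data."""
        return CalibratedImage(pixels, self.pixel_size_um, self.channel_name)
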