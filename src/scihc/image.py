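"""Shared raster containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SlideImage:
    """An RGB raster for one staining round.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array, indexed [y, x].
    marker : name of the biomarker visualized in this round, or
        ``"hematoxylin"`` for the counterstain-only reference.
    mpp : microns per pixel (isotropic).
    """

    pixels: np.ndarray
    marker: str
    mpp: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlideImage expects an (H, W, 3) RGB array")
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def luminance(self) -> np.ndarray:
        """Rec. 601 luma as float64 in [0, 255]."""
        r, g, b = (self.pixels[..., i].astype(np.float64) for i in range(3))
        return 0.299 * r + 0.587 * g + 0.114 * b


def as_gray(image: "SlideImage | np.ndarray") -> np.ndarray:
    """Coerce a SlideImage or raw array to a 2-D float grayscale raster."""
    if isinstance(image, SlideImage):
        return image.luminance()
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        return 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return arr
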