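"""Shared containers and small IO helpers."""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import tifffile


@dataclasses.dataclass
class ImageField:
    """An RGB brightfield field with physical pixel size.

    Attributes
    ----------
    rgb:
        (H, W, 3) uint8 array.
    pixel_size_um:
        Physical edge length of one pixel in micrometres.
    field_id:
        Free-form identifier used in output tables.
    provenance:
        Dict recording how the field was produced (seed, config hash, ...).
    """

    rgb: np.ndarray
    pixel_size_um: float
    field_id: str = "field"
    provenance: Optional[dict] = None

    @property
    def shape(self):
        return self.rgb.shape[:2]

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um * 1e-3) ** 2


def write_image(path, array: np.ndarray) -> None:
    tifffile.imwrite(str(path), array)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


def mm2_of(mask: np.ndarray, pixel_size_um: float) -> float:
    """Area of a boolean mask in mm^2."""
    return float(np.count_nonzero(mask)) * (pixel_size_um * 1e-3) ** 2
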