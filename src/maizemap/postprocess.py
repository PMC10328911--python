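"""Map noise removal: cropland masking and minimum-mapping-unit despeckling.

A raw classifier map contains two kinds of noise the classifier cannot see:
positives on non-agricultural land, and isolated speckle from pixel-level
misclassification.  The pipeline fixes the order mask -> despeckle; the two
operations do not commute in general, and masking first means the speckle
filter also removes slivers the mask cuts off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classifier import NODATA_BYTE

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], int)

#: Which mask vintage serves each map year, following the production recipe:
#: the 2015 and 2019 cropland layers cover 2013-2015 and 2016-2019, the 2020
#: layer covers 2020-2021.
DEFAULT_MASK_SCHEDULE: dict[int, str] = {
    **{y: "mask_2015" for y in range(2013, 2016)},
    **{y: "mask_2019" for y in range(2016, 2020)},
    **{y: "mask_2020" for y in (2020, 2021)},
}


@dataclass(frozen=True)
class MaskSchedule:
    """Maps a map year to the provenance label of the cropland mask to use."""

    schedule: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_MASK_SCHEDULE))

    def mask_for_year(self, year: int) -> str:
        try:
            return self.schedule[year]
        except KeyError:
            raise KeyError(f"no cropland mask scheduled for map year {year}") from None


def apply_cropland_mask(maize_map: np.ndarray, mask: np.ndarray,
                        nodata: int = NODATA_BYTE) -> np.ndarray:
    """Zero out maize pixels outside cropland; nodata propagates unchanged."""
    maize_map = np.asarray(maize_map)
    mask = np.asarray(mask)
    if maize_map.shape != mask.shape:
        raise ValueError(f"map {maize_map.shape} and mask {mask.shape} grids differ")
    bad = np.setdiff1d(np.unique(mask), [0, 1])
    if bad.size:
        raise ValueError(f"cropland mask must be binary; found values {bad.tolist()}")
    out = np.where(mask == 1, maize_map, 0).astype(maize_map.dtype)
    out[maize_map == nodata] = nodata
    return out


def remove_speckle(maize_map: np.ndarray, min_patch_px: int = 4,
                   nodata: int = NODATA_BYTE) -> np.ndarray:
    """Drop 4-connected maize components smaller than ``min_patch_px``.

    A minimum-mapping-unit filter: with a 30 m pixel the default of 4 pixels
    corresponds to 0.36 ha.  ``min_patch_px = 1`` is the identity.
    """
    if min_patch_px < 1:
        raise ValueError("min_patch_px must be >= 1")
    maize_map = np.asarray(maize_map)
    out = maize_map.copy()
    if min_patch_px == 1:
        return out
    lab, n = ndimage.label(maize_map == 1, structure=FOUR_CONNECTED)
    if n == 0:
        return out
    sizes = np.bincount(lab.ravel())
    small = sizes < min_patch_px
    small[0] = False
    out[small[lab]] = 0
    return out
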