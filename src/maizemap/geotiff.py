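"""GeoTIFF-style raster I/O on a single local metric grid.

Rasters are written as tiled-less striped TIFFs carrying the three GeoTIFF
tags GDAL needs to georeference a north-up image on a projected grid:
``ModelPixelScale`` (33550), ``ModelTiepoint`` (33922) and ``GDAL_NODATA``
(42113).  Multi-band rasters are stored band-interleaved (one sample per
plane), band order is the caller's contract and additionally recorded in the
``ImageDescription`` tag as JSON.

The package works on a 30 m nominal grid with the origin at the raster's
upper-left corner; no CRS beyond that local metric frame is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

PIXEL_SIZE_M = 30.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GeoRef:
    """Upper-left origin (map units) and square pixel size in metres."""

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = PIXEL_SIZE_M


@dataclass
class Raster:
    """An in-memory raster: ``data`` is (H, W) or (bands, H, W)."""

    data: np.ndarray
    georef: GeoRef = field(default_factory=GeoRef)
    nodata: float | int | None = None
    band_names: tuple[str, ...] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]


class RasterFormatError(ValueError):
    """Raised when a raster on disk violates the package's conventions."""


def write_raster(path, raster: Raster) -> None:
    """Write ``raster`` to ``path`` with georeference and nodata tags."""
    data = np.asarray(raster.data)
    if data.ndim not in (2, 3):
        raise RasterFormatError(f"{path}: expected 2-D or 3-D array, got {data.ndim}-D")
    g = raster.georef
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.pixel_size, g.pixel_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
    ]
    if raster.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)))
    desc = json.dumps({"band_names": list(raster.band_names)}) if raster.band_names else None
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate" if data.ndim == 3 else None,
        description=desc,
        extratags=extratags,
    )


def read_raster(path) -> Raster:
    """Read a raster written by :func:`write_raster` (or compatible)."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = tif.asarray()
            tags = page.tags
            georef = GeoRef()
            if _TAG_PIXEL_SCALE in tags and _TAG_TIEPOINT in tags:
                scale = tags[_TAG_PIXEL_SCALE].value
                tie = tags[_TAG_TIEPOINT].value
                georef = GeoRef(origin_x=float(tie[3]), origin_y=float(tie[4]),
                                pixel_size=float(scale[0]))
            nodata = None
            if _TAG_GDAL_NODATA in tags:
                raw = tags[_TAG_GDAL_NODATA].value
                nodata = float(raw) if "." in str(raw) or "e" in str(raw) else int(raw)
            band_names = None
            if page.description:
                try:
                    meta = json.loads(page.description)
                    if isinstance(meta, dict) and "band_names" in meta:
                        band_names = tuple(meta["band_names"])
                except (json.JSONDecodeError, TypeError):
                    pass
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise RasterFormatError(f"cannot read raster {path}: {exc}") from exc
    return Raster(data=data, georef=georef, nodata=nodata, band_names=band_names)


def validate_binary_map(raster: Raster, path="<map>") -> None:
    """A published maize map holds only 1 (maize), 0 (non-maize) and nodata."""
    data = raster.data
    mask = np.ones(data.shape, bool)
    if raster.nodata is not None:
        mask = data != raster.nodata
    bad = np.setdiff1d(np.unique(data[mask]), [0, 1])
    if bad.size:
        raise RasterFormatError(
            f"{path}: maize map must contain only values 1 and 0 "
            f"(plus nodata); found {bad.tolist()}"
        )
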