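"""Minimal georeferenced raster container and GeoTIFF-compatible I/O.

All layers in a run share one grid: 30 m square pixels, row-major storage,
origin at the top-left corner.  Georeferencing (affine transform, CRS string,
nodata) rides along with the pixel array and survives a write/read round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

PIXEL_SIZE = 30.0
#: area of one 30 m pixel in hectares
PIXEL_HA = (PIXEL_SIZE * PIXEL_SIZE) / 10_000.0

_META_KEY = "potholescape_geo"


class RasterAlignmentError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass
class RasterGrid:
    """A single-band raster on a regular grid of square pixels.

    Parameters
    ----------
    data :
        2-D array, row-major, row 0 at the map top.
    pixel_size :
        Cell edge length in meters (square pixels only).
    origin :
        (x, y) map coordinate of the top-left corner of pixel (0, 0).
    crs :
        CRS identifier, passed through verbatim.
    nodata :
        Sentinel for missing cells, or None if the band is complete.
    """

    data: np.ndarray
    pixel_size: float = PIXEL_SIZE
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "EPSG:5070"
    nodata: float | int | None = None
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster must be 2-D, got shape {self.data.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    # -- grid bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_ha(self) -> float:
        return (self.pixel_size**2) / 10_000.0

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of observed (non-nodata) cells."""
        if self.nodata is None:
            if np.issubdtype(self.data.dtype, np.floating):
                return ~np.isnan(self.data)
            return np.ones(self.shape, dtype=bool)
        if np.issubdtype(self.data.dtype, np.floating) and np.isnan(self.nodata):
            return ~np.isnan(self.data)
        return self.data != self.nodata

    def like(self, data: np.ndarray, nodata=None, name: str = "") -> "RasterGrid":
        """New raster on this grid carrying ``data``."""
        if data.shape != self.shape:
            raise RasterAlignmentError(
                f"data shape {data.shape} does not match grid {self.shape}"
            )
        return replace(self, data=data, nodata=nodata, name=name)

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.pixel_size == other.pixel_size
            and self.origin == other.origin
            and self.crs == other.crs
        )

    def copy(self) -> "RasterGrid":
        return replace(self, data=self.data.copy())


def check_aligned(*rasters: RasterGrid, names: list[str] | None = None) -> None:
    """Raise :class:`RasterAlignmentError` naming the first offending layer."""
    if not rasters:
        return
    ref = rasters[0]
    for i, r in enumerate(rasters[1:], start=1):
        if not ref.same_grid(r):
            label = names[i] if names else (r.name or f"layer {i}")
            raise RasterAlignmentError(
                f"layer '{label}' (shape {r.shape}, pixel {r.pixel_size} m) is not "
                f"aligned with '{names[0] if names else ref.name or 'reference'}' "
                f"(shape {ref.shape}, pixel {ref.pixel_size} m)"
            )


# -- I/O -------------------------------------------------------------------


def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write a single-band TIFF; georeferencing is stored as a JSON tag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        _META_KEY: {
            "pixel_size": grid.pixel_size,
            "origin": list(grid.origin),
            "crs": grid.crs,
            "nodata": None if grid.nodata is None else float(grid.nodata),
            "name": grid.name,
        }
    }
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(path, data, description=json.dumps(meta))
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read a raster written by :func:`write_raster` (or any single-band TIFF)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = page.description or ""
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    meta = {}
    try:
        meta = json.loads(desc).get(_META_KEY, {})
    except (json.JSONDecodeError, AttributeError):
        pass
    nodata = meta.get("nodata")
    if nodata is not None and np.issubdtype(data.dtype, np.integer):
        nodata = int(nodata)
    return RasterGrid(
        data=data,
        pixel_size=float(meta.get("pixel_size", PIXEL_SIZE)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        crs=meta.get("crs", "EPSG:5070"),
        nodata=nodata,
        name=meta.get("name", path.stem),
    )
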