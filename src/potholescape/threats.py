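"""Threat-raster assembly: focal densities, inversions, wetland-area classes.

Six threats degrade waterbird habitat:

* ``crop`` — density of cropland within 1 km;
* ``corn`` — 1 − density of corn within 5 km (field-foraging dabblers only;
  corn residue is forage, so its *absence* is the threat);
* ``road`` — density of roads within 0.5 km;
* ``roost`` — 1 − density of roostable habitat within the group's typical
  stopover flight radius;
* ``wetarea`` — wetland-size classes for diving ducks (8-connected patches:
  > 4 ha no threat, 0.4–4 ha threat 0.5, < 0.4 ha threat 1.0);
* ``dry`` — the hydroperiod dryness raster (in place).

Focal densities use a circular window (cell centers within the radius),
normalized by the window cells that fall inside the grid so a constant
raster keeps its value at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from . import codebook as cb
from .codebook import GROUP_THREATS, GROUP_WINDOW, GROUPS, ROOST_RADIUS_M
from .hydro import HydroperiodRaster, WindowMismatchError
from .raster import PIXEL_HA, RasterGrid
from .scenarios import ScenarioMap

#: maximum decay distance of each proximity threat, meters (0 = in place)
THREAT_MAX_DIST_M = {"crop": 1_000.0, "corn": 5_000.0, "road": 500.0, "wetarea": 0.0, "dry": 0.0}


@dataclass
class BirdGroupSpec:
    """One modelled waterbird group: flight radius, seasonal window, threats."""

    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")

    @property
    def roost_radius(self) -> float:
        return ROOST_RADIUS_M[self.group]

    @property
    def window(self) -> str:
        return GROUP_WINDOW[self.group]

    @property
    def threats(self) -> tuple[str, ...]:
        return GROUP_THREATS[self.group]


@dataclass
class ThreatSpec:
    """One assembled threat layer with its weight and decay reach."""

    name: str
    weight: float
    max_dist: float  # meters; 0 = in-place (no spatial decay)
    raster: RasterGrid

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"threat weight must be nonnegative, got {self.weight}")
        data = self.raster.data
        valid = self.raster.valid_mask()
        if valid.any():
            vals = data[valid]
            if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
                raise ValueError(f"threat raster {self.name!r} not in [0, 1]")


# --------------------------------------------------------------------------
# focal statistics


def disk_kernel(radius_px: float) -> np.ndarray:
    """Binary circular window: cells whose centers lie within the radius."""
    half = int(np.floor(radius_px))
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    return (rr**2 + cc**2 <= radius_px**2).astype(np.float64)

def linear_decay_kernel(max_dist_m: float, pixel_size: float) -> np.ndarray:
    """Linear distance-decay weights 1 − d/max over d < max, unit sum."""
    radius_px = max_dist_m / pixel_size
    half = int(np.ceil(radius_px))
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    d = np.hypot(rr, cc) * pixel_size
    k = np.clip(1.0 - d / max_dist_m, 0.0, None)
    s = k.sum()
    if s <= 0:
        raise ValueError(f"decay distance {max_dist_m} m collapses below one pixel")
    return k / s


def _convolve(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Symmetric-kernel convolution; direct for small problems (exact),
    FFT otherwise."""
    if values.size * kernel.size <= 4e7:
        return ndimage.convolve(values, kernel, mode="constant", cval=0.0)
    return signal.fftconvolve(values, kernel, mode="same")


def edge_normalized_mean(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Weighted window mean of ``values``, renormalized by the kernel mass
    that falls inside the grid (no padding bias at edges)."""
    num = _convolve(values.astype(np.float64), kernel)
    den = _convolve(np.ones_like(values, dtype=np.float64), kernel)
    return num / den


def focal_density(binary: RasterGrid, radius_m: float) -> RasterGrid:
    """Fraction of cells within the circular window that are 1."""
    if radius_m < binary.pixel_size:
        raise ValueError(
            f"focal radius {radius_m} m is smaller than one {binary.pixel_size} m pixel"
        )
    kernel = disk_kernel(radius_m / binary.pixel_size)
    dens = edge_normalized_mean((binary.data != 0).astype(np.float64), kernel)
    return binary.like(np.clip(dens, 0.0, 1.0), name=f"density_r{int(radius_m)}")


def invert(raster: RasterGrid) -> RasterGrid:
    """1 − value; nodata (NaN) preserved."""
    data = raster.data.astype(np.float64)
    valid = raster.valid_mask()
    if valid.any():
        vals = data[valid]
        if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
            raise ValueError("invert expects values in [0, 1]")
    out = np.where(valid, 1.0 - data, np.nan)
    return raster.like(out, nodata=np.nan, name=f"inv_{raster.name}")


# --------------------------------------------------------------------------
# per-threat source rasters


def wetland_area_threat(lulc: ScenarioMap) -> RasterGrid:
    """Size-class threat on 8-connected wetland components.

    area > 4 ha → 0; 0.4 ha ≤ area ≤ 4 ha → 0.5; area < 0.4 ha → 1.0;
    non-wetland pixels 0.
    """
    wet = np.isin(lulc.lulc.data, cb.WETLAND_CLASSES)
    labels, n = ndimage.label(wet, structure=np.ones((3, 3), dtype=int))
    out = np.zeros(lulc.lulc.shape, dtype=np.float64)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        areas_ha = sizes * lulc.lulc.pixel_area_ha
        threat = np.where(areas_ha > 4.0, 0.0, np.where(areas_ha >= 0.4, 0.5, 1.0))
        out[wet] = threat[labels[wet] - 1]
    return lulc.lulc.like(out, name="wetarea")


def roost_mask(lulc: ScenarioMap, group: BirdGroupSpec, codebook: cb.Codebook) -> RasterGrid:
    """1 where the class is suitable habitat and not an ephemeral
    depressional class."""
    out = np.zeros(lulc.lulc.shape, dtype=np.uint8)
    for code in np.unique(lulc.lulc.data):
        if codebook.is_roost(int(code), group.group):
            out[lulc.lulc.data == code] = 1
    return lulc.lulc.like(out, name=f"roost_{group.group}")


def assemble_threats(
    scenario: ScenarioMap,
    group: BirdGroupSpec,
    dry: HydroperiodRaster,
    weights: dict[str, float],
    codebook: cb.Codebook | None = None,
    dry_fill: float = 1.0,
) -> list[ThreatSpec]:
    """Build every threat applicable to the group, tagged with its weight.

    ``dry`` pixels that were never observed cloud-free carry no dryness
    estimate; they are filled with ``dry_fill`` here (maximally dry) and the
    post-model activity filter handles their removal where requested.
    """
    codebook = codebook or cb.default_codebook()
    if dry.window != group.window:
        raise WindowMismatchError(
            f"dry raster window {dry.window!r} does not match group window "
            f"{group.window!r} for {group.group}"
        )
    missing = [t for t in group.threats if t not in weights]
    if missing:
        raise ValueError(f"missing weights for threats {missing} ({group.group})")

    lulc = scenario.lulc
    out: list[ThreatSpec] = []

    def add(name: str, raster: RasterGrid, max_dist: float) -> None:
        out.append(ThreatSpec(name=name, weight=float(weights[name]), max_dist=max_dist, raster=raster))

    dry_data = np.where(np.isnan(dry.dry.data), dry_fill, dry.dry.data)
    add("dry", lulc.like(dry_data, name="dry"), 0.0)

    crop_bin = lulc.like(np.isin(lulc.data, cb.CROPLAND_CLASSES).astype(np.uint8))
    add("crop", focal_density(crop_bin, THREAT_MAX_DIST_M["crop"]), THREAT_MAX_DIST_M["crop"])

    add(
        "roost",
        invert(focal_density(roost_mask(scenario, group, codebook), group.roost_radius)),
        group.roost_radius,
    )

    road_bin = lulc.like((lulc.data == cb.ROAD).astype(np.uint8))
    add("road", focal_density(road_bin, THREAT_MAX_DIST_M["road"]), THREAT_MAX_DIST_M["road"])

    if "corn" in group.threats:
        corn_bin = lulc.like(np.isin(lulc.data, cb.CORN_CLASSES).astype(np.uint8))
        add("corn", invert(focal_density(corn_bin, THREAT_MAX_DIST_M["corn"])), THREAT_MAX_DIST_M["corn"])

    if "wetarea" in group.threats:
        add("wetarea", wetland_area_threat(scenario), 0.0)

    return out
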