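"""Seeded synthetic prairie-pothole watersheds.

Generates crop-dominated land-cover mosaics with embedded drained
depressions, sparse semipermanent wetlands, a section-road grid, and a
candidate water-quality-wetland footprint, plus multi-year stacks of
classified surface-water scenes — everything the downstream scenario /
hydroperiod / habitat-quality stages consume, with the statistical
structure the analysis assumes:

* depression areas follow a log-normal law anchored to the published
  inventory quantiles (min 0.04 ha, median 0.47 ha, max 50.15 ha);
* the water-quality wetland pool occupies a configurable fraction of
  watershed area (the study catchments span 0.4–6.4%);
* per-depression ponding is an annual Bernoulli event with a per-patch
  probability (defaults span the 14–47% ponding frequencies reported for
  drained Des Moines Lobe depressions), and the ponded area within a patch
  is nested by a depth-rank ordering (distance to patch edge), so wetter
  realizations always contain drier ones.

All randomness flows from a single integer seed; two runs with the same
config are bit-identical.
"""

from __future__ import annotations

import datetime as _dt
import importlib.resources
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import codebook as cb
from .hydro import DsweScene
from .raster import PIXEL_HA, PIXEL_SIZE, RasterGrid, write_raster


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of one synthetic watershed."""

    grid_rows: int = 200
    grid_cols: int = 200
    pixel_size: float = PIXEL_SIZE
    n_depressions: int = 60
    depression_area_range: tuple[float, float] = (0.04, 50.15)  # ha
    depression_area_median: float = 0.47  # ha
    crop_fraction: float = 0.85
    corn_vs_soy_split: float = 0.55
    n_nwi_wetlands: int = 4
    road_spacing: float = 1_600.0  # m, section-road default
    wq_wetland_fraction: float = 0.017  # pool : watershed area
    easement_buffer: float = 90.0  # m
    watershed_area_ha: float | None = None  # None -> full grid
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size != PIXEL_SIZE:
            raise ValueError("the analysis is defined on 30 m pixels")
        lo, hi = self.depression_area_range
        if not (lo < self.depression_area_median < hi):
            raise ValueError("depression area range must bracket the median")
        for name in ("crop_fraction", "corn_vs_soy_split", "wq_wetland_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_depressions < 0 or self.n_nwi_wetlands < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def grid_area_ha(self) -> float:
        return self.grid_rows * self.grid_cols * PIXEL_HA


@dataclass
class SyntheticWatershed:
    """All layers of one generated watershed, on a shared grid."""

    config: LandscapeConfig
    lulc: RasterGrid  # crop base: crop classes / grassland / developed / road
    depressions: RasterGrid  # labeled patches, 0 = background
    depression_records: pd.DataFrame  # id, n_pixels, area_ha, majority_class
    nwi_wetlands: RasterGrid  # labeled patches
    nwi_records: pd.DataFrame  # id, n_pixels, area_ha, regime
    roads: RasterGrid  # binary
    watershed_mask: RasterGrid  # binary
    wq_footprint: RasterGrid  # binary pool
    wq_easement: RasterGrid  # binary ring, disjoint from the pool

    def depression_majority(self) -> dict[int, int]:
        return dict(
            zip(self.depression_records["id"], self.depression_records["majority_class"])
        )

    def write(self, outdir: str | Path) -> Path:
        """Write all layers (TIFF), patch tables (CSV) and footprints (GeoJSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "lulc",
            "depressions",
            "nwi_wetlands",
            "roads",
            "watershed_mask",
            "wq_footprint",
            "wq_easement",
        ):
            write_raster(getattr(self, name), outdir / f"{name}.tif")
        self.depression_records.to_csv(outdir / "depressions.csv", index=False)
        self.nwi_records.to_csv(outdir / "nwi_wetlands.csv", index=False)
        (outdir / "wq_footprint.geojson").write_text(
            json.dumps(_footprint_geojson(self.wq_footprint), indent=1)
        )
        return outdir


def _footprint_geojson(footprint: RasterGrid) -> dict:
    """Pixel-outline polygons of a binary footprint raster."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    px = footprint.pixel_size
    x0, y0 = footprint.origin
    cells = [
        box(x0 + c * px, y0 - (r + 1) * px, x0 + (c + 1) * px, y0 - r * px)
        for r, c in zip(*np.nonzero(footprint.data))
    ]
    geom = unary_union(cells) if cells else None
    features = []
    if geom is not None and not geom.is_empty:
        features.append({"type": "Feature", "properties": {}, "geometry": mapping(geom)})
    return {"type": "FeatureCollection", "features": features}


# --------------------------------------------------------------------------
# landscape generation


def _lognormal_params(lo: float, med: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matched to the median, spread set so the
    stated extremes sit near ±3 sigma of log-area."""
    mu = math.log(med)
    sigma = max(math.log(hi / med), math.log(med / lo)) / 3.0
    return mu, sigma


def _sample_areas_ha(config: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.depression_area_range
    mu, sigma = _lognormal_params(lo, config.depression_area_median, hi)
    areas = np.exp(rng.normal(mu, sigma, size=config.n_depressions))
    return np.clip(areas, lo, hi)


def _ellipse_cells(
    shape: tuple[int, int],
    center: tuple[float, float],
    area_px: float,
    aspect: float,
    theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of an ellipse of ~area_px pixels, clipped to the grid."""
    a = math.sqrt(max(area_px, 1.0) / (math.pi * aspect))
    b = a * aspect
    r0, c0 = center
    half = int(math.ceil(max(a, b))) + 1
    rlo, rhi = max(0, int(r0) - half), min(shape[0], int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(shape[1], int(c0) + half + 1)
    if rlo >= rhi or clo >= chi:
        return np.array([], dtype=int), np.array([], dtype=int)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _build_watershed_mask(config: LandscapeConfig) -> np.ndarray:
    """Full grid, or a centered disc of exactly round(area/0.09) pixels."""
    shape = (config.grid_rows, config.grid_cols)
    if config.watershed_area_ha is None:
        return np.ones(shape, dtype=bool)
    n_target = int(round(config.watershed_area_ha / PIXEL_HA))
    if n_target > shape[0] * shape[1]:
        raise ValueError(
            f"watershed_area_ha {config.watershed_area_ha} needs {n_target} pixels "
            f"but the grid has only {shape[0] * shape[1]}"
        )
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    order = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
    mask = np.zeros(shape[0] * shape[1], dtype=bool)
    mask[order[:n_target]] = True
    return mask.reshape(shape)


def _build_crop_base(config: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Blocky field mosaic: crop (corn/soy/other) vs grassland/developed."""
    shape = (config.grid_rows, config.grid_cols)
    block = 13  # ~400 m fields
    nbr = math.ceil(shape[0] / block)
    nbc = math.ceil(shape[1] / block)
    is_crop = rng.random((nbr, nbc)) < config.crop_fraction
    crop_kind = rng.random((nbr, nbc))
    # 90% of cropland is corn/soy (split per config), remainder other crops
    codes = np.where(
        crop_kind < 0.9 * config.corn_vs_soy_split,
        cb.CORN,
        np.where(crop_kind < 0.9, cb.SOY, cb.OTHER_CROP),
    )
    noncrop = np.where(rng.random((nbr, nbc)) < 0.12, cb.DEVELOPED, cb.GRASSLAND)
    blocks = np.where(is_crop, codes, noncrop)
    full = np.repeat(np.repeat(blocks, block, axis=0), block, axis=1)
    return full[: shape[0], : shape[1]].astype(np.int16)


def _build_roads(config: LandscapeConfig) -> np.ndarray:
    shape = (config.grid_rows, config.grid_cols)
    roads = np.zeros(shape, dtype=np.uint8)
    step = max(2, int(round(config.road_spacing / config.pixel_size)))
    roads[::step, :] = 1
    roads[:, ::step] = 1
    return roads


def _place_patches(
    available: np.ndarray,
    areas_ha: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 40,
) -> tuple[np.ndarray, list[int]]:
    """Drop elliptical patches onto available cells; returns labels + placed ids.

    Cells already taken or unavailable are clipped out of each ellipse, so
    patches never overlap and stay inside the allowed support.
    """
    shape = available.shape
    labels = np.zeros(shape, dtype=np.int32)
    free = available.copy()
    placed: list[int] = []
    next_id = 1
    for area_ha in areas_ha:
        area_px = max(1.0, area_ha / PIXEL_HA)
        got = False
        for _ in range(max_tries):
            r0 = rng.uniform(0, shape[0])
            c0 = rng.uniform(0, shape[1])
            aspect = rng.uniform(0.4, 1.0)
            theta = rng.uniform(0, math.pi)
            rr, cc = _ellipse_cells(shape, (r0, c0), area_px, aspect, theta)
            if rr.size == 0:
                continue
            keep = free[rr, cc]
            if keep.sum() == 0:
                continue
            # require at least ~40% of the target footprint to land
            if keep.sum() < 0.4 * min(area_px, rr.size) and keep.sum() < area_px:
                continue
            labels[rr[keep], cc[keep]] = next_id
            free[rr[keep], cc[keep]] = False
            placed.append(next_id)
            next_id += 1
            got = True
            break
        if not got:
            # fall back: single free cell keeps the patch count honest
            idx = np.nonzero(free)
            if idx[0].size == 0:
                raise ValueError(
                    "no room left to place patches: requested patch area exceeds "
                    "the available land area"
                )
            j = rng.integers(idx[0].size)
            labels[idx[0][j], idx[1][j]] = next_id
            free[idx[0][j], idx[1][j]] = False
            placed.append(next_id)
            next_id += 1
    return labels, placed


def generate_landscape(config: LandscapeConfig) -> SyntheticWatershed:
    """Generate one synthetic watershed; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    grid = RasterGrid(np.zeros(shape, dtype=np.int16), pixel_size=config.pixel_size)

    mask = _build_watershed_mask(config)
    crop_base = _build_crop_base(config, rng)
    roads = _build_roads(config)

    # depressions live on cropland inside the watershed, off roads
    dep_areas = _sample_areas_ha(config, rng)
    cropland = np.isin(crop_base, cb.CROP_CLASSES) & mask & (roads == 0)
    if dep_areas.sum() > cropland.sum() * PIXEL_HA:
        raise ValueError(
            f"requested depression area {dep_areas.sum():.1f} ha exceeds cropland "
            f"area {cropland.sum() * PIXEL_HA:.1f} ha"
        )
    if config.n_depressions > 0:
        dep_labels, _ = _place_patches(cropland, dep_areas, rng)
    else:
        dep_labels = np.zeros(shape, dtype=np.int32)

    dep_rows = []
    for pid in range(1, dep_labels.max() + 1):
        cells = dep_labels == pid
        under = crop_base[cells]
        counts = {c: int((under == c).sum()) for c in cb.CROP_CLASSES}
        majority = min(
            (c for c in cb.CROP_CLASSES if counts[c] == max(counts.values()))
        )
        dep_rows.append(
            {
                "id": pid,
                "n_pixels": int(cells.sum()),
                "area_ha": float(cells.sum() * PIXEL_HA),
                "majority_class": majority,
            }
        )
    dep_records = pd.DataFrame(
        dep_rows, columns=["id", "n_pixels", "area_ha", "majority_class"]
    )

    # sparse NWI wetlands; ~1 in 5 lacustrine, the rest semipermanent
    nwi_avail = mask & (roads == 0) & (dep_labels == 0)
    if config.n_nwi_wetlands > 0:
        nwi_areas = np.clip(
            np.exp(rng.normal(math.log(2.0), 0.8, size=config.n_nwi_wetlands)), 0.2, 30.0
        )
        nwi_labels, nwi_ids = _place_patches(nwi_avail, nwi_areas, rng)
        regimes = [
            "lacustrine" if rng.random() < 0.2 else "semipermanent" for _ in nwi_ids
        ]
    else:
        nwi_labels, nwi_ids, regimes = np.zeros(shape, dtype=np.int32), [], []
    nwi_rows = [
        {
            "id": pid,
            "n_pixels": int((nwi_labels == pid).sum()),
            "area_ha": float((nwi_labels == pid).sum() * PIXEL_HA),
            "regime": regime,
        }
        for pid, regime in zip(nwi_ids, regimes)
    ]
    nwi_records = pd.DataFrame(nwi_rows, columns=["id", "n_pixels", "area_ha", "regime"])

    # water-quality wetland pool near the watershed "outlet" (lower third),
    # surrounded by a disjoint easement ring
    wq = np.zeros(shape, dtype=np.uint8)
    easement = np.zeros(shape, dtype=np.uint8)
    pool_px = int(round(config.wq_wetland_fraction * mask.sum()))
    if pool_px > 0:
        placed = False
        for _ in range(60):
            r0 = rng.uniform(0.6 * shape[0], 0.95 * shape[0])
            c0 = rng.uniform(0.2 * shape[1], 0.8 * shape[1])
            rr, cc = _ellipse_cells(
                shape, (r0, c0), pool_px, rng.uniform(0.5, 0.9), rng.uniform(0, math.pi)
            )
            if rr.size == 0:
                continue
            ok = mask[rr, cc] & (nwi_labels[rr, cc] == 0)
            if ok.sum() >= 0.8 * pool_px:
                wq[rr[ok], cc[ok]] = 1
                placed = True
                break
        if not placed:  # deterministic fallback: centered block in the lower half
            side = max(1, int(math.sqrt(pool_px)))
            r0 = int(0.7 * shape[0])
            c0 = shape[1] // 2
            wq[r0 : r0 + side, c0 : c0 + side] = 1
            wq &= mask.astype(np.uint8)
        buf_px = max(1, int(round(config.easement_buffer / config.pixel_size)))
        dist = ndimage.distance_transform_edt(wq == 0)
        easement = ((dist <= buf_px) & (wq == 0) & mask).astype(np.uint8)

    return SyntheticWatershed(
        config=config,
        lulc=grid.like(crop_base, name="crop_base"),
        depressions=grid.like(dep_labels, name="depressions"),
        depression_records=dep_records,
        nwi_wetlands=grid.like(nwi_labels, name="nwi_wetlands"),
        nwi_records=nwi_records,
        roads=grid.like(roads, name="roads"),
        watershed_mask=grid.like(mask.astype(np.uint8), name="watershed_mask"),
        wq_footprint=grid.like(wq, name="wq_footprint"),
        wq_easement=grid.like(easement, name="wq_easement"),
    )


# --------------------------------------------------------------------------
# ponding and surface-water scenes


@dataclass
class PondingModel:
    """Annual ponding behaviour of depressions and wetlands.

    ``ponding_prob`` maps depression patch id -> probability the patch
    ponds at all in a given spring; semipermanent wetlands hold water
    almost every year (``wetland_prob``).  Within a ponding patch, wet
    cells are the deepest ``fraction`` of cells by distance-to-edge rank,
    so wet extents are nested across realizations.
    """

    ponding_prob: dict[int, float]
    wetland_prob: float = 0.95
    cloud_prob: float = 0.3
    acquisitions_per_window: int = 3
    years: list[int] = field(default_factory=lambda: list(range(2013, 2020)))
    wet_fraction_range: tuple[float, float] = (0.4, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("at least one year is required")
        if self.acquisitions_per_window < 1:
            raise ValueError("at least one acquisition per window is required")
        for p in list(self.ponding_prob.values()) + [self.wetland_prob, self.cloud_prob]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    @classmethod
    def from_watershed(
        cls,
        watershed: SyntheticWatershed,
        seed: int = 0,
        prob_range: tuple[float, float] = (0.14, 0.47),
        **kwargs,
    ) -> "PondingModel":
        """Per-depression probabilities drawn uniformly over ``prob_range``,
        the span of published ponding-frequency estimates for drained
        depressions in this landscape."""
        rng = np.random.default_rng(seed)
        ids = list(watershed.depression_records["id"])
        probs = {int(i): float(rng.uniform(*prob_range)) for i in ids}
        return cls(ponding_prob=probs, seed=seed, **kwargs)


def _depth_rank(labels: np.ndarray) -> np.ndarray:
    """Per-cell depth ordering within each patch: higher = deeper (more
    interior), from Euclidean distance to the patch edge with a stable
    deterministic tie-break."""
    dist = ndimage.distance_transform_edt(labels > 0)
    rows, cols = np.indices(labels.shape)
    # tie-break on (row, col) keeps the ordering unique and reproducible
    return dist + 1e-6 * (rows * labels.shape[1] + cols) / (labels.size + 1.0)


def generate_dswe_series(
    watershed: SyntheticWatershed, model: PondingModel
) -> list[DsweScene]:
    """Classified surface-water scene stack over the model years.

    Scenes are dated through March–May of each year so the March–April and
    April–May windows each capture ``acquisitions_per_window`` scenes (the
    April overlap serves both).  Water codes appear only inside depression
    or wetland patches; an annual wet/dry state per patch drives nested
    per-scene wet extents; block-shaped cloud masks remove observations.
    """
    rng = np.random.default_rng(model.seed + 1)
    dep = watershed.depressions.data
    nwi = watershed.nwi_wetlands.data
    shape = dep.shape
    grid = watershed.depressions

    dep_rank = _depth_rank(dep)
    nwi_rank = _depth_rank(nwi)

    dep_ids = [int(i) for i in np.unique(dep) if i > 0]
    nwi_ids = [int(i) for i in np.unique(nwi) if i > 0]

    # annual wet state per patch (shared across both seasonal windows)
    wet_state = {
        ("dep", i, y): rng.random() < model.ponding_prob.get(i, 0.0)
        for i in dep_ids
        for y in model.years
    }
    wet_state.update(
        {
            ("nwi", i, y): rng.random() < model.wetland_prob
            for i in nwi_ids
            for y in model.years
        }
    )

    # acquisition days: spread per window, Mar-Apr then Apr-May
    day_ranges = {"mar_apr": (60, 120), "apr_may": (91, 151)}
    scenes: list[DsweScene] = []
    for year in model.years:
        days: list[int] = []
        for window in ("mar_apr", "apr_may"):
            lo, hi = day_ranges[window]
            days.extend(
                sorted(rng.choice(np.arange(lo, hi), size=model.acquisitions_per_window, replace=False))
            )
        for day in days:
            date = _dt.date(year, 1, 1) + _dt.timedelta(days=int(day) - 1)
            codes = np.zeros(shape, dtype=np.int16)
            for kind, labels, rank, ids in (
                ("dep", dep, dep_rank, dep_ids),
                ("nwi", nwi, nwi_rank, nwi_ids),
            ):
                for pid in ids:
                    if not wet_state[(kind, pid, year)]:
                        continue
                    cells = labels == pid
                    n = int(cells.sum())
                    frac = rng.uniform(*model.wet_fraction_range)
                    n_wet = max(1, int(round(frac * n)))
                    r = rank[cells]
                    order = np.argsort(-r)  # deepest first
                    wet_local = np.zeros(n, dtype=bool)
                    wet_local[order[:n_wet]] = True
                    # deepest 70% open water, shallow margin partial water
                    core = np.zeros(n, dtype=bool)
                    core[order[: max(1, int(round(0.7 * n_wet)))]] = True
                    vals = np.zeros(n, dtype=np.int16)
                    vals[wet_local & core] = 1
                    vals[wet_local & ~core] = 3
                    # occasional moderate-confidence speckle in the core
                    mod = rng.random(n) < 0.15
                    vals[wet_local & core & mod] = 2
                    codes[cells] = vals
            # sparse low-confidence detections (code 4, not water) on wet margins
            margin = (codes == 3) & (rng.random(shape) < 0.1)
            codes[margin] = 4

            # block cloud mask with per-scene cover around model.cloud_prob
            block = 10
            nbr = math.ceil(shape[0] / block)
            nbc = math.ceil(shape[1] / block)
            cover = rng.uniform(0.0, 2 * model.cloud_prob)
            cloud_blocks = rng.random((nbr, nbc)) < cover
            cloud = np.repeat(np.repeat(cloud_blocks, block, axis=0), block, axis=1)
            cloud = cloud[: shape[0], : shape[1]].astype(np.uint8)

            scenes.append(
                DsweScene(
                    date=date,
                    codes=grid.like(codes, name=f"dswe_{date.isoformat()}"),
                    cloud=grid.like(cloud, name=f"cloud_{date.isoformat()}"),
                )
            )
    return scenes


# --------------------------------------------------------------------------
# published catchment presets


def load_preset_table() -> pd.DataFrame:
    """The packaged table of the 37 study catchments."""
    ref = importlib.resources.files("potholescape.data") / "watershed_presets.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def table1_preset(catchment_id: int, seed: int = 0) -> LandscapeConfig:
    """Config matching one published catchment row: watershed area,
    water-quality-wetland fraction, crop fraction and depression load."""
    table = load_preset_table()
    row = table[table["catchment_id"] == catchment_id]
    if row.empty:
        raise ValueError(f"catchment_id must be in 1..37, got {catchment_id}")
    row = row.iloc[0]
    area_ha = float(row["watershed_area_ha"])
    n_px = area_ha / PIXEL_HA
    side = int(math.ceil(math.sqrt(n_px) * 1.15))  # margin so the disc mask fits
    dep_area_ha = float(row["total_depressional_area_pct"]) / 100.0 * area_ha
    n_dep = int(round(dep_area_ha / 0.47))  # median-sized depressions
    crop_frac = min(
        1.0,
        (
            float(row["non_depressional_corn_soy_pct"])
            + float(row["total_depressional_area_pct"])
        )
        / 100.0
        + 0.02,  # headroom so depressions always find cropland
    )
    n_nwi = max(1, int(round(float(row["existing_wetland_area_pct"]) / 100.0 * area_ha / 2.0)))
    return LandscapeConfig(
        grid_rows=side,
        grid_cols=side,
        n_depressions=n_dep,
        crop_fraction=crop_frac,
        n_nwi_wetlands=n_nwi,
        wq_wetland_fraction=float(row["wq_wetland_watershed_pct"]) / 100.0,
        watershed_area_ha=area_ha,
        seed=seed,
        label=f"catchment_{catchment_id}",
    )


def fixture_config(seed: int = 42) -> LandscapeConfig:
    """The shipped 200×200 (360 ha) reference landscape used in examples
    and qualitative checks."""
    return LandscapeConfig(
        grid_rows=200,
        grid_cols=200,
        n_depressions=60,
        crop_fraction=0.85,
        n_nwi_wetlands=4,
        wq_wetland_fraction=0.017,
        seed=seed,
        label="fixture",
    )
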