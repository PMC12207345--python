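"""Scenario land-cover construction: overlay and conversion rules.

Four management scenarios are built from a watershed's layers:

``baseline``
    Crop base mosaic, then depressional crop classes, then NWI wetlands
    (which may override depressions), then the 30 m interior littoral edge
    of lacustrine patches, then roads on top.
``drain_mod``
    Drainage modernization: every depression — including any wetland cover
    inside it — collapses to the depression's majority non-depressional
    crop class (complete loss of depressional aquatic resources).
``wqw``
    A constructed water-quality wetland: pool and easement-buffer classes
    stamped over the baseline; optionally a one-pixel interior shoreline
    ring (the shallow, shorebird-accessible margin).
``drain_mod_wqw``
    Both edits, drainage first.

Rings ("interior negative buffer of 30 m") are computed by binary erosion
with a 4-connected structuring element, so the ring is exactly one pixel
wide on axis-aligned shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import codebook as cb
from .raster import RasterGrid, check_aligned
from .synthetic import SyntheticWatershed

SCENARIOS = ("baseline", "drain_mod", "wqw", "drain_mod_wqw")

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class ScenarioMap:
    """One scenario's land-cover map plus the overlay steps that built it."""

    lulc: RasterGrid
    scenario: str
    shoreline_enabled: bool = False
    provenance: list[str] = field(default_factory=list)

    def with_step(self, lulc: RasterGrid, scenario: str, step: str) -> "ScenarioMap":
        return ScenarioMap(
            lulc=lulc,
            scenario=scenario,
            shoreline_enabled=self.shoreline_enabled,
            provenance=self.provenance + [step],
        )


def interior_ring(mask: np.ndarray, width_px: int = 1) -> np.ndarray:
    """One-or-more-pixel interior ring: mask minus its 4-connected erosion."""
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, iterations=width_px)
    return mask & ~eroded


def majority_lulc(patch_mask: np.ndarray, crop_base: np.ndarray) -> int:
    """Majority non-depressional crop class over a patch; ties go to the
    lowest class code."""
    if not patch_mask.any():
        raise ValueError("empty patch has no majority class")
    under = crop_base[patch_mask]
    counts = {c: int((under == c).sum()) for c in cb.CROP_CLASSES}
    best = max(counts.values())
    if best == 0:
        raise ValueError("patch does not overlap any crop class")
    return min(c for c, n in counts.items() if n == best)


def build_baseline(watershed: SyntheticWatershed) -> ScenarioMap:
    """Mosaic order (later overrides earlier): crop base → depressional
    classes → NWI wetlands → lacustrine interior edge → roads."""
    layers = [
        watershed.lulc,
        watershed.depressions,
        watershed.nwi_wetlands,
        watershed.roads,
    ]
    check_aligned(*layers, names=["crop_base", "depressions", "nwi_wetlands", "roads"])

    out = watershed.lulc.data.astype(np.int16).copy()

    dep = watershed.depressions.data
    majority = watershed.depression_majority()
    for pid, crop_class in majority.items():
        out[dep == pid] = cb.DEPRESSIONAL_OF[crop_class]

    nwi = watershed.nwi_wetlands.data
    regime = dict(zip(watershed.nwi_records["id"], watershed.nwi_records["regime"]))
    for pid, reg in regime.items():
        code = cb.LACUSTRINE if reg == "lacustrine" else cb.NWI_SEMIPERM
        out[nwi == pid] = code

    # 30 m interior littoral edge of lacustrine patches
    lac = out == cb.LACUSTRINE
    if lac.any():
        out[interior_ring(lac)] = cb.LACUSTRINE_EDGE

    out[watershed.roads.data != 0] = cb.ROAD

    return ScenarioMap(
        lulc=watershed.lulc.like(out, name="lulc_baseline"),
        scenario="baseline",
        provenance=["crop_base", "depressions", "nwi_wetlands", "lacustrine_edge", "roads"],
    )


def apply_drainage_modernization(
    base: ScenarioMap, watershed: SyntheticWatershed
) -> ScenarioMap:
    """Convert every depression pixel — wetland cover included — to the
    depression's majority crop class; nothing outside depressions changes."""
    dep = watershed.depressions.data
    out = base.lulc.data.copy()
    majority = watershed.depression_majority()
    for pid in (int(i) for i in np.unique(dep) if i > 0):
        cells = dep == pid
        if pid in majority:
            crop_class = majority[pid]
        else:
            crop_class = majority_lulc(cells, watershed.lulc.data)
        out[cells] = crop_class
    scenario = "drain_mod" if base.scenario == "baseline" else "drain_mod_wqw"
    return base.with_step(
        base.lulc.like(out, name=f"lulc_{scenario}"), scenario, "drainage_modernization"
    )


def add_wq_wetland(
    base: ScenarioMap,
    footprint: RasterGrid,
    easement: RasterGrid,
    shoreline_enabled: bool = True,
) -> ScenarioMap:
    """Stamp the water-quality wetland pool, its easement buffer, and
    (optionally) the one-pixel interior shoreline ring over the map.

    The constructed wetland replaces whatever cover it lands on.
    """
    check_aligned(base.lulc, footprint, easement, names=["lulc", "footprint", "easement"])
    fp = footprint.data != 0
    ease = easement.data != 0
    if (fp & ease).any():
        raise ValueError("wq footprint and easement must be disjoint")
    out = base.lulc.data.copy()
    out[ease] = cb.WQ_BUFFER
    out[fp] = cb.WQ_POOL
    if shoreline_enabled and fp.any():
        out[interior_ring(fp)] = cb.WQ_SHORELINE
    scenario = "wqw" if base.scenario == "baseline" else "drain_mod_wqw"
    new = base.with_step(
        base.lulc.like(out, name=f"lulc_{scenario}"), scenario, "wq_wetland"
    )
    new.shoreline_enabled = shoreline_enabled
    return new


def build_scenario(
    watershed: SyntheticWatershed, scenario: str, shoreline_enabled: bool = True
) -> ScenarioMap:
    """Build any of the four scenario maps from scratch."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    m = build_baseline(watershed)
    if scenario in ("drain_mod", "drain_mod_wqw"):
        m = apply_drainage_modernization(m, watershed)
    if scenario in ("wqw", "drain_mod_wqw"):
        m = add_wq_wetland(
            m, watershed.wq_footprint, watershed.wq_easement, shoreline_enabled
        )
    m.scenario = scenario
    return m
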