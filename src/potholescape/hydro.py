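"""Surface-water scene summarization into seasonal dryness threats.

Classified surface-water scenes (DSWE-style integer codes per acquisition
date) are reduced to a per-pixel *dry* threat in [0, 1] for a seasonal
window — March–April for duck models, April–May for shorebirds — by one of
two methods:

``presence_absence``
    Scenes within a window are composited per year by per-pixel maximum;
    dry = 1 − (years with water) / (years observed).
``all_measurements``
    Every cloud-free observation counts individually;
    dry = 1 − (wet observations) / (total observations).

Pixels never observed cloud-free carry nodata (NaN) rather than a dryness
penalty: downstream post-model filtering removes depressions with no
observations instead of scoring them as dry.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid, check_aligned

#: DSWE codes treated as surface water: open water high/moderate confidence
#: and partial surface water conservative.
WATER_CODES = (1, 2, 3)

WINDOWS = ("mar_apr", "apr_may")
_WINDOW_MONTHS = {"mar_apr": (3, 4), "apr_may": (4, 5)}


class WindowMismatchError(ValueError):
    """A hydroperiod product was offered to a group with a different window."""


@dataclass
class DsweScene:
    """One classified surface-water acquisition.

    ``codes`` holds integer class codes (0–4); ``cloud`` is 1 where the
    pixel was unobserved (cloud/shadow) and the code is meaningless.
    """

    date: _dt.date
    codes: RasterGrid
    cloud: RasterGrid

    def __post_init__(self) -> None:
        check_aligned(self.codes, self.cloud, names=["codes", "cloud"])

    @property
    def year(self) -> int:
        return self.date.year

    def in_window(self, window: str) -> bool:
        if window not in WINDOWS:
            raise ValueError(f"unknown window {window!r}")
        return self.date.month in _WINDOW_MONTHS[window]


@dataclass
class HydroperiodRaster:
    """Per-pixel dryness threat for one seasonal window.

    ``dry`` is in [0, 1] wherever ``obs_count`` > 0 and NaN elsewhere.
    """

    dry: RasterGrid
    window: str
    method: str
    n_years: int
    obs_count: RasterGrid

    def __post_init__(self) -> None:
        if self.window not in WINDOWS:
            raise ValueError(f"unknown window {self.window!r}")
        if self.method not in ("presence_absence", "all_measurements"):
            raise ValueError(f"unknown method {self.method!r}")


def reclassify_water(scene: DsweScene) -> RasterGrid:
    """Binary water raster: 1 for water codes, 0 otherwise, NaN under cloud."""
    codes = scene.codes.data
    wet = np.isin(codes, WATER_CODES).astype(np.float64)
    wet[scene.cloud.data != 0] = np.nan
    return scene.codes.like(wet, nodata=np.nan, name=f"water_{scene.date.isoformat()}")


def scenes_in_window(
    scenes: list[DsweScene], window: str, year: int | None = None
) -> list[DsweScene]:
    out = [s for s in scenes if s.in_window(window)]
    if year is not None:
        out = [s for s in out if s.year == year]
    return out


def annual_window_composite(
    scenes: list[DsweScene], window: str, year: int
) -> RasterGrid:
    """Per-pixel maximum of reclassified scenes for (window, year).

    A pixel is NaN only if it was unobserved in every scene of that year.
    """
    selected = scenes_in_window(scenes, window, year)
    if not selected:
        raise ValueError(f"no scenes for window {window!r}, year {year}")
    stack = np.stack([reclassify_water(s).data for s in selected])
    valid = ~np.isnan(stack)
    comp = np.where(valid, stack, -np.inf).max(axis=0)
    comp[~valid.any(axis=0)] = np.nan
    return selected[0].codes.like(comp, nodata=np.nan, name=f"composite_{window}_{year}")


def window_years(scenes: list[DsweScene], window: str) -> list[int]:
    return sorted({s.year for s in scenes if s.in_window(window)})


def _observation_count(scenes: list[DsweScene], window: str) -> np.ndarray:
    counts = None
    for s in scenes_in_window(scenes, window):
        free = (s.cloud.data == 0).astype(np.int64)
        counts = free if counts is None else counts + free
    if counts is None:
        raise ValueError(f"no scenes in window {window!r}")
    return counts


def dry_threat_presence_absence(
    scenes: list[DsweScene], window: str
) -> HydroperiodRaster:
    """dry = 1 − (years wet) / (years observed), per pixel.

    A year enters a pixel's denominator only if the pixel had at least one
    cloud-free observation that year.
    """
    years = window_years(scenes, window)
    if not years:
        raise ValueError(f"no scenes in window {window!r}")
    wet_years = None
    obs_years = None
    for year in years:
        comp = annual_window_composite(scenes, window, year).data
        observed = ~np.isnan(comp)
        wet = observed & (comp > 0)
        wet_years = wet.astype(np.int64) if wet_years is None else wet_years + wet
        obs_years = observed.astype(np.int64) if obs_years is None else obs_years + observed
    with np.errstate(invalid="ignore", divide="ignore"):
        dry = 1.0 - np.where(obs_years > 0, wet_years / np.maximum(obs_years, 1), np.nan)
    dry[obs_years == 0] = np.nan
    grid = scenes[0].codes
    return HydroperiodRaster(
        dry=grid.like(dry, nodata=np.nan, name=f"dry_pa_{window}"),
        window=window,
        method="presence_absence",
        n_years=len(years),
        obs_count=grid.like(_observation_count(scenes, window), name="obs_count"),
    )


def dry_threat_all_measurements(
    scenes: list[DsweScene], window: str
) -> HydroperiodRaster:
    """dry = 1 − (wet observations) / (total cloud-free observations)."""
    selected = scenes_in_window(scenes, window)
    if not selected:
        raise ValueError(f"no scenes in window {window!r}")
    wet_obs = np.zeros(selected[0].codes.shape, dtype=np.int64)
    tot_obs = np.zeros_like(wet_obs)
    for s in selected:
        w = reclassify_water(s).data
        observed = ~np.isnan(w)
        tot_obs += observed
        wet_obs += observed & (w > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dry = 1.0 - np.where(tot_obs > 0, wet_obs / np.maximum(tot_obs, 1), np.nan)
    dry[tot_obs == 0] = np.nan
    grid = selected[0].codes
    return HydroperiodRaster(
        dry=grid.like(dry, nodata=np.nan, name=f"dry_all_{window}"),
        window=window,
        method="all_measurements",
        n_years=len(window_years(scenes, window)),
        obs_count=grid.like(tot_obs, name="obs_count"),
    )


def dry_threat(scenes: list[DsweScene], window: str, method: str) -> HydroperiodRaster:
    if method in ("pa", "presence_absence"):
        return dry_threat_presence_absence(scenes, window)
    if method in ("all", "all_measurements"):
        return dry_threat_all_measurements(scenes, window)
    raise ValueError(f"unknown dry-threat method {method!r}")


def depression_activity(
    patches: RasterGrid, scenes: list[DsweScene], window: str
) -> dict[int, bool]:
    """True per patch iff any pixel was wet in any year's window composite.

    A patch that was never observed cloud-free has no surface-water records
    and is inactive.
    """
    labels = patches.data
    ids = [int(i) for i in np.unique(labels) if i > 0]
    active = {i: False for i in ids}
    for year in window_years(scenes, window):
        comp = annual_window_composite(scenes, window, year).data
        wet = comp > 0  # NaN compares False
        for i in ids:
            if not active[i] and bool(wet[labels == i].any()):
                active[i] = True
    return active
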