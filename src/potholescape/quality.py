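"""The half-saturation habitat-quality index.

Per-pixel habitat suitability H (0 / 0.5 / 1 per bird group) is degraded by
the combined, sensitivity-weighted threat level D:

    D_x = sum_r (w_r / sum w) * S_{j(x),r} * T_{r,x}

where T is the threat exposure at the pixel — the raw raster value for
in-place threats (dry, wetarea), or a linear-distance-decay weighted
average of the threat raster for proximity threats — S is the sensitivity
of the pixel's land-cover class j(x) to threat r, and weights w are
normalized to sum 1 so D stays in [0, 1] regardless of the weight scale.

Quality is the half-saturation function of degradation:

    Q_x = H_x * (1 - D_x^z / (D_x^z + k^z))

with scaling constant z = 2.5 and half-saturation constant k = 0.5 by
default, so quality is halved exactly where D equals k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codebook as cb
from .raster import RasterGrid, check_aligned
from .scenarios import ScenarioMap
from .threats import ThreatSpec, edge_normalized_mean, linear_decay_kernel

BIN_EDGES = (0.01, 0.05, 0.15)
BIN_LABELS = ("minimal", "low", "intermediate", "high")


@dataclass
class QualityParams:
    """Index constants and threat weighting."""

    z: float = 2.5
    k: float = 0.5
    weights: dict[str, float] = field(default_factory=dict)
    decay_enabled: bool = True  # convolve proximity threats with the decay kernel

    def __post_init__(self) -> None:
        if self.z <= 0 or self.k <= 0:
            raise ValueError("z and k must be positive")
        if self.weights and not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one threat weight must be positive")


@dataclass
class QualityResult:
    """Per-pixel quality and its aggregates for one (group, scenario, filter)."""

    Q: RasterGrid
    D: RasterGrid
    total_score: float
    bin_areas: dict[str, float]  # hectares, over Q > 0
    group: str
    scenario: str
    filter: str = "all_depressions"
    mask: RasterGrid | None = None


def suitability_raster(
    lulc: ScenarioMap, group: str, codebook: cb.Codebook | None = None
) -> RasterGrid:
    """Per-pixel habitat suitability H in {0, 0.5, 1} for a bird group."""
    codebook = codebook or cb.default_codebook()
    data = lulc.lulc.data
    out = np.zeros(data.shape, dtype=np.float64)
    for code in np.unique(data):
        out[data == code] = codebook.H(int(code), group)  # raises on unknown code
    return lulc.lulc.like(out, name=f"H_{group}_{lulc.scenario}")


def _sensitivity_raster(
    lulc: ScenarioMap, threat: str, group: str, codebook: cb.Codebook
) -> np.ndarray:
    data = lulc.lulc.data
    out = np.zeros(data.shape, dtype=np.float64)
    for code in np.unique(data):
        out[data == code] = codebook.S(int(code), threat, group)
    return out


def threat_exposure(spec: ThreatSpec, decay_enabled: bool = True) -> np.ndarray:
    """Threat exposure T_r: in-place value, or the linear-decay window mean."""
    values = np.asarray(spec.raster.data, dtype=np.float64)
    if spec.max_dist <= 0 or not decay_enabled:
        return values
    kernel = linear_decay_kernel(spec.max_dist, spec.raster.pixel_size)
    return np.clip(edge_normalized_mean(values, kernel), 0.0, 1.0)


def degradation(
    threats: list[ThreatSpec],
    lulc: ScenarioMap,
    group: str,
    codebook: cb.Codebook | None = None,
    weights: dict[str, float] | None = None,
    decay_enabled: bool = True,
    _exposures: dict[str, np.ndarray] | None = None,
) -> RasterGrid:
    """Combined degradation D in [0, 1].

    ``weights`` overrides the per-spec weights (used by the sensitivity
    grid, which re-weights cached exposures instead of re-convolving);
    ``_exposures`` is an optional cache of precomputed exposure arrays.
    """
    codebook = codebook or cb.default_codebook()
    if not threats:
        raise ValueError("at least one threat is required")
    w = {t.name: t.weight for t in threats}
    if weights is not None:
        w.update(weights)
    for name, val in w.items():
        if val < 0:
            raise ValueError(f"negative weight for threat {name!r}")
    total_w = sum(w.values())
    if total_w <= 0:
        raise ValueError("at least one threat weight must be positive")

    D = np.zeros(lulc.lulc.shape, dtype=np.float64)
    for spec in threats:
        if _exposures is not None and spec.name in _exposures:
            T = _exposures[spec.name]
        else:
            T = threat_exposure(spec, decay_enabled)
            if _exposures is not None:
                _exposures[spec.name] = T
        S = _sensitivity_raster(lulc, spec.name, group, codebook)
        D += (w[spec.name] / total_w) * S * T
    return lulc.lulc.like(D, name=f"D_{group}_{lulc.scenario}")


def quality_index(H: RasterGrid, D: RasterGrid, params: QualityParams) -> RasterGrid:
    """Q = H * (1 - D^z / (D^z + k^z))."""
    check_aligned(H, D, names=["H", "D"])
    d = np.asarray(D.data, dtype=np.float64)
    if np.nanmin(d) < -1e-12:
        raise ValueError("degradation must be nonnegative")
    dz = np.power(np.clip(d, 0.0, None), params.z)
    q = H.data * (1.0 - dz / (dz + params.k**params.z))
    return H.like(q, name=H.name.replace("H_", "Q_", 1) or "Q")


def total_score(Q: RasterGrid, mask: RasterGrid | None = None) -> float:
    """Sum of per-pixel quality over the watershed mask (unitless)."""
    q = Q.data
    if mask is not None:
        check_aligned(Q, mask, names=["Q", "mask"])
        q = np.where(mask.data != 0, q, 0.0)
    return float(np.nansum(q))


def bin_areas(Q: RasterGrid, mask: RasterGrid | None = None) -> dict[str, float]:
    """Hectares of Q > 0 area per quality bin.

    Bins partition (0, 1]: minimal (0, 0.01], low (0.01, 0.05],
    intermediate (0.05, 0.15], high (0.15, 1].
    """
    q = Q.data
    keep = ~np.isnan(q) & (q > 0)
    if mask is not None:
        keep &= mask.data != 0
    vals = q[keep]
    lo, mid, hi = BIN_EDGES
    px_ha = Q.pixel_area_ha
    return {
        "minimal": float((vals <= lo).sum() * px_ha),
        "low": float(((vals > lo) & (vals <= mid)).sum() * px_ha),
        "intermediate": float(((vals > mid) & (vals <= hi)).sum() * px_ha),
        "high": float((vals > hi).sum() * px_ha),
    }


def quality_bin(value: float) -> str:
    """Bin label for one quality value (NaN/0 -> 'zero')."""
    if np.isnan(value) or value <= 0:
        return "zero"
    lo, mid, hi = BIN_EDGES
    if value <= lo:
        return "minimal"
    if value <= mid:
        return "low"
    if value <= hi:
        return "intermediate"
    return "high"


def evaluate_quality(
    threats: list[ThreatSpec],
    lulc: ScenarioMap,
    group: str,
    params: QualityParams,
    codebook: cb.Codebook | None = None,
    mask: RasterGrid | None = None,
    _exposures: dict[str, np.ndarray] | None = None,
) -> QualityResult:
    """Run suitability, degradation and the index; aggregate to a result."""
    codebook = codebook or cb.default_codebook()
    H = suitability_raster(lulc, group, codebook)
    D = degradation(
        threats,
        lulc,
        group,
        codebook,
        weights=params.weights or None,
        decay_enabled=params.decay_enabled,
        _exposures=_exposures,
    )
    Q = quality_index(H, D, params)
    return QualityResult(
        Q=Q,
        D=D,
        total_score=total_score(Q, mask),
        bin_areas=bin_areas(Q, mask),
        group=group,
        scenario=lulc.scenario,
        mask=mask,
    )
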