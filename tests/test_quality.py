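"""Half-saturation index: closed-form values, degradation oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import potholescape as pp
from potholescape import codebook as cb
from potholescape.quality import evaluate_quality, quality_bin, threat_exposure
from potholescape.raster import RasterGrid
from potholescape.scenarios import ScenarioMap
from potholescape.threats import ThreatSpec, linear_decay_kernel


def _grid(data):
    return RasterGrid(np.asarray(data, dtype=np.float64))


def _smap(lulc):
    return ScenarioMap(lulc=RasterGrid(np.asarray(lulc, dtype=np.int16)), scenario="baseline")


def _inplace_threat(name, value, weight=1.0, shape=(1, 1)):
    return ThreatSpec(
        name=name, weight=weight, max_dist=0.0,
        raster=RasterGrid(np.full(shape, value, dtype=np.float64)),
    )


def brute_force_degradation(threats, sens, weights):
    """Oracle: explicit double loop over threats and source cells."""
    total_w = sum(weights[t.name] for t in threats)
    shape = threats[0].raster.shape
    D = np.zeros(shape)
    for t in threats:
        vals = t.raster.data
        if t.max_dist <= 0:
            T = vals.astype(float)
        else:
            T = np.zeros(shape)
            px = t.raster.pixel_size
            for r in range(shape[0]):
                for c in range(shape[1]):
                    num = den = 0.0
                    for rr in range(shape[0]):
                        for cc in range(shape[1]):
                            d = np.hypot(rr - r, cc - c) * px
                            w = max(0.0, 1.0 - d / t.max_dist)
                            num += w * vals[rr, cc]
                            den += w
                    T[r, c] = num / den
        D += (weights[t.name] / total_w) * sens * T
    return D


class TestQualityIndex:
    def test_no_degradation_keeps_full_quality(self):
        q = pp.quality_index(_grid([[1.0]]), _grid([[0.0]]), pp.QualityParams())
        assert q.data[0, 0] == 1.0

    def test_zero_suitability_stays_zero(self):
        q = pp.quality_index(_grid([[0.0]]), _grid([[3.0]]), pp.QualityParams())
        assert q.data[0, 0] == 0.0

    def test_half_saturation_point(self):
        # D = k halves the quality exactly: D^z/(D^z + k^z) = 1/2
        params = pp.QualityParams(z=2.5, k=0.5)
        q = pp.quality_index(_grid([[1.0]]), _grid([[0.5]]), params)
        assert q.data[0, 0] == pytest.approx(0.5, abs=1e-15)
        # cross-check by direct evaluation of the formula
        direct = 1.0 * (1 - 0.5**2.5 / (0.5**2.5 + 0.5**2.5))
        assert q.data[0, 0] == pytest.approx(direct)

    def test_quality_vanishes_at_large_degradation(self):
        q = pp.quality_index(_grid([[1.0]]), _grid([[1e6]]), pp.QualityParams())
        assert q.data[0, 0] == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 5.0), st.floats(0.01, 5.0),
        st.sampled_from([0.5, 1.0]),
    )
    def test_strictly_decreasing_in_degradation(self, d1, d2, h):
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        params = pp.QualityParams()
        q_lo = pp.quality_index(_grid([[h]]), _grid([[lo]]), params).data[0, 0]
        q_hi = pp.quality_index(_grid([[h]]), _grid([[hi]]), params).data[0, 0]
        assert q_hi < q_lo
        assert 0.0 <= q_hi <= h and 0.0 <= q_lo <= h


class TestDegradation:
    def test_all_zero_threats_give_zero(self):
        lulc = _smap([[cb.NWI_SEMIPERM]])
        threats = [_inplace_threat("dry", 0.0), _inplace_threat("crop", 0.0)]
        D = pp.degradation(threats, lulc, "wetland_dabbler")
        assert D.data[0, 0] == 0.0

    def test_single_inplace_threat_passes_through(self):
        lulc = _smap([[cb.NWI_SEMIPERM]])
        D = pp.degradation([_inplace_threat("dry", 0.6)], lulc, "wetland_dabbler")
        assert D.data[0, 0] == pytest.approx(0.6)

    def test_two_equal_weight_threats_average(self):
        lulc = _smap([[cb.NWI_SEMIPERM]])
        threats = [_inplace_threat("dry", 0.2), _inplace_threat("crop", 0.8)]
        D = pp.degradation(threats, lulc, "wetland_dabbler")
        assert D.data[0, 0] == pytest.approx(0.5)

    def test_unsuitable_class_feels_no_degradation_by_default(self):
        lulc = _smap([[cb.DEVELOPED]])
        D = pp.degradation([_inplace_threat("dry", 0.9)], lulc, "wetland_dabbler")
        assert D.data[0, 0] == 0.0

    def test_negative_weight_rejected(self):
        lulc = _smap([[cb.NWI_SEMIPERM]])
        threats = [_inplace_threat("dry", 0.5)]
        with pytest.raises(ValueError, match="egative"):
            pp.degradation(threats, lulc, "wetland_dabbler", weights={"dry": -1.0})

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(4, 11), rng.integers(4, 11))
        lulc = _smap(np.full(shape, cb.NWI_SEMIPERM))
        threats = [
            ThreatSpec("dry", 1.0, 0.0, RasterGrid(rng.random(shape))),
            ThreatSpec("crop", 0.7, 90.0, RasterGrid(rng.random(shape))),
            ThreatSpec("road", 1.3, 150.0, RasterGrid(rng.random(shape))),
        ]
        weights = {t.name: t.weight for t in threats}
        sens = np.ones(shape)
        D = pp.degradation(threats, lulc, "wetland_dabbler")
        np.testing.assert_allclose(
            D.data, brute_force_degradation(threats, sens, weights), atol=1e-9
        )

    def test_weight_scale_invariance(self):
        lulc = _smap(np.full((6, 6), cb.NWI_SEMIPERM))
        rng = np.random.default_rng(3)
        threats = [
            ThreatSpec("dry", 1.0, 0.0, RasterGrid(rng.random((6, 6)))),
            ThreatSpec("crop", 2.0, 60.0, RasterGrid(rng.random((6, 6)))),
        ]
        D1 = pp.degradation(threats, lulc, "wetland_dabbler",
                            weights={"dry": 1.0, "crop": 2.0})
        D2 = pp.degradation(threats, lulc, "wetland_dabbler",
                            weights={"dry": 10.0, "crop": 20.0})
        np.testing.assert_allclose(D1.data, D2.data, atol=1e-14)

    def test_zeroing_a_threat_never_decreases_quality(self, small_run):
        lulc = small_run.scenario_map("baseline")
        threats = small_run.threats("wetland_dabbler", "baseline")
        params = pp.QualityParams()
        full = evaluate_quality(threats, lulc, "wetland_dabbler", params)
        for i, drop in enumerate(threats):
            reduced = [
                t if j != i else ThreatSpec(
                    t.name, t.weight, t.max_dist,
                    t.raster.like(np.zeros(t.raster.shape)),
                )
                for j, t in enumerate(threats)
            ]
            less = evaluate_quality(reduced, lulc, "wetland_dabbler", params)
            assert (less.Q.data >= full.Q.data - 1e-12).all(), drop.name

    def test_degradation_stays_in_unit_interval(self, small_run):
        for group in ("field_dabbler", "diver"):
            D = small_run.evaluate(group, "baseline").D.data
            assert D.min() >= 0.0 and D.max() <= 1.0 + 1e-12


class TestExposure:
    def test_inplace_exposure_is_identity(self):
        spec = _inplace_threat("dry", 0.4, shape=(3, 3))
        np.testing.assert_array_equal(threat_exposure(spec), spec.raster.data)

    def test_decay_kernel_is_normalized_and_peaks_at_center(self):
        k = linear_decay_kernel(150.0, 30.0)
        assert k.sum() == pytest.approx(1.0)
        assert k.max() == k[k.shape[0] // 2, k.shape[1] // 2]

    def test_constant_field_invariant_under_decay(self):
        spec = ThreatSpec("crop", 1.0, 300.0, RasterGrid(np.full((12, 12), 0.37)))
        np.testing.assert_allclose(threat_exposure(spec), 0.37, atol=1e-12)


class TestAggregation:
    def test_all_zero_quality(self):
        Q = _grid(np.zeros((5, 5)))
        assert pp.total_score(Q) == 0.0
        assert all(v == 0.0 for v in pp.bin_areas(Q).values())

    def test_high_bin_area(self):
        Q = _grid(np.full((10, 10), 0.2))  # 100 px of Q=0.2 -> 9 ha high
        bins = pp.bin_areas(Q)
        assert bins["high"] == pytest.approx(9.0)
        assert bins["low"] == bins["minimal"] == bins["intermediate"] == 0.0

    def test_total_is_pixel_sum(self):
        Q = _grid(np.zeros((5, 5)))
        Q.data[:2, :5] = 1.0
        assert pp.total_score(Q) == pytest.approx(10.0)

    def test_mask_restricts_total(self):
        Q = _grid(np.ones((4, 4)))
        mask = RasterGrid(np.zeros((4, 4), dtype=np.uint8))
        mask.data[0, :] = 1
        assert pp.total_score(Q, mask) == pytest.approx(4.0)

    def test_bin_partition(self):
        assert quality_bin(0.0) == "zero"
        assert quality_bin(0.01) == "minimal"
        assert quality_bin(0.05) == "low"
        assert quality_bin(0.15) == "intermediate"
        assert quality_bin(0.151) == "high"

    def test_suitability_raster_values(self):
        lulc = _smap([[cb.DEVELOPED, cb.DEP_CORN, cb.NWI_SEMIPERM]])
        book = cb.default_codebook()
        for group, expect in [
            ("wetland_dabbler", [0.0, 1.0, 1.0]),
            ("diver", [0.0, 0.0, 1.0]),
            ("shorebird", [0.0, 1.0, 0.5]),
        ]:
            H = pp.suitability_raster(lulc, group, book)
            assert H.data[0].tolist() == expect

    def test_unknown_class_code_fails(self):
        lulc = _smap([[99]])
        with pytest.raises(KeyError):
            pp.suitability_raster(lulc, "diver")
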