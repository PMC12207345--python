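"""Scenario construction: overlay order, conversion rules, shoreline rings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import potholescape as pp
from potholescape import codebook as cb
from potholescape.raster import RasterGrid
from potholescape.scenarios import interior_ring


def brute_force_ring(mask: np.ndarray) -> np.ndarray:
    """Oracle: ring = mask minus its 4-connected erosion, by explicit loops."""
    rows, cols = mask.shape
    eroded = np.zeros_like(mask, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            neighbors = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                neighbors.append(
                    mask[rr, cc] if 0 <= rr < rows and 0 <= cc < cols else False
                )
            eroded[r, c] = all(neighbors)
    return mask & ~eroded


def _tiny_watershed(dep_classes, nwi_cells=(), regime="semipermanent"):
    """Hand-built 8x8 watershed: one depression patch over given crop cells."""
    shape = (8, 8)
    grid = RasterGrid(np.zeros(shape, dtype=np.int16))
    crop = np.full(shape, cb.SOY, dtype=np.int16)
    for (r, c), code in dep_classes.items():
        crop[r, c] = code
    dep = np.zeros(shape, dtype=np.int32)
    for r, c in dep_classes:
        dep[r, c] = 1
    nwi = np.zeros(shape, dtype=np.int32)
    for r, c in nwi_cells:
        nwi[r, c] = 1
    under = crop[dep == 1]
    counts = {c: int((under == c).sum()) for c in cb.CROP_CLASSES}
    majority = min(c for c in cb.CROP_CLASSES if counts[c] == max(counts.values()))
    return pp.SyntheticWatershed(
        config=pp.LandscapeConfig(grid_rows=8, grid_cols=8, n_depressions=1, seed=0),
        lulc=grid.like(crop),
        depressions=grid.like(dep),
        depression_records=pd.DataFrame(
            [{"id": 1, "n_pixels": int((dep == 1).sum()),
              "area_ha": (dep == 1).sum() * 0.09, "majority_class": majority}]
        ),
        nwi_wetlands=grid.like(nwi),
        nwi_records=pd.DataFrame(
            [{"id": 1, "n_pixels": len(nwi_cells), "area_ha": len(nwi_cells) * 0.09,
              "regime": regime}] if nwi_cells else [],
            columns=["id", "n_pixels", "area_ha", "regime"],
        ),
        roads=grid.like(np.zeros(shape, dtype=np.uint8)),
        watershed_mask=grid.like(np.ones(shape, dtype=np.uint8)),
        wq_footprint=grid.like(np.zeros(shape, dtype=np.uint8)),
        wq_easement=grid.like(np.zeros(shape, dtype=np.uint8)),
    )


class TestBaseline:
    def test_depression_majority_corn_becomes_depressional_corn(self):
        ws = _tiny_watershed({(2, 2): cb.CORN, (2, 3): cb.CORN, (3, 2): cb.SOY})
        base = pp.build_baseline(ws)
        assert base.lulc.data[2, 2] == cb.DEP_CORN
        assert base.lulc.data[3, 2] == cb.DEP_CORN  # patch takes its majority

    def test_nwi_wetland_overrides_depression(self):
        ws = _tiny_watershed({(2, 2): cb.CORN, (2, 3): cb.CORN}, nwi_cells=[(2, 2)])
        base = pp.build_baseline(ws)
        assert base.lulc.data[2, 2] == cb.NWI_SEMIPERM
        assert base.lulc.data[2, 3] == cb.DEP_CORN

    def test_empty_watershed_baseline_is_crop_base(self):
        config = pp.LandscapeConfig(
            grid_rows=30, grid_cols=30, n_depressions=0, n_nwi_wetlands=0,
            wq_wetland_fraction=0.0, road_spacing=1e9, seed=9,
        )
        ws = pp.generate_landscape(config)
        ws.roads.data[:] = 0  # road grid always draws edge lines; strip them
        base = pp.build_baseline(ws)
        np.testing.assert_array_equal(base.lulc.data, ws.lulc.data)

    def test_lacustrine_interior_edge_is_ring(self):
        ws = _tiny_watershed({}, nwi_cells=[(r, c) for r in range(2, 7) for c in range(2, 7)],
                             regime="lacustrine")
        base = pp.build_baseline(ws)
        edge = base.lulc.data == cb.LACUSTRINE_EDGE
        interior = base.lulc.data == cb.LACUSTRINE
        assert edge.sum() == 16 and interior.sum() == 9  # 5x5 -> ring 16 + core 9

    def test_roads_on_top(self, small_watershed):
        base = pp.build_baseline(small_watershed)
        roads = small_watershed.roads.data != 0
        assert (base.lulc.data[roads] == cb.ROAD).all()


class TestDrainageModernization:
    def test_depressional_corn_converts_to_corn(self):
        ws = _tiny_watershed({(2, 2): cb.CORN, (2, 3): cb.CORN})
        out = pp.apply_drainage_modernization(pp.build_baseline(ws), ws)
        assert out.lulc.data[2, 2] == cb.CORN
        assert out.scenario == "drain_mod"

    def test_wetland_inside_depression_also_converts(self):
        ws = _tiny_watershed({(2, 2): cb.SOY, (2, 3): cb.SOY}, nwi_cells=[(2, 2)])
        out = pp.apply_drainage_modernization(pp.build_baseline(ws), ws)
        assert out.lulc.data[2, 2] == cb.SOY

    def test_no_depressions_is_identity(self):
        ws = _tiny_watershed({})
        ws.depression_records = ws.depression_records.iloc[:0]
        base = pp.build_baseline(ws)
        out = pp.apply_drainage_modernization(base, ws)
        np.testing.assert_array_equal(out.lulc.data, base.lulc.data)

    def test_idempotent(self, small_watershed):
        base = pp.build_baseline(small_watershed)
        once = pp.apply_drainage_modernization(base, small_watershed)
        twice = pp.apply_drainage_modernization(once, small_watershed)
        np.testing.assert_array_equal(once.lulc.data, twice.lulc.data)

    def test_local_to_depressions(self, small_watershed):
        base = pp.build_baseline(small_watershed)
        out = pp.apply_drainage_modernization(base, small_watershed)
        changed = base.lulc.data != out.lulc.data
        assert (changed <= (small_watershed.depressions.data > 0)).all()


class TestWqWetland:
    @staticmethod
    def _square_footprint(side, offset=(5, 5), shape=(20, 20)):
        grid = RasterGrid(np.zeros(shape, dtype=np.int16))
        fp = np.zeros(shape, dtype=np.uint8)
        fp[offset[0]:offset[0] + side, offset[1]:offset[1] + side] = 1
        return grid, grid.like(fp), grid.like(np.zeros(shape, dtype=np.uint8))

    def test_5x5_footprint_splits_16_ring_9_pool(self):
        grid, fp, ease = self._square_footprint(5)
        base = pp.ScenarioMap(lulc=grid.like(np.full(grid.shape, cb.SOY, dtype=np.int16)),
                              scenario="baseline")
        out = pp.add_wq_wetland(base, fp, ease, shoreline_enabled=True)
        assert (out.lulc.data == cb.WQ_SHORELINE).sum() == 16
        assert (out.lulc.data == cb.WQ_POOL).sum() == 9

    def test_shoreline_disabled_gives_no_ring(self):
        grid, fp, ease = self._square_footprint(5)
        base = pp.ScenarioMap(lulc=grid.like(np.full(grid.shape, cb.SOY, dtype=np.int16)),
                              scenario="baseline")
        out = pp.add_wq_wetland(base, fp, ease, shoreline_enabled=False)
        assert (out.lulc.data == cb.WQ_SHORELINE).sum() == 0
        assert (out.lulc.data == cb.WQ_POOL).sum() == 25

    def test_single_pixel_footprint_is_all_shoreline(self):
        grid, fp, ease = self._square_footprint(1)
        base = pp.ScenarioMap(lulc=grid.like(np.full(grid.shape, cb.SOY, dtype=np.int16)),
                              scenario="baseline")
        out = pp.add_wq_wetland(base, fp, ease, shoreline_enabled=True)
        assert (out.lulc.data == cb.WQ_SHORELINE).sum() == 1
        assert (out.lulc.data == cb.WQ_POOL).sum() == 0

    def test_overlapping_footprint_and_easement_rejected(self):
        grid, fp, _ = self._square_footprint(3)
        base = pp.ScenarioMap(lulc=grid.like(np.full(grid.shape, cb.SOY, dtype=np.int16)),
                              scenario="baseline")
        with pytest.raises(ValueError, match="disjoint"):
            pp.add_wq_wetland(base, fp, fp)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ring_matches_erosion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(5, 30), rng.integers(5, 30))
        mask = rng.random(shape) < 0.4
        ring = interior_ring(mask)
        np.testing.assert_array_equal(ring, brute_force_ring(mask))
        # ring and erosion partition the footprint
        assert ring.sum() + (mask & ~ring).sum() == mask.sum()


class TestMajorityAndComposition:
    def test_strict_majority(self):
        patch = np.ones((2, 5), dtype=bool)
        crop = np.array([[cb.CORN] * 3 + [cb.SOY] * 2] * 2, dtype=np.int16)
        assert pp.majority_lulc(patch, crop) == cb.CORN

    def test_tie_breaks_to_lowest_code(self):
        patch = np.ones((1, 4), dtype=bool)
        crop = np.array([[cb.CORN, cb.CORN, cb.SOY, cb.SOY]], dtype=np.int16)
        # brute-force enumeration over orderings gives the same winner
        assert pp.majority_lulc(patch, crop) == min(cb.CORN, cb.SOY)

    def test_empty_patch_fails(self):
        with pytest.raises(ValueError, match="empty"):
            pp.majority_lulc(np.zeros((3, 3), dtype=bool), np.zeros((3, 3), dtype=np.int16))

    def test_combined_scenario_composes(self, small_watershed):
        direct = pp.build_scenario(small_watershed, "drain_mod_wqw")
        stepwise = pp.add_wq_wetland(
            pp.apply_drainage_modernization(pp.build_baseline(small_watershed), small_watershed),
            small_watershed.wq_footprint,
            small_watershed.wq_easement,
            shoreline_enabled=True,
        )
        np.testing.assert_array_equal(direct.lulc.data, stepwise.lulc.data)

    def test_edits_are_local(self, small_watershed):
        base = pp.build_baseline(small_watershed)
        wqw = pp.build_scenario(small_watershed, "wqw")
        changed = base.lulc.data != wqw.lulc.data
        footprint = (small_watershed.wq_footprint.data > 0) | (
            small_watershed.wq_easement.data > 0
        )
        assert (changed <= footprint).all()
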