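"""Shared fixtures: a small seeded watershed and the 200x200 reference run."""

from __future__ import annotations

import numpy as np
import pytest

import potholescape as pp


@pytest.fixture(scope="session")
def small_watershed() -> pp.SyntheticWatershed:
    """An 80x80 (57.6 ha) watershed, cheap enough for per-module tests."""
    config = pp.LandscapeConfig(
        grid_rows=80, grid_cols=80, n_depressions=12, n_nwi_wetlands=3, seed=7
    )
    return pp.generate_landscape(config)


@pytest.fixture(scope="session")
def small_scenes(small_watershed) -> list[pp.DsweScene]:
    model = pp.PondingModel.from_watershed(small_watershed, seed=7)
    return pp.generate_dswe_series(small_watershed, model)


@pytest.fixture(scope="session")
def small_run(small_watershed, small_scenes) -> pp.ModelRun:
    return pp.ModelRun(watershed=small_watershed, scenes=small_scenes)


@pytest.fixture(scope="session")
def fixture_run() -> pp.ModelRun:
    """The shipped 200x200 reference landscape with its scene stack."""
    watershed = pp.generate_landscape(pp.fixture_config(42))
    model = pp.PondingModel.from_watershed(watershed, seed=42)
    scenes = pp.generate_dswe_series(watershed, model)
    return pp.ModelRun(watershed=watershed, scenes=scenes)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def grid(data, **kwargs) -> pp.RasterGrid:
    return pp.RasterGrid(np.asarray(data), **kwargs)
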