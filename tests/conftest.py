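"""Shared fixtures and raster-building helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pollenscape.raster import (
    BROAD,
    HabitatRaster,
    Landcover,
    LandcoverRaster,
    NARROW,
    SamplingSite,
)

M = int(Landcover.MATURE)
R = int(Landcover.REGEN)
E = int(Landcover.NARROW_ELEM)
A = int(Landcover.ARABLE)
P = int(Landcover.PASTURE)


def landcover_from(rows: list[list[int]], cell: float = 10.0) -> LandcoverRaster:
    """Landcover raster from a row list; origin at pixel (0, 0) centre."""
    grid = np.asarray(rows, dtype=np.uint8)
    return LandcoverRaster(grid=grid, cell_size=cell, origin=(0.0, (grid.shape[0] - 1) * cell))


def habitat_from(rows: list[list[int]], definition: str = NARROW, cell: float = 10.0) -> HabitatRaster:
    """Binary habitat raster from a 0/1 row list."""
    grid = np.asarray(rows, dtype=np.uint8)
    return HabitatRaster(
        grid=grid,
        definition=definition,
        cell_size=cell,
        origin=(0.0, (grid.shape[0] - 1) * cell),
    )


def site_at(habitat, row: int, col: int, site_id: str = "s") -> SamplingSite:
    x, y = habitat.xy_of(row, col)
    return SamplingSite(site_id=site_id, x=x, y=y)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
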