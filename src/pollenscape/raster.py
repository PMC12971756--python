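"""Rasterized landcover, trapliner-habitat classification and patch geometry.

The analysis operates on a 10 m landcover grid with five classes (mature
forest, regenerating forest, narrow forest elements such as fencerows and
riparian strips, arable land, pasture).  Habitat for traplining
hummingbirds is defined either *narrowly* (mature forest only) or
*broadly* (mature + regenerating forest + narrow forest elements);
agriculture and pasture are never habitat.  Patches are connected
components of the binary habitat grid, and inter-patch gaps are measured
edge-to-edge in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


class Landcover(IntEnum):
    """Landcover codes of the 10 m classification."""

    MATURE = 1
    REGEN = 2
    NARROW_ELEM = 3
    ARABLE = 4
    PASTURE = 5
    NODATA = 0


#: habitat sets under the two trapliner-habitat definitions
NARROW = "narrow"
BROAD = "broad"

_HABITAT_CLASSES = {
    NARROW: frozenset({Landcover.MATURE}),
    BROAD: frozenset({Landcover.MATURE, Landcover.REGEN, Landcover.NARROW_ELEM}),
}

_VALID_CODES = frozenset(int(c) for c in Landcover)


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


class FocalPatchUndefinedError(InvalidInputError):
    """The sampling site does not fall on a habitat pixel.

    Signals a mismatch between site coordinates and the landcover map
    (or a habitat definition that excludes the site's landcover class).
    """


@dataclass
class LandcoverRaster:
    """A rectangular grid of landcover codes in a projected metric CRS.

    ``origin`` is the (x, y) map coordinate of the *centre* of the pixel
    at row 0, col 0; rows increase with decreasing y (north-up raster).
    """

    grid: np.ndarray
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise InvalidInputError("landcover grid must be 2-D")
        if self.cell_size <= 0:
            raise InvalidInputError("cell_size must be positive")
        bad = set(np.unique(self.grid)) - _VALID_CODES
        if bad:
            raise InvalidInputError(f"unknown landcover codes: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def pixel_of(self, x: float, y: float) -> tuple[int, int]:
        """Map coordinate -> (row, col) of the containing pixel."""
        col = int(round((x - self.origin[0]) / self.cell_size))
        row = int(round((self.origin[1] - y) / self.cell_size))
        return row, col

    def xy_of(self, row: int, col: int) -> tuple[float, float]:
        """Pixel (row, col) -> map coordinate of the pixel centre."""
        return (
            self.origin[0] + col * self.cell_size,
            self.origin[1] - row * self.cell_size,
        )


@dataclass
class HabitatRaster:
    """Binary trapliner-habitat grid (1 habitat, 0 non-habitat)."""

    grid: np.ndarray
    definition: str
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        if self.grid.ndim != 2:
            raise InvalidInputError("habitat grid must be 2-D")
        if not np.isin(self.grid, (0, 1)).all():
            raise InvalidInputError("habitat grid must be binary")
        if self.definition not in (NARROW, BROAD):
            raise InvalidInputError(f"unknown habitat definition {self.definition!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def pixel_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def habitat_area_ha(self) -> float:
        return float(self.grid.sum()) * self.pixel_area_ha

    # coordinate helpers mirror LandcoverRaster
    pixel_of = LandcoverRaster.pixel_of
    xy_of = LandcoverRaster.xy_of


@dataclass
class SamplingSite:
    """A sampling site: the reference point of a local landscape."""

    site_id: str
    x: float
    y: float

    def pixel(self, raster: LandcoverRaster | HabitatRaster) -> tuple[int, int]:
        row, col = raster.pixel_of(self.x, self.y)
        nrow, ncol = raster.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise InvalidInputError(
                f"site {self.site_id!r} at ({self.x}, {self.y}) outside raster extent"
            )
        return row, col


@dataclass
class PatchMap:
    """Labeled habitat patches: 0 = non-habitat, k >= 1 = patch id."""

    labels: np.ndarray
    neighbourhood: int
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    patch_areas: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patch_areas:
            pix_ha = self.cell_size**2 / 10_000.0
            ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
            self.patch_areas = {int(i): float(c) * pix_ha for i, c in zip(ids, counts)}

    @property
    def patch_ids(self) -> list[int]:
        return sorted(self.patch_areas)

    def pixels_of(self, patch_id: int) -> np.ndarray:
        """(n, 2) array of (row, col) indices of the patch's pixels."""
        if patch_id not in self.patch_areas:
            raise InvalidInputError(f"no patch with id {patch_id}")
        return np.argwhere(self.labels == patch_id)


def classify_habitat(landcover: LandcoverRaster, definition: str) -> HabitatRaster:
    """Binarize a landcover raster under a trapliner-habitat definition.

    ``narrow`` keeps mature forest only; ``broad`` adds regenerating
    forest and narrow forest elements.  Arable, pasture and nodata are
    always non-habitat.
    """
    try:
        habitat_classes = _HABITAT_CLASSES[definition]
    except KeyError:
        raise InvalidInputError(f"unknown habitat definition {definition!r}") from None
    grid = np.isin(landcover.grid, [int(c) for c in habitat_classes]).astype(np.uint8)
    return HabitatRaster(
        grid=grid,
        definition=definition,
        cell_size=landcover.cell_size,
        origin=landcover.origin,
        crs_id=landcover.crs_id,
    )


def median_site_coordinate(plant_coords: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Component-wise median of maternal-plant coordinates.

    For even counts each axis uses the mean of the two central order
    statistics (the ordinary sample median).
    """
    if len(plant_coords) == 0:
        raise InvalidInputError("need at least one plant coordinate")
    arr = np.asarray(plant_coords, dtype=float)
    med = np.median(arr, axis=0)
    return float(med[0]), float(med[1])


def clip_local_landscape(
    habitat: HabitatRaster, site: SamplingSite, radius: float = 1000.0
) -> HabitatRaster:
    """Zero out habitat pixels whose centre lies beyond ``radius`` of the site.

    The local landscape is the 1 km-radius disk around the site — the
    assumed maximum daily movement range of traplining hummingbirds.
    Geometry (shape, origin) is unchanged.
    """
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    srow, scol = site.pixel(habitat)
    sx, sy = habitat.xy_of(srow, scol)
    rows = np.arange(habitat.shape[0])
    cols = np.arange(habitat.shape[1])
    xs = habitat.origin[0] + cols * habitat.cell_size
    ys = habitat.origin[1] - rows * habitat.cell_size
    dist2 = (ys[:, None] - sy) ** 2 + (xs[None, :] - sx) ** 2
    grid = np.where(dist2 <= radius**2, habitat.grid, 0).astype(np.uint8)
    return HabitatRaster(
        grid=grid,
        definition=habitat.definition,
        cell_size=habitat.cell_size,
        origin=habitat.origin,
        crs_id=habitat.crs_id,
    )


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_patches(habitat: HabitatRaster, neighbourhood: int = 8) -> PatchMap:
    """Connected-component labeling of the habitat grid.

    8-connectivity by default: diagonally adjacent forest pixels are
    traversable by a flying pollinator.  Labels are relabeled to
    row-major first-seen order so labeling is deterministic.
    """
    if neighbourhood not in _STRUCTURES:
        raise InvalidInputError("neighbourhood must be 4 or 8")
    raw, n = ndimage.label(habitat.grid, structure=_STRUCTURES[neighbourhood])
    # scipy already labels in row-major first-encounter order, but make the
    # contract explicit and independent of its internals
    labels = np.zeros_like(raw)
    remap: dict[int, int] = {}
    flat = raw.ravel()
    order = np.nonzero(flat)[0]
    for idx in order:
        lab = flat[idx]
        if lab not in remap:
            remap[lab] = len(remap) + 1
    if remap:
        lut = np.zeros(n + 1, dtype=raw.dtype)
        for old, new in remap.items():
            lut[old] = new
        labels = lut[raw]
    return PatchMap(
        labels=labels,
        neighbourhood=neighbourhood,
        cell_size=habitat.cell_size,
        origin=habitat.origin,
    )


def focal_patch_of(patches: PatchMap, site: SamplingSite) -> int:
    """Patch id of the habitat patch containing the sampling site."""
    col = int(round((site.x - patches.origin[0]) / patches.cell_size))
    row = int(round((patches.origin[1] - site.y) / patches.cell_size))
    nrow, ncol = patches.labels.shape
    if not (0 <= row < nrow and 0 <= col < ncol):
        raise InvalidInputError(f"site {site.site_id!r} outside raster extent")
    label = int(patches.labels[row, col])
    if label == 0:
        raise FocalPatchUndefinedError(
            f"site {site.site_id!r} does not fall on a habitat pixel"
        )
    return label


def _boundary_pixels(patches: PatchMap, patch_id: int) -> np.ndarray:
    """Pixels of a patch that touch a non-patch 4-neighbour (or the edge).

    The minimum inter-patch pixel distance is always attained at boundary
    pixels, so gap distances can be computed on this reduced set.
    """
    mask = patches.labels == patch_id
    interior = ndimage.binary_erosion(mask, structure=_STRUCTURES[4], border_value=0)
    return np.argwhere(mask & ~interior)


def patch_gap_distance(patches: PatchMap, a: int, b: int) -> float:
    """Edge-to-edge gap between two patches, in metres.

    Approximated on the raster as the minimum centre-to-centre distance
    between pixels of the two patches minus one cell width, floored at
    zero; symmetric in its arguments.
    """
    if a == b:
        raise InvalidInputError("gap distance requires two distinct patches")
    pa = _boundary_pixels(patches, a) * patches.cell_size
    pb = _boundary_pixels(patches, b) * patches.cell_size
    if len(pa) == 0 or len(pb) == 0:
        raise InvalidInputError("patch id not present in patch map")
    tree = cKDTree(pb)
    dmin = float(tree.query(pa, k=1)[0].min())
    return max(0.0, dmin - patches.cell_size)


def all_pairwise_gap_distances(patches: PatchMap) -> dict[tuple[int, int], float]:
    """Gap distances for every unordered pair of patches."""
    ids = patches.patch_ids
    boundaries = {i: _boundary_pixels(patches, i) * patches.cell_size for i in ids}
    trees = {i: cKDTree(boundaries[i]) for i in ids}
    out: dict[tuple[int, int], float] = {}
    for ix, a in enumerate(ids):
        for b in ids[ix + 1 :]:
            dmin = float(trees[b].query(boundaries[a], k=1)[0].min())
            out[(a, b)] = max(0.0, dmin - patches.cell_size)
    return out
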