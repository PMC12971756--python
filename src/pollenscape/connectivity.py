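"""Incidence-function-model connectivity metrics on raster landscapes.

The core quantity is the patch-connectivity sum

    S_i = sum_{j != i} exp(-alpha * d_ij) * A_j * p_j

redefined over 10 m raster cells: *i* is the sampling-site pixel, *j*
ranges over trapliner-habitat pixels, d_ij is the centre-to-centre
Euclidean distance, A_j = 1 (all cells equal area) and p_j encodes
gap-crossing behaviour of the patch containing *j*.  Three intra-patch
metrics and a 2 x 2 x 3 factorial of twelve local landscape metrics
(habitat definition x distance-weighting x gap-crossing mode) are
derived from this sum, all expressed in hectares of habitat.

Gap-crossing modes
------------------
unlimited      p = 1 everywhere: pollinators ignore non-forested gaps.
threshold      p = 1 only for patches whose 25 m buffers (edge-to-edge
               gap <= 50 m) connect them to the focal patch, directly or
               through stepping stones; p = 0 otherwise.
probabilistic  p = exp(-lambda * d_k), where d_k is the minimum summed
               gap distance from patch k to the focal patch and
               lambda = log(2)/50 halves the crossing odds per 50 m of
               open gap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .raster import (
    BROAD,
    NARROW,
    HabitatRaster,
    InvalidInputError,
    LandcoverRaster,
    PatchMap,
    SamplingSite,
    all_pairwise_gap_distances,
    classify_habitat,
    clip_local_landscape,
    focal_patch_of,
    label_patches,
)

# scales
INTRA_PATCH = "intra_patch"
LOCAL = "local"

# intra-patch variants
TOTAL_AREA = "total_area"
AREA_WITHIN_RADIUS = "area_within_radius"
DISTANCE_WEIGHTED = "distance_weighted"

# distance weighting
UNWEIGHTED = "unweighted"
KERNEL = "kernel"

# gap-crossing modes
UNLIMITED = "unlimited"
THRESHOLD = "threshold"
PROBABILISTIC = "probabilistic"

#: inverse mean home-range length of Phaethornis guy (282 m)
DEFAULT_ALPHA = 1.0 / 282.0
#: 50 % reduction in gap-crossing odds per 50 m of open gap
DEFAULT_LAMBDA = math.log(2.0) / 50.0
DEFAULT_GAP_THRESHOLD = 50.0
DEFAULT_BUFFER = 25.0
DEFAULT_RADIUS = 1000.0


@dataclass(frozen=True)
class MetricSpec:
    """Full parameterization of one connectivity metric."""

    scale: str
    variant: str | None = None  # intra-patch only
    habitat_def: str = NARROW
    weighting: str = UNWEIGHTED
    gap_mode: str = UNLIMITED
    alpha: float = DEFAULT_ALPHA
    lam: float = DEFAULT_LAMBDA
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    buffer: float = DEFAULT_BUFFER
    radius: float = DEFAULT_RADIUS
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.lam <= 0:
            raise InvalidInputError("alpha and lambda must be positive")
        if self.scale not in (INTRA_PATCH, LOCAL):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        if self.scale == INTRA_PATCH and self.habitat_def != NARROW:
            raise InvalidInputError("intra-patch metrics use the narrow habitat definition")

    @property
    def name(self) -> str:
        if self.scale == INTRA_PATCH:
            return f"intra:{self.variant}"
        return f"local:{self.habitat_def}:{self.weighting}:{self.gap_mode}"


@dataclass(frozen=True)
class MetricValue:
    """A computed metric in hectares, with any transform applied."""

    spec: MetricSpec
    site_id: str
    value_ha: float
    transformed: float


@dataclass
class PatchGraph:
    """Complete graph of pairwise edge-to-edge gap distances between patches."""

    nodes: dict[int, float]  # patch id -> area (ha)
    edges: dict[tuple[int, int], float]  # unordered pair -> gap (m)
    focal: int

    def gap(self, a: int, b: int) -> float:
        if a == b:
            return 0.0
        return self.edges[(a, b) if a < b else (b, a)]


def intra_patch_specs(**overrides) -> list[MetricSpec]:
    """The three intra-patch metric specifications."""
    return [
        MetricSpec(scale=INTRA_PATCH, variant=v, log_transform=True, **overrides)
        for v in (TOTAL_AREA, AREA_WITHIN_RADIUS, DISTANCE_WEIGHTED)
    ]


def local_specs(**overrides) -> list[MetricSpec]:
    """The full 2 x 2 x 3 factorial of local landscape metrics."""
    return [
        MetricSpec(
            scale=LOCAL, habitat_def=h, weighting=w, gap_mode=g, **overrides
        )
        for h, w, g in itertools.product(
            (NARROW, BROAD), (UNWEIGHTED, KERNEL), (UNLIMITED, THRESHOLD, PROBABILISTIC)
        )
    ]


def _maybe_log(value_ha: float, spec: MetricSpec) -> float:
    return math.log(value_ha) if spec.log_transform else value_ha


def focal_patch_area(
    patches_full_extent: PatchMap, focal: int, spec: MetricSpec, site_id: str = ""
) -> MetricValue:
    """Area (ha) of the entire focal patch, log-transformed.

    The one purely structural metric: it ignores the 1 km disk and uses
    the full raster extent.
    """
    if focal not in patches_full_extent.patch_areas:
        raise InvalidInputError(f"no patch with id {focal}")
    area = patches_full_extent.patch_areas[focal]
    return MetricValue(spec, site_id, area, _maybe_log(area, spec))


def _site_distances(habitat: HabitatRaster, site: SamplingSite) -> tuple[np.ndarray, np.ndarray]:
    """Habitat pixels (excluding the site pixel) and their distances to it."""
    srow, scol = site.pixel(habitat)
    pix = np.argwhere(habitat.grid == 1)
    keep = ~((pix[:, 0] == srow) & (pix[:, 1] == scol))
    pix = pix[keep]
    d = np.hypot(pix[:, 0] - srow, pix[:, 1] - scol) * habitat.cell_size
    return pix, d


def focal_patch_area_within_radius(
    habitat: HabitatRaster,
    site: SamplingSite,
    spec: MetricSpec,
    patches: PatchMap | None = None,
) -> MetricValue:
    """Area (ha) of the focal patch inside the 1 km disk, log-transformed.

    The focal patch is delineated on the full (unclipped) extent, then
    masked to pixels within the disk; the site pixel itself is excluded
    from the sum (j != i)."""
    if patches is None:
        patches = label_patches(habitat)
    focal = focal_patch_of(patches, site)
    pix, d = _site_distances(habitat, site)
    in_patch = patches.labels[pix[:, 0], pix[:, 1]] == focal
    n = int((in_patch & (d <= spec.radius)).sum())
    area = n * habitat.pixel_area_ha
    return MetricValue(spec, site.site_id, area, _maybe_log(area, spec))


def distance_weighted_focal_patch_area(
    habitat: HabitatRaster,
    site: SamplingSite,
    spec: MetricSpec,
    patches: PatchMap | None = None,
) -> MetricValue:
    """Kernel-weighted focal-patch area: sum exp(-alpha d_ij) over patch pixels.

    An elongated patch scores lower than a round patch of equal area
    because distant pixels contribute less.
    """
    if patches is None:
        patches = label_patches(habitat)
    focal = focal_patch_of(patches, site)
    pix, d = _site_distances(habitat, site)
    sel = (patches.labels[pix[:, 0], pix[:, 1]] == focal) & (d <= spec.radius)
    area = float(np.exp(-spec.alpha * d[sel]).sum()) * habitat.pixel_area_ha
    return MetricValue(spec, site.site_id, area, _maybe_log(area, spec))


def build_patch_graph(patches: PatchMap, focal: int) -> PatchGraph:
    """Materialize the complete gap-distance graph of a (clipped) patch map."""
    if not patches.patch_areas:
        raise InvalidInputError("patch map contains no patches")
    if focal not in patches.patch_areas:
        raise InvalidInputError(f"focal patch {focal} not in patch map")
    return PatchGraph(
        nodes=dict(patches.patch_areas),
        edges=all_pairwise_gap_distances(patches),
        focal=focal,
    )


def connected_patches_threshold(graph: PatchGraph, gap_threshold: float) -> set[int]:
    """Patches connected to the focal patch under the buffer-overlap rule.

    Two 25 m buffers overlap iff the edge-to-edge gap is <= 50 m; the
    component may be reached indirectly through stepping stones.
    """
    ids = sorted(graph.nodes)
    component = {graph.focal}
    frontier = [graph.focal]
    while frontier:
        a = frontier.pop()
        for b in ids:
            if b not in component and graph.gap(a, b) <= gap_threshold:
                component.add(b)
                frontier.append(b)
    return component


def min_summed_gap_distance(graph: PatchGraph) -> dict[int, float]:
    """Minimum summed gap distance d_k from every patch to the focal patch.

    Shortest paths on the complete gap graph: traversing habitat is free,
    only open gaps accumulate cost, so d_k <= the direct focal gap and
    stepping-stone routes can shorten it.
    """
    ids = sorted(graph.nodes)
    index = {p: i for i, p in enumerate(ids)}
    n = len(ids)
    if n == 1:
        return {graph.focal: 0.0}
    rows, cols, vals = [], [], []
    for (a, b), w in graph.edges.items():
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
        vals += [w, w]
    mat = csr_matrix((vals, (rows, cols)), shape=(n, n))
    # dijkstra treats explicit zeros as missing; nudge exact-zero gaps
    mat.data = np.maximum(mat.data, 1e-12)
    dist = dijkstra(mat, directed=False, indices=index[graph.focal])
    out = {p: float(dist[index[p]]) for p in ids}
    out = {p: (0.0 if d < 1e-9 else d) for p, d in out.items()}
    return out


def gap_crossing_probability(d_k: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Probability of crossing d_k metres of summed open gap: exp(-lambda d_k)."""
    if d_k < 0:
        raise InvalidInputError("gap distance must be non-negative")
    return math.exp(-lam * d_k)


def _patch_probabilities(graph: PatchGraph, spec: MetricSpec) -> dict[int, float]:
    if spec.gap_mode == UNLIMITED:
        return {p: 1.0 for p in graph.nodes}
    if spec.gap_mode == THRESHOLD:
        comp = connected_patches_threshold(graph, spec.gap_threshold)
        return {p: (1.0 if p in comp else 0.0) for p in graph.nodes}
    if spec.gap_mode == PROBABILISTIC:
        d = min_summed_gap_distance(graph)
        return {p: gap_crossing_probability(d[p], spec.lam) for p in graph.nodes}
    raise InvalidInputError(f"unknown gap mode {spec.gap_mode!r}")


def local_connectivity(
    habitat_clipped: HabitatRaster,
    site: SamplingSite,
    spec: MetricSpec,
    patches: PatchMap | None = None,
    graph: PatchGraph | None = None,
) -> MetricValue:
    """One local landscape connectivity metric S_i, in hectares.

    ``habitat_clipped`` must already be clipped to the local-landscape
    disk and classified under ``spec.habitat_def``.  ``patches`` and
    ``graph`` may be passed to reuse work across the factorial.
    """
    if spec.scale != LOCAL:
        raise InvalidInputError("local_connectivity requires a LOCAL-scale spec")
    if patches is None:
        patches = label_patches(habitat_clipped)
    focal = focal_patch_of(patches, site)
    if graph is None:
        graph = build_patch_graph(patches, focal)
    p_by_patch = _patch_probabilities(graph, spec)
    pix, d = _site_distances(habitat_clipped, site)
    labels = patches.labels[pix[:, 0], pix[:, 1]]
    lut = np.zeros(int(patches.labels.max()) + 1)
    for pid, prob in p_by_patch.items():
        lut[pid] = prob
    p = lut[labels]
    k = np.exp(-spec.alpha * d) if spec.weighting == KERNEL else 1.0
    value = float(np.sum(k * p)) * habitat_clipped.pixel_area_ha
    return MetricValue(spec, site.site_id, value, _maybe_log(value, spec))


def compute_metric_suite(
    landcover: LandcoverRaster,
    site: SamplingSite,
    *,
    alpha: float = DEFAULT_ALPHA,
    lam: float = DEFAULT_LAMBDA,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    radius: float = DEFAULT_RADIUS,
    neighbourhood: int = 8,
) -> list[MetricValue]:
    """All 15 metrics for one site: 3 intra-patch + the 12-metric factorial."""
    overrides = dict(alpha=alpha, lam=lam, gap_threshold=gap_threshold, radius=radius)
    out: list[MetricValue] = []

    narrow_full = classify_habitat(landcover, NARROW)
    patches_full = label_patches(narrow_full, neighbourhood)
    focal_full = focal_patch_of(patches_full, site)
    narrow_clip = clip_local_landscape(narrow_full, site, radius)

    i_total, i_radius, i_kernel = intra_patch_specs(**overrides)
    out.append(focal_patch_area(patches_full, focal_full, i_total, site.site_id))
    out.append(focal_patch_area_within_radius(narrow_full, site, i_radius, patches_full))
    out.append(distance_weighted_focal_patch_area(narrow_full, site, i_kernel, patches_full))

    clipped = {
        NARROW: narrow_clip,
        BROAD: clip_local_landscape(classify_habitat(landcover, BROAD), site, radius),
    }
    cache: dict[str, tuple[PatchMap, PatchGraph]] = {}
    for spec in local_specs(**overrides):
        if spec.habitat_def not in cache:
            patches = label_patches(clipped[spec.habitat_def], neighbourhood)
            focal = focal_patch_of(patches, site)
            cache[spec.habitat_def] = (patches, build_patch_graph(patches, focal))
        patches, graph = cache[spec.habitat_def]
        out.append(
            local_connectivity(clipped[spec.habitat_def], site, spec, patches, graph)
        )
    return out
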