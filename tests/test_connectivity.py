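"""Intra-patch and local landscape connectivity metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest

import _oracles
from conftest import M, P, habitat_from, landcover_from, site_at
from pollenscape.connectivity import (
    DEFAULT_ALPHA,
    DEFAULT_LAMBDA,
    INTRA_PATCH,
    KERNEL,
    LOCAL,
    PROBABILISTIC,
    THRESHOLD,
    UNLIMITED,
    UNWEIGHTED,
    MetricSpec,
    PatchGraph,
    build_patch_graph,
    compute_metric_suite,
    connected_patches_threshold,
    distance_weighted_focal_patch_area,
    focal_patch_area,
    focal_patch_area_within_radius,
    gap_crossing_probability,
    intra_patch_specs,
    local_connectivity,
    local_specs,
    min_summed_gap_distance,
)
from pollenscape.raster import (
    BROAD,
    InvalidInputError,
    NARROW,
    classify_habitat,
    label_patches,
)


def _intra_spec(variant, **kw):
    return MetricSpec(scale=INTRA_PATCH, variant=variant, log_transform=True, **kw)


def _local_spec(**kw):
    return MetricSpec(scale=LOCAL, **kw)


class TestSpecs:
    def test_three_intra_and_twelve_local(self):
        assert len(intra_patch_specs()) == 3
        specs = local_specs()
        assert len(specs) == 12
        combos = {(s.habitat_def, s.weighting, s.gap_mode) for s in specs}
        assert len(combos) == 12

    def test_intra_rejects_broad_habitat(self):
        with pytest.raises(InvalidInputError):
            MetricSpec(scale=INTRA_PATCH, variant="total_area", habitat_def=BROAD)

    def test_nonpositive_kernel_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            MetricSpec(scale=LOCAL, alpha=0.0)
        with pytest.raises(InvalidInputError):
            MetricSpec(scale=LOCAL, lam=-1.0)


class TestFocalPatchArea:
    def test_100_pixels_is_one_hectare_log_zero(self):
        habitat = habitat_from([[1] * 10] * 10)
        patches = label_patches(habitat)
        mv = focal_patch_area(patches, 1, _intra_spec("total_area"))
        assert mv.value_ha == pytest.approx(1.0)
        assert mv.transformed == pytest.approx(0.0)

    def test_1000_pixels_is_ten_hectares(self):
        habitat = habitat_from([[1] * 40] * 25)
        patches = label_patches(habitat)
        mv = focal_patch_area(patches, 1, _intra_spec("total_area"))
        assert mv.value_ha == pytest.approx(10.0)
        assert mv.transformed == pytest.approx(math.log(10.0))

    def test_single_pixel_patch(self):
        habitat = habitat_from([[1, 0], [0, 0]])
        patches = label_patches(habitat)
        mv = focal_patch_area(patches, 1, _intra_spec("total_area"))
        assert mv.value_ha == pytest.approx(0.01)
        assert mv.transformed == pytest.approx(math.log(0.01))


class TestAreaWithinRadius:
    def test_patch_inside_disk_equals_total_minus_site_pixel(self):
        habitat = habitat_from([[1] * 10] * 10)
        site = site_at(habitat, 5, 5)
        spec = _intra_spec("area_within_radius")
        mv = focal_patch_area_within_radius(habitat, site, spec)
        # the sampling pixel itself is excluded (j != i)
        assert mv.value_ha == pytest.approx(0.99)

    def test_patch_beyond_disk_is_clipped(self):
        habitat = habitat_from([[1] * 60], cell=10.0)
        site = site_at(habitat, 0, 0)
        spec = _intra_spec("area_within_radius", radius=200.0)
        mv = focal_patch_area_within_radius(habitat, site, spec)
        assert mv.value_ha < 0.6  # whole strip is 0.6 ha
        assert mv.value_ha == pytest.approx(0.20)  # 20 pixels at <= 200 m

    def test_matches_membership_and_distance_oracle(self, rng):
        grid = (rng.random((30, 30)) < 0.55).astype(np.uint8)
        grid[15, 15] = 1
        habitat = habitat_from(grid.tolist())
        site = site_at(habitat, 15, 15)
        spec = _intra_spec("area_within_radius", radius=100.0)
        mv = focal_patch_area_within_radius(habitat, site, spec)
        patches = label_patches(habitat)
        focal = patches.labels[15, 15]
        count = 0
        for r in range(30):
            for c in range(30):
                if (r, c) == (15, 15) or patches.labels[r, c] != focal:
                    continue
                if math.hypot(r - 15, c - 15) * 10.0 <= 100.0:
                    count += 1
        assert mv.value_ha == pytest.approx(count * 0.01)


class TestDistanceWeightedArea:
    def test_single_neighbour_at_10m(self):
        habitat = habitat_from([[1, 1]])
        site = site_at(habitat, 0, 0)
        mv = distance_weighted_focal_patch_area(habitat, site, _intra_spec("distance_weighted"))
        assert mv.value_ha == pytest.approx(0.01 * math.exp(-10.0 / 282.0), abs=1e-9)
        assert mv.value_ha == pytest.approx(0.009652, abs=5e-7)

    def test_ring_symmetry_common_factor(self):
        # 4-neighbour plus shape: every non-site pixel at exactly 10 m
        habitat = habitat_from([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        site = site_at(habitat, 1, 1)
        mv = distance_weighted_focal_patch_area(habitat, site, _intra_spec("distance_weighted"))
        assert mv.value_ha == pytest.approx(4 * 0.01 * math.exp(-10.0 * DEFAULT_ALPHA))

    def test_elongated_patch_scores_below_round_patch(self):
        round_hab = habitat_from([[1] * 5] * 5)
        mv_round = distance_weighted_focal_patch_area(
            round_hab, site_at(round_hab, 2, 2), _intra_spec("distance_weighted")
        )
        long_hab = habitat_from([[1] * 25])
        mv_long = distance_weighted_focal_patch_area(
            long_hab, site_at(long_hab, 0, 12), _intra_spec("distance_weighted")
        )
        assert mv_round.value_ha > mv_long.value_ha


class TestPatchGraph:
    def test_single_patch_graph(self):
        habitat = habitat_from([[1, 1]])
        patches = label_patches(habitat)
        graph = build_patch_graph(patches, 1)
        assert set(graph.nodes) == {1}
        assert graph.edges == {}

    def test_three_patches_three_symmetric_edges(self):
        habitat = habitat_from([[1, 0, 1], [0, 0, 0], [1, 0, 0]])
        patches = label_patches(habitat, neighbourhood=4)
        graph = build_patch_graph(patches, 1)
        assert len(graph.nodes) == 3
        assert len(graph.edges) == 3
        for a in graph.nodes:
            for b in graph.nodes:
                if a != b:
                    assert graph.gap(a, b) == graph.gap(b, a)

    def test_edge_weights_match_pixel_pair_oracle(self, rng):
        grid = (rng.random((20, 20)) < 0.3).astype(np.uint8)
        habitat = habitat_from(grid.tolist())
        patches = label_patches(habitat)
        if len(patches.patch_ids) >= 2:
            graph = build_patch_graph(patches, patches.patch_ids[0])
            for (a, b), got in graph.edges.items():
                want = _oracles.exhaustive_gap_distance(patches.labels, a, b, 10.0)
                assert got == pytest.approx(want)

    def test_missing_focal_rejected(self):
        habitat = habitat_from([[1]])
        patches = label_patches(habitat)
        with pytest.raises(InvalidInputError):
            build_patch_graph(patches, 99)


def _graph(nodes, edges, focal):
    return PatchGraph(nodes={n: 1.0 for n in nodes}, edges=dict(edges), focal=focal)


class TestThresholdComponent:
    def test_stepping_stone_chain(self):
        g = _graph([1, 2, 3], {(1, 2): 40.0, (2, 3): 45.0, (1, 3): 120.0}, focal=1)
        assert connected_patches_threshold(g, 50.0) == {1, 2, 3}

    def test_isolated_patch_excluded(self):
        g = _graph([1, 2], {(1, 2): 60.0}, focal=1)
        assert connected_patches_threshold(g, 50.0) == {1}

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            nodes = list(range(1, n + 1))
            edges = {
                (a, b): float(rng.uniform(0, 120))
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
            }
            g = _graph(nodes, edges, focal=1)
            got = connected_patches_threshold(g, 50.0)
            want = _oracles.reachable_within_threshold(nodes, edges, 1, 50.0)
            assert got == want


class TestMinSummedGap:
    def test_focal_distance_zero(self):
        g = _graph([1, 2], {(1, 2): 30.0}, focal=1)
        assert min_summed_gap_distance(g)[1] == 0.0

    def test_stepping_stone_shortens_route(self):
        g = _graph([1, 2, 3], {(1, 2): 30.0, (2, 3): 25.0, (1, 3): 80.0}, focal=1)
        assert min_summed_gap_distance(g)[3] == pytest.approx(55.0)

    def test_unused_patch_does_not_change_distances(self):
        g3 = _graph([1, 2, 3], {(1, 2): 30.0, (2, 3): 25.0, (1, 3): 80.0}, focal=1)
        g4 = _graph(
            [1, 2, 3, 4],
            {(1, 2): 30.0, (2, 3): 25.0, (1, 3): 80.0, (1, 4): 500.0, (2, 4): 500.0, (3, 4): 500.0},
            focal=1,
        )
        d3 = min_summed_gap_distance(g3)
        d4 = min_summed_gap_distance(g4)
        for p in (1, 2, 3):
            assert d4[p] == pytest.approx(d3[p])

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            nodes = list(range(1, n + 1))
            edges = {
                (a, b): float(rng.uniform(0, 100))
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
            }
            g = _graph(nodes, edges, focal=1)
            got = min_summed_gap_distance(g)
            want = _oracles.enumerate_min_summed_gap(nodes, edges, 1)
            for p in nodes:
                assert got[p] == pytest.approx(want[p]), (nodes, edges)

    def test_zero_gap_edges_are_traversable(self):
        g = _graph([1, 2, 3], {(1, 2): 0.0, (2, 3): 10.0, (1, 3): 40.0}, focal=1)
        d = min_summed_gap_distance(g)
        assert d[2] == 0.0
        assert d[3] == pytest.approx(10.0)


class TestGapCrossingProbability:
    def test_zero_gap_certain(self):
        assert gap_crossing_probability(0.0) == 1.0

    def test_half_at_50m(self):
        assert gap_crossing_probability(50.0) == pytest.approx(0.5)

    def test_quarter_at_100m(self):
        assert gap_crossing_probability(100.0) == pytest.approx(0.25)

    def test_negative_gap_rejected(self):
        with pytest.raises(InvalidInputError):
            gap_crossing_probability(-1.0)


class TestLocalConnectivity:
    #: focal block 10x4 (0.4 ha), 5 empty columns (gap 50 m), 10x20 block (2 ha)
    def _layout(self):
        row = [1] * 4 + [0] * 5 + [1] * 20
        habitat = habitat_from([row] * 10)
        return habitat, site_at(habitat, 5, 1)

    def test_unlimited_unweighted_counts_all_pixels(self):
        habitat, site = self._layout()
        mv = local_connectivity(habitat, site, _local_spec(weighting=UNWEIGHTED, gap_mode=UNLIMITED))
        assert mv.value_ha == pytest.approx((240 - 1) * 0.01)

    def test_probabilistic_halves_the_far_patch_at_gap_50(self):
        habitat, site = self._layout()
        mv = local_connectivity(
            habitat, site, _local_spec(weighting=UNWEIGHTED, gap_mode=PROBABILISTIC)
        )
        assert mv.value_ha == pytest.approx((40 - 1) * 0.01 + 0.5 * 2.0)

    def test_threshold_includes_patch_at_exactly_50(self):
        habitat, site = self._layout()
        mv = local_connectivity(habitat, site, _local_spec(weighting=UNWEIGHTED, gap_mode=THRESHOLD))
        assert mv.value_ha == pytest.approx((40 - 1) * 0.01 + 2.0)

    def test_kernel_weighting_discounts_by_distance(self):
        habitat, site = self._layout()
        unw = local_connectivity(habitat, site, _local_spec(weighting=UNWEIGHTED, gap_mode=UNLIMITED))
        ker = local_connectivity(habitat, site, _local_spec(weighting=KERNEL, gap_mode=UNLIMITED))
        assert ker.value_ha < unw.value_ha

    def test_intra_spec_rejected(self):
        habitat, site = self._layout()
        with pytest.raises(InvalidInputError):
            local_connectivity(habitat, site, _intra_spec("total_area"))


class TestMetricSuite:
    def _landscape(self):
        grid = [[P] * 30 for _ in range(30)]
        for r in range(5, 15):
            for c in range(5, 15):
                grid[r][c] = M
        for r in range(5, 15):
            for c in range(20, 28):
                grid[r][c] = M
        return landcover_from(grid)

    def test_fifteen_metrics_cover_factorial(self):
        lc = self._landscape()
        site = site_at(lc, 10, 10)
        suite = compute_metric_suite(lc, site)
        assert len(suite) == 15
        intra = [mv for mv in suite if mv.spec.scale == INTRA_PATCH]
        local = [mv for mv in suite if mv.spec.scale == LOCAL]
        assert len(intra) == 3 and len(local) == 12
        combos = {(mv.spec.habitat_def, mv.spec.weighting, mv.spec.gap_mode) for mv in local}
        assert len(combos) == 12

    def test_solid_block_collapses_gap_modes(self):
        grid = [[M] * 20 for _ in range(20)]
        lc = landcover_from(grid)
        site = site_at(lc, 10, 10)
        suite = {mv.spec.name: mv.value_ha for mv in compute_metric_suite(lc, site)}
        for habitat_def in (NARROW, BROAD):
            for weighting in (UNWEIGHTED, KERNEL):
                vals = [
                    suite[f"local:{habitat_def}:{weighting}:{mode}"]
                    for mode in (UNLIMITED, THRESHOLD, PROBABILISTIC)
                ]
                assert max(vals) == pytest.approx(min(vals))

    def test_dominance_on_fixed_landscape(self):
        lc = self._landscape()
        suite = {mv.spec.name: mv.value_ha for mv in compute_metric_suite(lc, site_at(lc, 10, 10))}
        for habitat_def in (NARROW, BROAD):
            for weighting in (UNWEIGHTED, KERNEL):
                base = f"local:{habitat_def}:{weighting}"
                assert suite[f"{base}:unlimited"] >= suite[f"{base}:threshold"] - 1e-12
                assert suite[f"{base}:unlimited"] >= suite[f"{base}:probabilistic"] - 1e-12
            for mode in (UNLIMITED, THRESHOLD, PROBABILISTIC):
                assert (
                    suite[f"local:{habitat_def}:unweighted:{mode}"]
                    >= suite[f"local:{habitat_def}:kernel:{mode}"] - 1e-12
                )
        for weighting in (UNWEIGHTED, KERNEL):
            for mode in (UNLIMITED, THRESHOLD, PROBABILISTIC):
                assert (
                    suite[f"local:broad:{weighting}:{mode}"]
                    >= suite[f"local:narrow:{weighting}:{mode}"] - 1e-12
                )

    def test_lambda_limits(self):
        lc = self._landscape()
        site = site_at(lc, 10, 10)
        tiny = {mv.spec.name: mv.value_ha for mv in compute_metric_suite(lc, site, lam=1e-9)}
        huge = {mv.spec.name: mv.value_ha for mv in compute_metric_suite(lc, site, lam=1e3)}
        # lambda -> 0: gaps become free, probabilistic recovers unlimited
        assert tiny["local:narrow:unweighted:probabilistic"] == pytest.approx(
            tiny["local:narrow:unweighted:unlimited"], rel=1e-6
        )
        # lambda -> inf: any gap is impassable, only the focal patch remains
        narrow = classify_habitat(lc, NARROW)
        patches = label_patches(narrow)
        focal = patches.labels[10, 10]
        focal_ha = (np.count_nonzero(patches.labels == focal) - 1) * 0.01
        assert huge["local:narrow:unweighted:probabilistic"] == pytest.approx(focal_ha, rel=1e-6)
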