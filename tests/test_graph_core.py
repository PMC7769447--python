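"""Threshold graphs, components, covering counts and link-count matrices."""

import numpy as np
import pytest

from patchconn import (
    all_pairs_link_counts,
    build_threshold_graph,
    components,
    components_covering,
)
from patchconn.errors import ThresholdExceedsCutoffError
from patchconn.graph_core import ComponentPartition

from conftest import brute_iic_num, make_edge_list, random_graph

TRIANGLE_EDGES = [(1, 2, 10.0), (2, 3, 10.0), (1, 3, 20.0)]
AREAS = {1: 100.0, 2: 200.0, 3: 300.0}


class TestBuildThresholdGraph:
    @pytest.mark.parametrize(
        "d, expected_links",
        [
            (10.0, {frozenset({1, 2}), frozenset({2, 3})}),
            (5.0, set()),
            (20.0, {frozenset({1, 2}), frozenset({2, 3}), frozenset({1, 3})}),
        ],
        ids=["mid", "below", "inclusive-boundary"],
    )
    def test_link_pruning_inclusive(self, d, expected_links):
        edges = make_edge_list(TRIANGLE_EDGES, cutoff=25.0)
        g = build_threshold_graph(AREAS, edges, d)
        assert g.links() == expected_links
        assert g.nl == len(expected_links)

    def test_threshold_beyond_cutoff_rejected(self):
        edges = make_edge_list(TRIANGLE_EDGES, cutoff=25.0)
        with pytest.raises(ThresholdExceedsCutoffError):
            build_threshold_graph(AREAS, edges, 30.0)


class TestComponents:
    def test_no_links_all_singletons(self):
        g = build_threshold_graph(AREAS, make_edge_list([], 10.0), 5.0)
        assert components(g).nc == 3

    def test_path_single_component(self):
        edges = make_edge_list([(1, 2, 1.0), (2, 3, 1.0)], 10.0)
        g = build_threshold_graph(AREAS, edges, 5.0)
        assert components(g).nc == 1

    def test_component_areas(self):
        areas = {i: float(i) for i in range(1, 6)}
        edges = make_edge_list([(1, 2, 1.0), (4, 5, 1.0)], 10.0)
        part = components(build_threshold_graph(areas, edges, 5.0))
        assert part.nc == 3
        assert sorted(part.areas) == pytest.approx([3.0, 3.0, 9.0])
        assert sum(part.areas) == pytest.approx(sum(areas.values()))


class TestComponentsCovering:
    @pytest.mark.parametrize(
        "areas, p, expected",
        [
            ([60, 25, 15], 0.5, 1),
            ([40, 30, 20, 10], 0.5, 2),
            ([50, 50], 0.5, 2),  # strict "exceeds"
            ([10, 10, 10, 10], 1.0, 4),
        ],
        ids=["majority-single", "two-needed", "tie-strict", "p-one"],
    )
    def test_examples(self, areas, p, expected):
        part = ComponentPartition(
            members=[[i] for i in range(len(areas))],
            areas=[float(a) for a in areas],
            labels={i: i for i in range(len(areas))},
        )
        assert components_covering(part, p) == expected

    def test_invalid_p(self):
        part = ComponentPartition([[0]], [1.0], {0: 0})
        with pytest.raises(ValueError):
            components_covering(part, 0.0)

    def test_non_increasing_under_merging(self, rng):
        # merging components (coarser partition) cannot raise the count
        for _ in range(20):
            n = int(rng.integers(3, 12))
            areas = rng.uniform(1, 50, n).tolist()
            fine = ComponentPartition(
                [[i] for i in range(n)], areas, {i: i for i in range(n)}
            )
            merged_areas = [areas[0] + areas[1]] + areas[2:]
            coarse = ComponentPartition(
                [[0, 1]] + [[i] for i in range(2, n)],
                merged_areas,
                {0: 0, 1: 0, **{i: i - 1 for i in range(2, n)}},
            )
            for p in (0.3, 0.5, 0.8):
                assert components_covering(coarse, p) <= components_covering(fine, p)


class TestAllPairsLinkCounts:
    def test_path_graph(self):
        edges = make_edge_list([(1, 2, 1.0), (2, 3, 1.0)], 10.0)
        nl = all_pairs_link_counts(build_threshold_graph(AREAS, edges, 5.0))
        assert nl.nl(1, 1) == 0
        assert nl.nl(1, 2) == 1
        assert nl.nl(1, 3) == 2

    def test_unreachable_is_none(self):
        g = build_threshold_graph({1: 1.0, 2: 1.0}, make_edge_list([], 10.0), 5.0)
        assert all_pairs_link_counts(g).nl(1, 2) is None

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(5):
            g, areas_ha, links = random_graph(rng, n_max=30)
            nl = all_pairs_link_counts(g)
            ids = sorted(areas_ha)
            pos = {i: k for k, i in enumerate(ids)}
            n = len(ids)
            dist = np.full((n, n), np.inf)
            np.fill_diagonal(dist, 0.0)
            for a, b in links:
                dist[pos[a], pos[b]] = dist[pos[b], pos[a]] = 1.0
            for k in range(n):
                dist = np.minimum(dist, dist[:, k][:, None] + dist[k, :][None, :])
            for i in ids:
                for j in ids:
                    exp = dist[pos[i], pos[j]]
                    got = nl.nl(i, j)
                    if np.isinf(exp):
                        assert got is None
                    else:
                        assert got == int(exp)


class TestCoveringCountProperty:
    from hypothesis import given, settings, strategies as st

    @given(
        areas=st.lists(st.floats(0.01, 1e4, allow_nan=False), min_size=1, max_size=30),
        p=st.floats(0.05, 1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_matches_naive_accumulation(self, areas, p):
        """The covering count equals a naive sort-and-accumulate oracle."""
        part = ComponentPartition(
            [[i] for i in range(len(areas))], list(areas),
            {i: i for i in range(len(areas))},
        )
        got = components_covering(part, p)
        total = sum(areas)
        acc, k = 0.0, 0
        for a in sorted(areas, reverse=True):
            acc += a
            k += 1
            if acc > p * total:
                break
        assert got == k
        assert 1 <= got <= len(areas)


def test_monotonicity_in_threshold(rng):
    """NL never falls and NC never rises as the dispersal distance grows."""
    from patchconn import LandscapeConfig, generate_landscape, pairwise_edge_distances

    cfg = LandscapeConfig(n_patches=150, extent=(4000.0, 4000.0), max_ha=30.0, seed=5)
    layer, _ = generate_landscape(cfg)
    edges = pairwise_edge_distances(layer, cutoff=1000)
    prev_nl, prev_nc = -1, np.inf
    for d in [2, 20, 44, 100, 1000]:
        g = build_threshold_graph(layer.area_map(), edges, d)
        part = components(g)
        assert g.nl >= prev_nl
        assert part.nc <= prev_nc
        assert components_covering(part, 0.5) <= part.nc
        assert sum(part.areas) == pytest.approx(float(layer.areas.sum()))
        prev_nl, prev_nc = g.nl, part.nc
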