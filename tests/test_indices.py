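"""IIC, node-removal importance and the intra/flux/connector partition.

The frozen expected values for the 3-patch path come from exhaustive pair
enumeration: with unit areas, iic_num = 3·1 + 4·(1/2) + 2·(1/3) = 17/3, and
removing the middle node leaves iic_num(G−2) = 2 (two isolated unit patches),
so dIIC_2 = 100·(17/3 − 2)/(17/3) = 1100/17 %.
"""

import numpy as np
import pandas as pd
import pytest

from patchconn import build_threshold_graph, fraction_profile, iic, node_importance
from patchconn.errors import SinglePatchError

from conftest import brute_iic_num, make_edge_list, random_graph


def path3(area_ha=1.0):
    areas = {i: area_ha * 1e4 for i in (1, 2, 3)}
    edges = make_edge_list([(1, 2, 1.0), (2, 3, 1.0)], 10.0)
    return build_threshold_graph(areas, edges, 5.0)


class TestIIC:
    def test_single_patch_whole_landscape(self):
        g = build_threshold_graph({1: 2e4}, make_edge_list([], 10.0), 5.0)
        res = iic(g, a_l=2.0)
        assert res.iic_num == pytest.approx(4.0)
        assert res.iic == pytest.approx(1.0)

    def test_two_isolated_patches(self):
        g = build_threshold_graph({1: 1e4, 2: 1e4}, make_edge_list([], 10.0), 5.0)
        res = iic(g, a_l=2.0)
        assert res.iic_num == pytest.approx(2.0)
        assert res.iic == pytest.approx(0.5)

    def test_path3_exhaustive_value(self):
        res = iic(path3())
        assert res.iic_num == pytest.approx(17 / 3, rel=1e-12)
        assert res.iic is None

    def test_normalization_requires_positive_al(self):
        with pytest.raises(ValueError):
            iic(path3(), a_l=0.0)

    def test_habitat_exceeding_landscape_warns(self):
        with pytest.warns(UserWarning):
            iic(path3(), a_l=1.0)  # 3 ha of habitat in a 1-ha landscape

    def test_closed_form_limits(self, rng):
        # edgeless: sum of squares; complete: sum sq + half the cross terms
        a = rng.uniform(0.5, 4.0, 8)
        areas = {i + 1: v * 1e4 for i, v in enumerate(a)}
        empty = build_threshold_graph(areas, make_edge_list([], 10.0), 5.0)
        assert iic(empty).iic_num == pytest.approx(np.sum(a**2), rel=1e-12)
        full_pairs = [(i, j, 1.0) for i in range(1, 9) for j in range(i + 1, 9)]
        full = build_threshold_graph(areas, make_edge_list(full_pairs, 10.0), 5.0)
        cross = np.sum(np.outer(a, a)) - np.sum(a**2)
        assert iic(full).iic_num == pytest.approx(np.sum(a**2) + cross / 2, rel=1e-12)

    def test_monotone_in_threshold(self):
        areas = {1: 1e4, 2: 2e4, 3: 3e4, 4: 1e4}
        edges = make_edge_list(
            [(1, 2, 5.0), (2, 3, 20.0), (3, 4, 80.0)], cutoff=100.0
        )
        nums = [
            iic(build_threshold_graph(areas, edges, d)).iic_num
            for d in (2, 10, 30, 100)
        ]
        assert all(b >= a for a, b in zip(nums, nums[1:]))


class TestNodeImportance:
    def test_path3_worked_example(self):
        table = node_importance(path3()).set_index("patch_id")
        mid = table.loc[2]
        assert mid["dIIC"] == pytest.approx(100 * 11 / 17, rel=1e-12)
        assert mid["dIIC_intra"] == pytest.approx(300 / 17, rel=1e-12)
        assert mid["dIIC_flux"] == pytest.approx(600 / 17, rel=1e-12)
        assert mid["dIIC_connector"] == pytest.approx(200 / 17, rel=1e-12)
        # leaves are no stepping stones
        assert table.loc[1, "dIIC_connector"] == 0.0
        assert table.loc[3, "dIIC_connector"] == 0.0
        assert table.loc[2, "rank"] == 1
        assert table.loc[2, "normalized_rank"] == pytest.approx(1.0)

    def test_isolated_patch_importance_is_intra(self):
        areas = {1: 1e4, 2: 2e4, 3: 3e4}
        edges = make_edge_list([(1, 2, 1.0)], 10.0)
        table = node_importance(
            build_threshold_graph(areas, edges, 5.0)
        ).set_index("patch_id")
        iso = table.loc[3]
        assert iso["dIIC_flux"] == 0.0
        assert iso["dIIC_connector"] == 0.0
        assert iso["dIIC"] == pytest.approx(iso["dIIC_intra"])

    def test_single_patch_rejected(self):
        g = build_threshold_graph({1: 1e4}, make_edge_list([], 10.0), 5.0)
        with pytest.raises(SinglePatchError):
            node_importance(g)

    def test_partition_identity_and_removal_oracle(self, rng):
        """intra+flux+connector == dIIC == 100·(IIC − IIC(G−k))/IIC, recomputed
        from scratch with an exhaustive Floyd–Warshall oracle."""
        for _ in range(15):
            g, areas_ha, links = random_graph(rng, n_max=40)
            table = node_importance(g)
            iic_full = brute_iic_num(areas_ha, links)
            assert iic(g).iic_num == pytest.approx(iic_full, rel=1e-9)
            for _, row in table.iterrows():
                k = int(row["patch_id"])
                rest = {i: a for i, a in areas_ha.items() if i != k}
                kept = [l for l in links if k not in l]
                expected = 100 * (iic_full - brute_iic_num(rest, kept)) / iic_full
                assert row["dIIC"] == pytest.approx(expected, rel=1e-9, abs=1e-12)
                parts = row["dIIC_intra"] + row["dIIC_flux"] + row["dIIC_connector"]
                assert parts == pytest.approx(row["dIIC"], rel=1e-9, abs=1e-12)

    def test_al_invariance(self, rng):
        g, _, _ = random_graph(rng, n_max=25)
        t1 = node_importance(g, a_l=None)
        t2 = node_importance(g, a_l=12345.0)
        cols = ["dIIC", "dIIC_intra", "dIIC_flux", "dIIC_connector"]
        pd.testing.assert_frame_equal(t1[cols], t2[cols])

    def test_rank_tiebreak_descending_area_then_id(self):
        # two equal isolated patches: equal dIIC, tie broken by id
        areas = {5: 1e4, 3: 1e4}
        table = node_importance(
            build_threshold_graph(areas, make_edge_list([], 10.0), 5.0)
        )
        assert table.iloc[0]["patch_id"] == 3
        assert table.iloc[0]["rank"] == 1


class TestFractionProfile:
    def test_path3_middle_node_shares(self):
        table = node_importance(path3())
        # per-patch shares for the middle node: (3, 6, 2)/11
        prof = fraction_profile({5.0: table.set_index("patch_id").loc[[2]].reset_index()})
        assert prof.iloc[0]["intra_share"] == pytest.approx(300 / 11)
        assert prof.iloc[0]["flux_share"] == pytest.approx(600 / 11)
        assert prof.iloc[0]["connector_share"] == pytest.approx(200 / 11)

    def test_no_links_all_intra(self):
        areas = {1: 1e4, 2: 3e4}
        table = node_importance(
            build_threshold_graph(areas, make_edge_list([], 10.0), 5.0)
        )
        prof = fraction_profile({5.0: table})
        assert prof.iloc[0]["intra_share"] == pytest.approx(100.0)
        assert prof.iloc[0]["flux_share"] == 0.0

    def test_two_connected_equal_patches(self):
        areas = {1: 1e4, 2: 1e4}
        table = node_importance(
            build_threshold_graph(areas, make_edge_list([(1, 2, 1.0)], 10.0), 5.0)
        )
        prof = fraction_profile({5.0: table})
        # per patch: intra = a², flux = 2·a²/2 = a² → shares (50, 50, 0)
        assert prof.iloc[0]["intra_share"] == pytest.approx(50.0)
        assert prof.iloc[0]["flux_share"] == pytest.approx(50.0)
        assert prof.iloc[0]["connector_share"] == 0.0

    def test_shares_sum_to_100_per_threshold(self, rng):
        tables = {}
        for d in (1.0, 2.0):
            g, _, _ = random_graph(rng, n_max=30)
            tables[d] = node_importance(g)
        prof = fraction_profile(tables)
        sums = prof[["intra_share", "flux_share", "connector_share"]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, rtol=1e-9)
        assert prof["threshold"].is_monotonic_increasing
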