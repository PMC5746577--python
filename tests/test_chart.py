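import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgchart.chart import (MapperChart, TopologicalChart, annotate_groups,
                            build_chart, build_cover, cluster_preimage,
                            decompose_chart, knn_filter,
                            planted_three_arm_cloud)

from _oracles import brute_mapper, naive_ward


class TestKnnFilter:
    def test_three_points_on_a_line(self):
        fv = knn_filter(np.array([[0.0], [1.0], [3.0]]), k=2)
        assert np.allclose(fv, [1.0, 1.0, 2.0])

    def test_duplicated_pair_gives_zero(self):
        fv = knn_filter(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]), k=2)
        assert fv[0] == 0.0 and fv[1] == 0.0

    def test_equilateral_triangle(self):
        s = 2.0
        pts = np.array([[0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]])
        assert np.allclose(knn_filter(pts, k=2), s)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            knn_filter(np.array([[0.0]]), k=2)


class TestCover:
    def test_worked_example(self):
        cov = build_cover([0.0, 3.0], 3, 50.0)
        assert [(c.low, c.high) for c in cov] == [(0.0, 1.5), (0.75, 2.25),
                                                 (1.5, 3.0)]

    def test_single_interval(self):
        cov = build_cover([2.0, 5.0], 1, 50.0)
        assert len(cov) == 1
        assert (cov[0].low, cov[0].high) == (2.0, 5.0)

    def test_fifty_percent_overlap_shares_half(self):
        for mi in (2, 4, 7):
            cov = build_cover([0.0, 10.0], mi, 50.0)
            for a, b in zip(cov, cov[1:]):
                shared = a.high - b.low
                assert shared == pytest.approx((a.high - a.low) / 2.0)

    def test_degenerate_range(self):
        cov = build_cover([1.0, 1.0, 1.0], 3, 50.0)
        assert len(cov) == 1 and cov[0].low == cov[0].high == 1.0

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            build_cover([0.0, 1.0], 3, 100.0)

    @settings(derandomize=True, max_examples=60)
    @given(lo=st.floats(-50, 50), width=st.floats(0.01, 100),
           mi=st.integers(1, 10), mo=st.floats(0, 90))
    def test_cover_construction_properties(self, lo, width, mi, mo):
        """First interval starts at min, last ends at max, all lengths
        equal, consecutive overlap fraction matches MO."""
        cov = build_cover([lo, lo + width], mi, mo)
        assert cov[0].low == pytest.approx(lo)
        assert cov[-1].high == pytest.approx(lo + width)
        lengths = [c.high - c.low for c in cov]
        assert np.allclose(lengths, lengths[0], rtol=1e-9)
        for a, b in zip(cov, cov[1:]):
            overlap = a.high - b.low
            assert overlap == pytest.approx(lengths[0] * mo / 100.0,
                                            abs=1e-9 * max(1.0, width))

    def test_extremal_point_always_covered(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            fv = rng.uniform(0, 1, 17)
            cov = build_cover(fv, 8, 50.0)
            assert any(c.contains(np.array([fv.max()]))[0] for c in cov)


class TestClusterPreimage:
    def test_two_separated_blobs(self):
        pts = np.array([[0.0], [0.1], [0.2], [10.0], [10.1]])
        clusters = cluster_preimage(pts)
        member_sets = {frozenset(c.tolist()) for c in clusters}
        assert member_sets == {frozenset({0, 1, 2}), frozenset({3, 4})}

    def test_single_point(self):
        assert [c.tolist() for c in cluster_preimage(np.array([[1.0]]))] \
            == [[0]]

    def test_identical_points_one_cluster(self):
        clusters = cluster_preimage(np.ones((6, 2)))
        assert len(clusters) == 1 and len(clusters[0]) == 6

    def test_smooth_chain_stays_whole(self):
        # evenly spaced chain: internal Ward height growth is not a gap
        pts = np.linspace(0, 1, 12)[:, None]
        assert len(cluster_preimage(pts)) == 1


class TestBuildChart:
    def test_identical_points_single_node(self):
        chart = build_chart(np.ones((7, 3)))
        assert len(chart.nodes) == 1
        assert len(chart.nodes[0].members) == 7

    def test_separated_blobs_give_disconnected_components(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, size=(8, 2))
        b = rng.normal(20.0, 0.4, size=(8, 2))  # distinct filter scale too
        chart = build_chart(np.vstack([a, b]), n_intervals=3)
        deco = decompose_chart(chart)
        assert deco.n_components >= 2

    def test_no_feature_in_more_than_two_nodes_at_fifty_percent(self):
        X, _ = planted_three_arm_cloud(seed=3)
        chart = build_chart(X, n_intervals=5, overlap_pct=50.0)
        assert max(chart.member_node_counts().values()) <= 2

    def test_edge_weight_equals_shared_member_count(self):
        X, _ = planted_three_arm_cloud(seed=2)
        chart = build_chart(X, n_intervals=4)
        members = {n.id: set(n.members) for n in chart.nodes}
        intervals = {n.id: n.interval for n in chart.nodes}
        for u, v, w in chart.edges:
            assert w == len(members[u] & members[v]) >= 1
            assert abs(intervals[u] - intervals[v]) == 1

    def test_graphml_and_json_roundtrip(self, tmp_path):
        X, _ = planted_three_arm_cloud(seed=1)
        chart = build_chart(X)
        annotate_groups(chart)
        chart.write_graphml(tmp_path / "chart.graphml")
        chart.write_json(tmp_path / "chart.json")
        back = TopologicalChart.from_json(tmp_path / "chart.json")
        assert [n.members for n in back.nodes] == \
            [n.members for n in chart.nodes]
        assert back.edges == chart.edges
        assert back.groups == chart.groups


class TestDecompose:
    @staticmethod
    def _chart_from_graph(n_nodes, edges):
        from emgchart.chart import MapperNode
        nodes = [MapperNode(i, (f"f{i}",), 0, 0.0) for i in range(n_nodes)]
        return TopologicalChart(nodes, [(u, v, 1) for u, v in edges], {})

    def test_path_graph_is_one_arm_no_core(self):
        chart = self._chart_from_graph(4, [(0, 1), (1, 2), (2, 3)])
        deco = decompose_chart(chart)
        assert deco.n_components == 1
        assert deco.cores[0] == []
        assert len(deco.arms[0]) == 1

    def test_star_with_three_chains(self):
        edges = [(0, 1), (1, 2), (0, 3), (3, 4), (0, 5), (5, 6)]
        deco = decompose_chart(self._chart_from_graph(7, edges))
        assert deco.cores[0] == [0]
        assert len(deco.arms[0]) == 3

    def test_isolated_node_has_no_arms(self):
        deco = decompose_chart(self._chart_from_graph(1, []))
        assert deco.n_components == 1
        assert deco.arms[0] == []

    def test_components_sorted_by_size(self):
        edges = [(0, 1), (1, 2), (3, 4)]
        deco = decompose_chart(self._chart_from_graph(6, edges))
        sizes = [len(c) for c in deco.components]
        assert sizes == sorted(sizes, reverse=True)


class TestOracleEquivalence:
    def test_naive_ward_heights_match_scipy(self):
        from scipy.cluster.hierarchy import linkage
        rng = np.random.default_rng(0)
        for _ in range(10):
            pts = rng.standard_normal((rng.integers(3, 10), 2))
            h_ref, _ = naive_ward(pts)
            h_scipy = linkage(pts, method="ward")[:, 2]
            assert np.allclose(np.sort(h_ref), np.sort(h_scipy), atol=1e-9)

    def test_mapper_matches_brute_force_on_small_clouds(self):
        """Node-for-node and edge-for-edge agreement with an independent
        enumeration-based Mapper on >= 20 random clouds of <= 12 points."""
        rng = np.random.default_rng(99)
        for trial in range(25):
            n = int(rng.integers(4, 13))
            dim = int(rng.integers(1, 4))
            X = rng.standard_normal((n, dim)) * rng.uniform(0.5, 3.0)
            mi = int(rng.integers(1, 5))
            chart = build_chart(X, n_intervals=mi, overlap_pct=50.0)
            fv_ref, nodes_ref, edges_ref = brute_mapper(
                X, n_intervals=mi, overlap_pct=50.0)
            got_nodes = sorted(
                (node.interval, frozenset(int(m[1:]) for m in node.members))
                for node in chart.nodes)
            assert got_nodes == sorted(nodes_ref), f"trial {trial}"
            node_key = {n_id: (node.interval,
                               frozenset(int(m[1:]) for m in node.members))
                        for n_id, node in enumerate(chart.nodes)}
            got_edges = sorted(
                (tuple(sorted((node_key[u], node_key[v]))), w)
                for u, v, w in chart.edges)
            ref_key = {i: nodes_ref[i] for i in range(len(nodes_ref))}
            ref_edges = sorted(
                (tuple(sorted((ref_key[u], ref_key[v]))), w)
                for (u, v), w in edges_ref.items())
            assert got_edges == ref_edges, f"trial {trial}"


class TestPlantedStructure:
    def test_three_arm_cloud_charts_as_y(self):
        X, _ = planted_three_arm_cloud(seed=0)
        deco = decompose_chart(build_chart(X, n_intervals=3,
                                           overlap_pct=50.0))
        assert deco.n_components == 1
        assert len(deco.cores[0]) == 1
        assert len(deco.arms[0]) == 3

    def test_refining_cover_preserves_arm_co_membership(self):
        """More intervals give more nodes but the same qualitative shape:
        points planted in one arm stay in one connected component."""
        X, labels = planted_three_arm_cloud(seed=0)
        coarse = build_chart(X, n_intervals=3, overlap_pct=50.0)
        fine = build_chart(X, n_intervals=8, overlap_pct=50.0)
        assert len(fine.nodes) >= len(coarse.nodes)
        deco = decompose_chart(fine)
        comp_of_node = {n: ci for ci, comp in enumerate(deco.components)
                        for n in comp}
        point_comps: dict[int, set] = {}
        for node in fine.nodes:
            for m in node.members:
                point_comps.setdefault(int(m[1:]), set()).add(
                    comp_of_node[node.id])
        for arm in "ABC":
            comps = set().union(*(point_comps[i]
                                  for i, lab in enumerate(labels)
                                  if lab == arm))
            assert len(comps) == 1, f"arm {arm} split across components"


class TestAnnotation:
    def test_auto_groups_partition_all_nodes(self):
        X, _ = planted_three_arm_cloud(seed=0)
        chart = build_chart(X, n_intervals=3)
        annotate_groups(chart)
        assert set(chart.groups) == {n.id for n in chart.nodes}

    def test_estimator_interface(self):
        X, _ = planted_three_arm_cloud(seed=0)
        est = MapperChart(n_intervals=3).fit(X)
        assert est.graph_.number_of_nodes() == len(est.chart_.nodes)
        params = est.get_params()
        assert params["n_intervals"] == 3 and params["k"] == 2
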