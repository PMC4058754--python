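import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agdist import (
    AttributedGraph,
    NormalizationConstants,
    SpatialConfig,
    WeightVector,
    graph_distance,
    node_cost_matrix,
    node_distance,
    pairwise_distances,
    profile_distance,
    solve_assignment,
    spatial_component,
    toy_graph_pair,
    training_constants,
)
from agdist.distance import read_distance_matrix, write_distance_matrix
from agdist.network import NodeSignature


def brute_force_assignment(c: np.ndarray) -> float:
    """Exhaustive minimum over all injections of rows into columns."""
    rows, cols = c.shape
    best = math.inf
    for perm in itertools.permutations(range(cols), rows):
        best = min(best, sum(c[i, p] for i, p in enumerate(perm)))
    return best


def sig(degree=0.0, nd=(), power=0.0, npow=(), coord=(0, 0, 0)):
    return NodeSignature(
        degree=degree,
        neighbor_degrees=np.array(sorted(nd, reverse=True), float),
        power=power,
        neighbor_powers=np.array(sorted(npow, reverse=True), float),
        coord=np.array(coord, float),
    )


class TestTrainingConstants:
    def test_maxima_over_graphs(self):
        g1, g2, _, (max_deg, max_pow) = toy_graph_pair(0)
        nc = training_constants([g1, g2])
        assert nc.max_degree == pytest.approx(max_deg)
        assert nc.max_power == pytest.approx(max_pow)

    def test_zero_degree_guard(self):
        g1, _, _, _ = toy_graph_pair(0)
        edgeless = AttributedGraph(g1.subject_id, g1.nodes, [])
        from agdist import compute_signature

        edgeless.signatures = {
            n.node_id: compute_signature(edgeless, n.node_id) for n in edgeless.nodes
        }
        nc = training_constants([edgeless])
        assert nc.max_degree == 1.0  # guarded
        assert nc.max_power == pytest.approx(0.9)

    def test_no_nodes_rejected(self):
        with pytest.raises(ValueError):
            training_constants([])


class TestSpatialComponent:
    def test_zero_distance_floor(self):
        assert spatial_component([1, 2, 3], [1, 2, 3]) == pytest.approx(1 / 301)

    def test_half_maximum_at_4ln300(self):
        x = 4 * math.log(300)
        assert spatial_component([0, 0, 0], [x, 0, 0]) == pytest.approx(0.5)

    def test_saturates_to_one(self):
        assert spatial_component([0, 0, 0], [1e4, 0, 0]) == pytest.approx(1.0)

    def test_strictly_increasing(self):
        gaps = np.linspace(0, 100, 200)
        vals = [spatial_component([0, 0, 0], [g, 0, 0]) for g in gaps]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_printed_variant_decreases(self):
        cfg = SpatialConfig(printed_variant=True)
        near = spatial_component([0, 0, 0], [0, 0, 0], cfg)
        far = spatial_component([0, 0, 0], [50, 0, 0], cfg)
        assert near == pytest.approx(1 / 301)
        assert far < near


class TestProfileDistance:
    def test_identical_lists(self):
        assert profile_distance([3, 2, 1], [3, 2, 1], 5.0) == 0.0

    def test_zero_padding_hand_value(self):
        assert profile_distance([2, 1], [], 2.0) == pytest.approx(0.75)

    def test_extreme_case(self):
        assert profile_distance([2.0], [0.0], 2.0) == 1.0

    def test_both_empty(self):
        assert profile_distance([], [], 1.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 5), max_size=8),
        st.lists(st.floats(0, 5), max_size=8),
    )
    def test_bounded_and_symmetric(self, a, b):
        a = sorted(a, reverse=True)
        b = sorted(b, reverse=True)
        d = profile_distance(a, b, 5.0)
        assert 0 <= d <= 1
        assert d == pytest.approx(profile_distance(b, a, 5.0))


class TestNodeDistance:
    nc = NormalizationConstants(max_degree=1.0, max_power=1.0)

    def test_identical_signatures_pay_only_spatial_floor(self):
        s = sig(degree=0.4, nd=[0.4], power=0.5, npow=[0.3], coord=(1, 2, 3))
        assert node_distance(s, s, nc=self.nc) == pytest.approx(0.4 / 301)

    def test_maximal_components_with_coincident_coords(self):
        s1 = sig(degree=1.0, nd=[1.0], power=1.0, npow=[1.0])
        s2 = sig()  # all-zero signature at the same coordinate
        expected = 0.6 + 0.4 / 301
        assert node_distance(s1, s2, nc=self.nc) == pytest.approx(expected)

    def test_default_weights_applied(self):
        # isolate each component and check its weight
        comps = [
            (sig(degree=1.0), sig(), 0.2),
            (sig(nd=[1.0]), sig(), 0.1),
            (sig(power=1.0), sig(), 0.2),
            (sig(npow=[1.0]), sig(), 0.1),
        ]
        floor = 0.4 / 301
        for s1, s2, w in comps:
            assert node_distance(s1, s2, nc=self.nc) == pytest.approx(w + floor)

    def test_clamping_beyond_training_maximum(self):
        s1 = sig(degree=5.0)  # exceeds max_degree=1
        d = node_distance(s1, sig(), nc=self.nc)
        assert d == pytest.approx(0.2 + 0.4 / 301)


class TestCostMatrixAndAssignment:
    def test_orientation_smaller_graph_rows(self):
        g1, g2, _, (md, mp) = toy_graph_pair(0)
        nc = NormalizationConstants(md, mp)
        c, row_g, col_g = node_cost_matrix(g2, g1, nc=nc)
        assert c.shape == (3, 4)
        assert row_g is g1 and col_g is g2

    def test_self_cost_diagonal(self):
        g1, _, _, (md, mp) = toy_graph_pair(0)
        nc = NormalizationConstants(md, mp)
        c, _, _ = node_cost_matrix(g1, g1, nc=nc)
        np.testing.assert_allclose(np.diag(c), 0.4 / 301, atol=1e-12)

    def test_matches_independent_arithmetic(self):
        for seed in range(3):
            g1, g2, expected, (md, mp) = toy_graph_pair(seed)
            nc = NormalizationConstants(md, mp)
            c, _, _ = node_cost_matrix(g1, g2, nc=nc)
            np.testing.assert_allclose(c, expected, atol=1e-12)

    @pytest.mark.parametrize(
        "matrix,cost",
        [
            ([[0, 1], [1, 0]], 0.0),
            ([[4, 1], [2, 3]], 3.0),
            ([[1, 2, 3]], 1.0),
        ],
    )
    def test_small_assignments(self, matrix, cost):
        res = solve_assignment(np.array(matrix, float))
        assert res.total_cost == pytest.approx(cost)
        assert len(res.assignment) == len(matrix)
        cols = [c for _, c in res.assignment]
        assert len(set(cols)) == len(cols)  # injective

    def test_rows_exceeding_cols_rejected(self):
        with pytest.raises(ValueError):
            solve_assignment(np.zeros((3, 2)))

    def test_oracle_equivalence_random_matrices(self, rng):
        for _ in range(60):
            r = rng.integers(1, 7)
            c = rng.integers(r, 7)
            m = rng.random((r, c))
            assert solve_assignment(m).total_cost == pytest.approx(
                brute_force_assignment(m)
            )


class TestGraphDistance:
    def setup_method(self):
        self.g1, self.g2, _, (md, mp) = toy_graph_pair(0)
        self.nc = NormalizationConstants(md, mp)

    def test_self_distance_closed_form(self):
        for g in (self.g1, self.g2):
            expected = g.n_nodes * 0.4 / 301
            d = graph_distance(g, g, nc=self.nc)
            assert d == pytest.approx(expected)
            # and the identity matching really is optimal (brute force)
            c, _, _ = node_cost_matrix(g, g, nc=self.nc)
            assert d == pytest.approx(brute_force_assignment(c))

    def test_symmetry(self):
        d12 = graph_distance(self.g1, self.g2, nc=self.nc)
        d21 = graph_distance(self.g2, self.g1, nc=self.nc)
        assert d12 == pytest.approx(d21)

    def test_bounded_by_node_count(self):
        d = graph_distance(self.g1, self.g2, nc=self.nc)
        assert d <= min(self.g1.n_nodes, self.g2.n_nodes) * WeightVector().total

    def test_single_node_graphs(self):
        a = AttributedGraph("a", [self.g1.nodes[0]], [])
        b = AttributedGraph("b", [self.g2.nodes[0]], [])
        from agdist import compute_signature

        a.signatures = {a.nodes[0].node_id: compute_signature(a, a.nodes[0].node_id)}
        b.signatures = {b.nodes[0].node_id: compute_signature(b, b.nodes[0].node_id)}
        d = graph_distance(a, b, nc=self.nc)
        assert d == pytest.approx(
            node_distance(
                a.signatures[a.nodes[0].node_id],
                b.signatures[b.nodes[0].node_id],
                nc=self.nc,
            )
        )

    def test_normalized_option(self):
        d = graph_distance(self.g1, self.g2, nc=self.nc)
        dn = graph_distance(self.g1, self.g2, nc=self.nc, normalize_by_nodes=True)
        assert dn == pytest.approx(d / min(self.g1.n_nodes, self.g2.n_nodes))


class TestPairwiseDistances:
    def test_consistency_symmetry_zero_diagonal(self):
        graphs = []
        for seed in range(3):
            g1, g2, _, _ = toy_graph_pair(seed)
            graphs.extend([g1, g2])
        nc = training_constants(graphs)
        D = pairwise_distances(graphs, nc=nc)
        np.testing.assert_array_equal(D, D.T)
        np.testing.assert_array_equal(np.diag(D), 0.0)
        for i in range(len(graphs)):
            for j in range(i + 1, len(graphs)):
                assert D[i, j] == pytest.approx(
                    graph_distance(graphs[i], graphs[j], nc=nc)
                )

    def test_identical_graphs_equidistant(self):
        g1, _, _, (md, mp) = toy_graph_pair(0)
        nc = NormalizationConstants(md, mp)
        D = pairwise_distances([g1, g1, g1], nc=nc)
        off = D[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0])

    def test_tsv_round_trip(self, tmp_path):
        g1, g2, _, _ = toy_graph_pair(0)
        nc = training_constants([g1, g2])
        D = pairwise_distances([g1, g2], nc=nc)
        path = tmp_path / "D.tsv"
        write_distance_matrix(D, ["a", "b"], path, sidecar={"weights": list(WeightVector().w)})
        back, ids = read_distance_matrix(path)
        np.testing.assert_allclose(back, D, atol=1e-12)
        assert ids == ["a", "b"]
        assert (tmp_path / "D.tsv.json").exists()
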