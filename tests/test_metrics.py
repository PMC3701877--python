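"""Global metrics: Fagiolo clustering, BFS path lengths, small-world
indices, directed assortativity — each against an independent oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aviannet import (
    Connectome,
    assortativity,
    clustering_coefficient,
    mean_path_length,
    path_length_report,
    small_world,
)
from aviannet.metrics import distance_matrix, local_clustering
from conftest import complete_digraph, random_digraph


def digraphs(max_n=8):
    """Hypothesis strategy: random simple digraphs as adjacency bits."""

    @st.composite
    def build(draw):
        n = draw(st.integers(3, max_n))
        bits = draw(st.lists(st.booleans(), min_size=n * n, max_size=n * n))
        A = np.array(bits, dtype=np.int8).reshape(n, n)
        np.fill_diagonal(A, 0)
        return Connectome(tuple(f"v{i}" for i in range(n)), A)

    return build()


class TestClustering:
    def test_complete_digraphs_are_maximally_clustered(self):
        for n in (3, 4, 6):
            assert clustering_coefficient(complete_digraph(n)) == pytest.approx(1.0)

    def test_three_cycle_by_hand(self, three_cycle):
        # numerator 2 and denominator 4 per node under the Fagiolo formula
        assert clustering_coefficient(three_cycle) == pytest.approx(0.5)

    def test_triangle_free_dag_is_zero(self):
        c = Connectome.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        # undirected skeleton is a 4-cycle: no triangles
        assert clustering_coefficient(c) == 0.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(digraphs())
    def test_matches_networkx_fagiolo(self, c):
        """networkx implements the same directed clustering independently."""
        ours = local_clustering(c)
        theirs = nx.clustering(c.to_networkx())
        for i, r in enumerate(c.regions):
            assert ours[i] == pytest.approx(theirs[r], abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(digraphs())
    def test_bounded_and_order_invariant(self, c):
        vals = local_clustering(c)
        assert ((0 <= vals) & (vals <= 1 + 1e-12)).all()
        perm = np.random.default_rng(0).permutation(c.n_regions)
        shuffled = Connectome(
            tuple(c.regions[i] for i in perm),
            c.adjacency[np.ix_(perm, perm)],
        )
        assert clustering_coefficient(shuffled) == pytest.approx(
            clustering_coefficient(c)
        )


def _floyd_warshall(A):
    n = len(A)
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    return D


class TestPathLength:
    def test_three_cycle(self, three_cycle):
        assert mean_path_length(three_cycle) == pytest.approx(1.5)

    def test_path_graph_excludes_unreachable(self, path_abc):
        rep = path_length_report(path_abc)
        assert rep.mean == pytest.approx(4 / 3)
        assert rep.n_finite_pairs == 3
        assert rep.n_unreachable_pairs == 3

    def test_complete_digraph_is_one(self):
        assert mean_path_length(complete_digraph(5)) == pytest.approx(1.0)

    def test_no_reachable_pair_raises(self):
        c = Connectome(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            mean_path_length(c)

    def test_bfs_matches_floyd_warshall_exhaustively(self):
        # all 4-node digraphs on a fixed undirected support, plus random 5-node
        rng = np.random.default_rng(1)
        for _ in range(40):
            c = random_digraph(5, 0.4, rng)
            assert np.array_equal(
                distance_matrix(c), _floyd_warshall(c.adjacency)
            )
        for code in range(0, 4096, 97):  # stride through 4-node digraphs
            A = np.zeros((4, 4), dtype=np.int8)
            slots = [(i, j) for i in range(4) for j in range(4) if i != j]
            for b, (i, j) in enumerate(slots):
                A[i, j] = (code >> b) & 1
            c = Connectome(("a", "b", "c", "d"), A)
            assert np.array_equal(distance_matrix(c), _floyd_warshall(A))


class TestAssortativity:
    def test_star_plus_leaf_edge_against_direct_summation(self):
        edges = [("h", f"l{i}") for i in range(5)] + [("l0", "l1")]
        c = Connectome.from_edges(edges)
        kout = {r: sum(1 for a, _ in edges if a == r) for r in c.regions}
        kin = {r: sum(1 for _, b in edges if b == r) for r in c.regions}
        x = np.array([kout[a] for a, _ in edges], float)
        y = np.array([kin[b] for _, b in edges], float)
        mu = (0.5 * (x + y)).mean()
        expected = ((x * y).mean() - mu**2) / (
            (0.5 * (x**2 + y**2)).mean() - mu**2
        )
        assert assortativity(c) == pytest.approx(expected)

    def test_degenerate_cycle_raises(self, three_cycle):
        with pytest.raises(ValueError):
            assortativity(three_cycle)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(digraphs())
    def test_bounded_and_relabel_invariant(self, c):
        try:
            r = assortativity(c)
        except ValueError:
            return  # degenerate graphs are allowed to refuse
        assert -1 - 1e-9 <= r <= 1 + 1e-9
        perm = np.random.default_rng(1).permutation(c.n_regions)
        shuffled = Connectome(
            tuple(c.regions[i] for i in perm), c.adjacency[np.ix_(perm, perm)]
        )
        assert assortativity(shuffled) == pytest.approx(r)


class TestSmallWorld:
    def test_rigid_graph_has_sigma_exactly_one(self, three_cycle):
        # the 3-cycle admits no degree-preserving swap: null == observed
        sw = small_world(three_cycle, "rewire", n_samples=5, seed=0)
        assert sw.sigma == pytest.approx(1.0)
        assert sw.gamma_null.null_sd == 0

    def test_report_is_consistent(self, pigeon):
        sw = small_world(pigeon, "rewire", n_samples=10, seed=0)
        assert sw.sigma == pytest.approx(
            (sw.gamma / sw.gamma_null.null_mean)
            / (sw.lam / sw.lambda_null.null_mean)
        )
        assert sw.gamma == pytest.approx(clustering_coefficient(pigeon))
        assert sw.n_unreachable_pairs == 200
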