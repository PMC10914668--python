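"""Correlation similarity, graph policies, Louvain vs brute-force optimum."""

import itertools

import numpy as np
import pytest

from aptaxa import (
    AdjustedMatrix,
    Partition,
    build_graph,
    correlation_matrix,
    louvain_partition,
    modularity,
)
from aptaxa.cluster import SimilarityMatrix


def adjusted(values):
    values = np.asarray(values, dtype=float)
    return AdjustedMatrix(
        drugs=[f"d{i}" for i in range(values.shape[0])],
        receptors=[f"R{j}" for j in range(values.shape[1])],
        values=values,
        observed=np.ones_like(values, dtype=bool),
    )


def sim_from_weights(W):
    """Similarity matrix wrapper around an explicit symmetric weight matrix."""
    n = W.shape[0]
    return SimilarityMatrix(drugs=[f"d{i}" for i in range(n)], values=np.asarray(W, float))


def set_partitions(items):
    """All set partitions (restricted-growth strings); oracle helper."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def brute_force_best_modularity(graph):
    """Exhaustive maximum of Q over all partitions (n <= 8)."""
    nodes = list(graph.graph.nodes)
    best_q, best_assignment = -np.inf, None
    for blocks in set_partitions(nodes):
        assignment = {v: c for c, block in enumerate(blocks) for v in block}
        q = modularity(graph, Partition(assignment=assignment))
        if q > best_q:
            best_q, best_assignment = q, assignment
    return best_q, best_assignment


class TestCorrelationMatrix:
    def test_identical_rows_correlate_perfectly(self, rng):
        row = rng.standard_normal(8)
        sim = correlation_matrix(adjusted([row, row, rng.standard_normal(8)]))
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_negated_row_anticorrelates(self, rng):
        row = rng.standard_normal(8)
        sim = correlation_matrix(adjusted([row, -row]))
        assert sim.values[0, 1] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        sim = correlation_matrix(adjusted(rng.standard_normal((6, 9))))
        v = sim.values
        assert np.allclose(v, v.T, atol=1e-12)
        assert np.allclose(np.diag(v), 1.0)
        assert v.min() >= -1.0 and v.max() <= 1.0

    def test_zero_variance_drug_named_in_error(self):
        with pytest.raises(ValueError, match="d1"):
            correlation_matrix(adjusted([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))

    def test_incomplete_matrix_rejected(self):
        mat = adjusted([[1.0, 2.0], [3.0, 4.0]])
        mat.observed[0, 0] = False
        with pytest.raises(ValueError, match="impute"):
            correlation_matrix(mat)


class TestBuildGraph:
    def test_clip_zero_drops_negative_edges(self):
        W = np.array([[1.0, -0.4, 0.8], [-0.4, 1.0, 0.1], [0.8, 0.1, 1.0]])
        g = build_graph(sim_from_weights(W)).graph
        assert not g.has_edge("d0", "d1")
        assert g["d0"]["d2"]["weight"] == pytest.approx(0.8)

    def test_shift_min_makes_all_nonnegative(self):
        W = np.array([[1.0, -0.4], [-0.4, 1.0]])
        g = build_graph(sim_from_weights(W), "shift_min").graph
        assert g.number_of_edges() == 0 or min(
            d["weight"] for _, _, d in g.edges(data=True)
        ) >= 0

    def test_abs_policy(self):
        W = np.array([[1.0, -0.4], [-0.4, 1.0]])
        g = build_graph(sim_from_weights(W), "abs").graph
        assert g["d0"]["d1"]["weight"] == pytest.approx(0.4)

    def test_no_self_loops(self, rng):
        sim = correlation_matrix(adjusted(rng.standard_normal((5, 6))))
        g = build_graph(sim).graph
        assert all(u != v for u, v in g.edges)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            build_graph(sim_from_weights(np.eye(2)), "bogus")

    def test_all_negative_graph_fails_downstream(self):
        W = np.array([[1.0, -0.5], [-0.5, 1.0]])
        graph = build_graph(sim_from_weights(W))
        with pytest.raises(ValueError, match="edge"):
            louvain_partition(graph, seed=0)


class TestModularityFormula:
    def test_all_in_one_partition_scores_zero(self, rng):
        sim = correlation_matrix(adjusted(rng.standard_normal((6, 9))))
        graph = build_graph(sim, "abs")
        part = Partition(assignment={d: 0 for d in sim.drugs})
        assert modularity(graph, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_edges_half(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        graph = build_graph(sim_from_weights(W))
        part = Partition(assignment={"d0": 0, "d1": 0, "d2": 1, "d3": 1})
        assert modularity(graph, part) == pytest.approx(0.5)

    def test_singletons_on_uniform_graph_negative(self):
        W = np.ones((4, 4))
        graph = build_graph(sim_from_weights(W))
        part = Partition(assignment={f"d{i}": i for i in range(4)})
        assert modularity(graph, part) < 0

    def test_missing_node_rejected(self):
        W = np.ones((3, 3))
        graph = build_graph(sim_from_weights(W))
        with pytest.raises(ValueError, match="misses"):
            modularity(graph, Partition(assignment={"d0": 0}))


class TestLouvain:
    def test_two_cliques_found(self):
        n = 8
        W = np.zeros((n, n))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                W[i, j] = W[j, i] = 1.0
        W[0, 4] = W[4, 0] = 1.0  # single bridge
        graph = build_graph(sim_from_weights(W))
        part = louvain_partition(graph, seed=0, n_restarts=10)
        assert part.n_clusters == 2
        assert {part.assignment[f"d{i}"] for i in range(4)} == {0} or {
            part.assignment[f"d{i}"] for i in range(4)
        } == {1}
        best_q, _ = brute_force_best_modularity(graph)
        assert part.modularity == pytest.approx(best_q, abs=1e-10)

    def test_uniform_complete_graph_single_cluster(self):
        W = np.ones((6, 6))
        graph = build_graph(sim_from_weights(W))
        part = louvain_partition(graph, seed=0, n_restarts=10)
        assert part.n_clusters == 1
        best_q, _ = brute_force_best_modularity(graph)
        assert best_q == pytest.approx(0.0, abs=1e-12)

    def test_planted_four_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        n_blocks, per = 4, 6
        n = n_blocks * per
        labels = np.repeat(np.arange(n_blocks), per)
        W = np.where(labels[:, None] == labels[None, :], 0.9, 0.05)
        np.fill_diagonal(W, 1.0)
        graph = build_graph(sim_from_weights(W))
        part = louvain_partition(graph, seed=0, n_restarts=10)
        found = [part.assignment[f"d{i}"] for i in range(n)]
        assert adjusted_rand_score(labels, found) == 1.0

    def test_reported_q_matches_independent_formula(self, rng):
        sim = correlation_matrix(adjusted(rng.standard_normal((10, 12))))
        graph = build_graph(sim)
        part = louvain_partition(graph, seed=3, n_restarts=10)
        assert part.modularity == pytest.approx(modularity(graph, part), abs=1e-10)
        assert part.modularity >= 0.0  # never worse than all-in-one

    def test_canonical_labels_are_stable_under_node_order(self, rng):
        # well-separated blocks: permuting drug order only relabels clusters
        labels = np.repeat([0, 1, 2], 5)
        W = np.where(labels[:, None] == labels[None, :], 0.95, 0.02)
        np.fill_diagonal(W, 1.0)
        names = [f"d{i}" for i in range(15)]
        perm = rng.permutation(15)
        sim_a = SimilarityMatrix(drugs=names, values=W)
        sim_b = SimilarityMatrix(
            drugs=[names[i] for i in perm], values=W[np.ix_(perm, perm)]
        )
        pa = louvain_partition(build_graph(sim_a), seed=0, n_restarts=10)
        pb = louvain_partition(build_graph(sim_b), seed=0, n_restarts=10)
        groups_a = {frozenset(pa.members(c)) for c in range(pa.n_clusters)}
        groups_b = {frozenset(pb.members(c)) for c in range(pb.n_clusters)}
        assert groups_a == groups_b

    def test_determinism_under_same_seed(self, rng):
        sim = correlation_matrix(adjusted(rng.standard_normal((12, 10))))
        graph = build_graph(sim)
        p1 = louvain_partition(graph, seed=5, n_restarts=10)
        p2 = louvain_partition(graph, seed=5, n_restarts=10)
        assert p1.assignment == p2.assignment and p1.modularity == p2.modularity
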