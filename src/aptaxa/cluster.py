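"""Drug-drug similarity and community detection.

Completed, adjusted receptor fingerprints are Pearson-correlated pairwise:
two drugs correlate highly when they share a receptor profile, which also
absorbs overall potency (dosing) differences.  The correlation matrix is then
treated as a weighted graph and partitioned by Louvain modularity
maximization.  Modularity is only defined for non-negative weights, so
negative correlations must be mapped to weights by an explicit policy;
``clip_zero`` (negative similarity carries no attractive force) is the
default, with ``shift_min`` and ``abs`` as sensitivity alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import AdjustedMatrix

__all__ = [
    "SimilarityMatrix",
    "WeightedGraph",
    "Partition",
    "correlation_matrix",
    "build_graph",
    "louvain_partition",
    "modularity",
]

NEGATIVE_POLICIES = ("clip_zero", "shift_min", "abs")


@dataclass
class SimilarityMatrix:
    drugs: list[str]
    values: np.ndarray  # n x n Pearson r, unit diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drugs, columns=self.drugs)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class WeightedGraph:
    graph: nx.Graph
    negative_policy: str

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class Partition:
    assignment: dict[str, int]
    modularity: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list[str]:
        return [d for d, c in self.assignment.items() if c == cluster_id]

    def labels(self, drugs: list[str]) -> np.ndarray:
        return np.array([self.assignment[d] for d in drugs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"drug": list(self.assignment), "cluster_id": list(self.assignment.values())}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def correlation_matrix(adjusted: AdjustedMatrix) -> SimilarityMatrix:
    """Pairwise Pearson correlation of drug fingerprints across receptors."""
    if not adjusted.observed.all():
        raise ValueError("correlation requires a completed matrix; impute first")
    X = adjusted.values
    sd = X.std(axis=1)
    flat = [adjusted.drugs[i] for i in np.nonzero(sd == 0)[0]]
    if flat:
        raise ValueError(f"zero-variance fingerprints (cannot correlate): {flat}")
    r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(drugs=list(adjusted.drugs), values=r)


def build_graph(sim: SimilarityMatrix, negative_policy: str = "clip_zero") -> WeightedGraph:
    """Turn the correlation matrix into a non-negatively weighted graph.

    Policies: ``clip_zero`` w = max(r, 0); ``shift_min`` w = r - min(r)
    (off-diagonal minimum); ``abs`` w = |r|.  Self-loops are never created.
    """
    if negative_policy not in NEGATIVE_POLICIES:
        raise ValueError(
            f"unknown negative_policy {negative_policy!r}; choose from {NEGATIVE_POLICIES}"
        )
    r = sim.values
    n = len(sim.drugs)
    off = r[~np.eye(n, dtype=bool)]
    if negative_policy == "clip_zero":
        w = np.maximum(r, 0.0)
    elif negative_policy == "abs":
        w = np.abs(r)
    else:  # shift_min
        w = r - off.min() if off.size and off.min() < 0 else r.copy()
    g = nx.Graph()
    g.add_nodes_from(sim.drugs)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(sim.drugs[i], sim.drugs[j], weight=float(w[i, j]))
    return WeightedGraph(graph=g, negative_policy=negative_policy)


def _canonical_relabel(assignment: dict[str, int]) -> dict[str, int]:
    """Relabel cluster ids 0..K-1 by decreasing size, ties by smallest member."""
    groups: dict[int, list[str]] = {}
    for node, cid in assignment.items():
        groups.setdefault(cid, []).append(node)
    order = sorted(groups.values(), key=lambda members: (-len(members), min(members)))
    relabeled = {}
    for new_id, members in enumerate(order):
        for node in members:
            relabeled[node] = new_id
    return relabeled


def modularity(graph: WeightedGraph, partition: Partition, resolution: float = 1.0) -> float:
    """Weighted modularity Q = (1/2m) sum_ij [A_ij - g k_i k_j / 2m] d(c_i, c_j).

    Computed directly from the formula (independent of the community-detection
    routine).  Q = 0 for the all-in-one partition by construction.
    """
    g = graph.graph
    missing = [v for v in g.nodes if v not in partition.assignment]
    if missing:
        raise ValueError(f"partition misses nodes: {missing}")
    two_m = sum(d["weight"] for _, _, d in g.edges(data=True)) * 2.0
    if two_m == 0:
        raise ValueError("graph has no positive-weight edges")
    degree = dict(g.degree(weight="weight"))
    q = 0.0
    for u, v, d in g.edges(data=True):
        if partition.assignment[u] == partition.assignment[v]:
            q += 2.0 * d["weight"] / two_m  # A_ij counted for (i,j) and (j,i)
    comm_deg: dict[int, float] = {}
    for node, cid in partition.assignment.items():
        comm_deg[cid] = comm_deg.get(cid, 0.0) + degree.get(node, 0.0)
    q -= resolution * sum((k / two_m) ** 2 for k in comm_deg.values())
    return q


def _local_move_refinement(
    graph: WeightedGraph, assignment: dict[str, int], resolution: float
) -> dict[str, int]:
    """Greedy single-node moves (including into a fresh singleton) to a local
    optimum of modularity.  A final flat-level local-moving pass: the greedy
    aggregation phases can lock in a split that one node move improves."""
    assign = dict(assignment)
    nodes = sorted(graph.graph.nodes)
    improved = True
    while improved:
        improved = False
        for v in nodes:
            current = assign[v]
            q_now = modularity(graph, Partition(assignment=assign), resolution)
            best_c, best_q = current, q_now
            candidates = set(assign.values()) | {max(assign.values()) + 1}
            candidates.discard(current)
            for c in sorted(candidates):
                assign[v] = c
                q = modularity(graph, Partition(assignment=assign), resolution)
                if q > best_q + 1e-12:
                    best_q, best_c = q, c
            assign[v] = best_c
            if best_c != current:
                improved = True
    return _canonical_relabel(assign)


def louvain_partition(
    graph: WeightedGraph,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 100,
) -> Partition:
    """Best-of-restarts Louvain community detection.

    Louvain is greedy and order-dependent, so the algorithm is run
    ``n_restarts`` times with node orders seeded from one master seed; the
    partition with the highest modularity wins, with ties broken by the
    lexicographically smallest canonical assignment vector, and a final
    deterministic single-node local-moving pass polishes the winner.  Cluster
    ids are relabeled by size then smallest member, so output is
    deterministic end to end.
    """
    g = graph.graph
    if g.number_of_edges() == 0:
        raise ValueError("graph has no positive-weight edges; cannot cluster")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    nodes_sorted = sorted(g.nodes)
    best: tuple[float, list[int], dict[str, int]] | None = None
    for s in sub_seeds:
        communities = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=int(s)
        )
        assignment = {}
        for cid, members in enumerate(communities):
            for node in members:
                assignment[node] = cid
        assignment = _canonical_relabel(assignment)
        q = modularity(graph, Partition(assignment=assignment), resolution=resolution)
        vector = [assignment[v] for v in nodes_sorted]
        if best is None or (q > best[0] + 1e-15) or (
            abs(q - best[0]) <= 1e-15 and vector < best[1]
        ):
            best = (q, vector, assignment)
    assert best is not None
    q, _, assignment = best
    assignment = _local_move_refinement(graph, assignment, resolution)
    q = modularity(graph, Partition(assignment=assignment), resolution=resolution)
    return Partition(
        assignment=assignment,
        modularity=q,
        meta={
            "seed": seed,
            "n_restarts": n_restarts,
            "resolution": resolution,
            "negative_policy": graph.negative_policy,
        },
    )
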