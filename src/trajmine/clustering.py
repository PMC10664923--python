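"""Trajectory clustering: Jaccard similarity graphs + Markov clustering.

Two strategies are provided.  The trajectory-graph strategy puts one node
per trajectory ID, weights every pair of trajectories by the Jaccard
index of their code SETS, and clusters that graph — every trajectory then
belongs to exactly one cluster by construction (total assignment).  The
legacy event-graph strategy clusters the event codes instead (nodes =
codes, edges = selected pairs weighted by a count-based Jaccard over the
trajectory list) and assigns a trajectory to a cluster only when ALL its
codes fall inside it; trajectories spanning several code clusters stay
unassigned, which is the defect the trajectory-graph strategy removes.

Markov clustering (MCL) alternates expansion (squaring the
column-stochastic matrix — random-walk spreading) with inflation
(elementwise powering and renormalization — sharpening) until the matrix
stabilizes; clusters are read off the attractor rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from .trajectories import Trajectory

__all__ = [
    "SimilarityGraph",
    "ClusterSet",
    "UNASSIGNED",
    "trajectory_jaccard",
    "edge_jaccard",
    "build_trajectory_graph",
    "build_event_graph",
    "mcl",
    "assign_clusters",
    "cluster_trajectories",
]

UNASSIGNED = -1

TRAJECTORY_MODE = "trajectory"  # trajectory-ID graph, total assignment
EVENT_MODE = "event"  # event-code graph, partial assignment


@dataclass
class SimilarityGraph:
    """Weighted undirected graph over trajectory IDs or event codes."""

    nodes: list  # node ids: ints (trajectory mode) or strings (event mode)
    edges: dict[tuple, float]  # key (u, v) with u < v, weight in (0, 1]
    mode: str = TRAJECTORY_MODE

    def __post_init__(self):
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError("self-edges are not stored")
            if not (0 <= w <= 1):
                raise ValueError(f"edge weight {w} outside [0, 1]")


@dataclass
class ClusterSet:
    """Partition (or partial assignment) of nodes into clusters.

    ``clusters`` holds node-id sets ordered by decreasing size (ties:
    smallest member id); ``assignment`` maps trajectory id -> cluster
    index or UNASSIGNED.  ``converged`` is False when MCL hit its
    iteration cap before stabilizing.
    """

    clusters: list[set]
    mode: str = TRAJECTORY_MODE
    assignment: dict[int, int] = field(default_factory=dict)
    converged: bool = True

    @property
    def unassigned(self) -> list[int]:
        return sorted(t for t, c in self.assignment.items() if c == UNASSIGNED)

    @property
    def unassigned_fraction(self) -> float:
        if not self.assignment:
            return 0.0
        return len(self.unassigned) / len(self.assignment)


# -- similarity measures ------------------------------------------------------


def trajectory_jaccard(t1: Trajectory, t2: Trajectory) -> float:
    """Jaccard index of two trajectories viewed as sets of event codes."""
    s1, s2 = set(t1.codes), set(t2.codes)
    inter = len(s1 & s2)
    denom = len(s1) + len(s2) - inter
    return inter / denom if denom else 0.0


def edge_jaccard(a: str, b: str, trajectories: list[Trajectory]) -> float:
    """Count-based Jaccard of a selected pair over the trajectory list.

    Counts trajectories containing the CONSECUTIVE pair a -> b versus
    trajectories containing a or b anywhere.
    """
    n_pair = n_a = n_b = 0
    for t in trajectories:
        if a in t.codes:
            n_a += 1
        if b in t.codes:
            n_b += 1
        if any(x == a and y == b for x, y in zip(t.codes, t.codes[1:])):
            n_pair += 1
    denom = n_a + n_b - n_pair
    return n_pair / denom if denom else 0.0


def build_trajectory_graph(trajectories: list[Trajectory]) -> SimilarityGraph:
    """Fully-connected trajectory-ID graph with code-set Jaccard weights.

    Zero-weight edges are omitted from storage (equivalent for MCL, which
    treats missing and zero entries alike).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    edges: dict[tuple, float] = {}
    for t1, t2 in combinations(trajectories, 2):
        w = trajectory_jaccard(t1, t2)
        if w > 0:
            u, v = sorted((t1.tid, t2.tid))
            edges[(u, v)] = w
    return SimilarityGraph(nodes=[t.tid for t in trajectories], edges=edges, mode=TRAJECTORY_MODE)


def build_event_graph(trajectories: list[Trajectory]) -> SimilarityGraph:
    """Event-code graph: nodes = codes, edges = consecutive pairs seen in trajectories."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    nodes = sorted({c for t in trajectories for c in t.codes})
    edges: dict[tuple, float] = {}
    pairs = {(x, y) for t in trajectories for x, y in zip(t.codes, t.codes[1:])}
    for a, b in pairs:
        w = edge_jaccard(a, b, trajectories)
        if w > 0:
            u, v = sorted((a, b))
            edges[(u, v)] = max(edges.get((u, v), 0.0), w)
    return SimilarityGraph(nodes=nodes, edges=edges, mode=EVENT_MODE)


# -- Markov clustering --------------------------------------------------------


def mcl(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    max_iterations: int = 200,
    prune_threshold: float = 1e-5,
) -> ClusterSet:
    """Markov clustering of a similarity graph.

    The weight matrix gets a self-loop per node equal to its maximum
    incident weight (at least 1e-6), is column-normalized, then iterates
    expansion (matrix square) and inflation (elementwise power, column
    renormalization) with pruning of entries below ``prune_threshold``
    until the maximum column change drops below 1e-8 or the iteration cap
    is hit.  Clusters are the attractor rows; a node claimed by several
    attractor sets goes to the lowest cluster index; untouched nodes form
    singleton clusters.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = list(graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    loop = np.full(n, 1e-6)
    for (u, v), w in graph.edges.items():
        i, j = pos[u], pos[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        loop[i] = max(loop[i], w)
        loop[j] = max(loop[j], w)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    M = _normalize_columns(M)

    converged = False
    for _ in range(max_iterations):
        prev = M.copy()
        M = M @ M  # expansion
        M = M.power(inflation)  # inflation
        M = _normalize_columns(M)
        M.data[M.data < prune_threshold] = 0.0
        M.eliminate_zeros()
        M = _normalize_columns(M)
        if abs(M - prev).max() < 1e-8:
            converged = True
            break

    clusters = _interpret(M, nodes)
    return ClusterSet(clusters=_order_clusters(clusters), mode=graph.mode, converged=converged)


def _normalize_columns(M: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(M.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    D = sp.diags(1.0 / sums)
    return (M @ D).tocsr()


def _interpret(M: sp.csr_matrix, nodes: list) -> list[set]:
    """Read clusters from attractor rows of the limit matrix."""
    n = len(nodes)
    Mc = M.tocsr()
    attractors = [i for i in range(n) if Mc[i, i] > 1e-7]
    raw: list[set[int]] = []
    for i in attractors:
        members = set(Mc.getrow(i).indices.tolist()) | {i}
        raw.append(members)
    # merge attractor sets that overlap (same attractor system)
    merged: list[set[int]] = []
    for s in raw:
        hit = [m for m in merged if m & s]
        for m in hit:
            merged.remove(m)
            s = s | m
        merged.append(s)
    assigned: dict[int, int] = {}
    # lowest cluster index wins for nodes claimed by several clusters
    for ci, s in enumerate(merged):
        for i in sorted(s):
            assigned.setdefault(i, ci)
    clusters: dict[int, set] = {}
    for i, ci in assigned.items():
        clusters.setdefault(ci, set()).add(nodes[i])
    out = list(clusters.values())
    for i in range(n):  # singletons for nodes no attractor claimed
        if i not in assigned:
            out.append({nodes[i]})
    return out


def _order_clusters(clusters: list[set]) -> list[set]:
    return sorted(clusters, key=lambda s: (-len(s), min(s)))


# -- assignment ---------------------------------------------------------------


def assign_clusters(
    trajectories: list[Trajectory], clusterset: ClusterSet, mode: str
) -> ClusterSet:
    """Map trajectories onto clusters.

    Trajectory-graph mode: a trajectory belongs to the cluster holding
    its node — assignment is total.  Event-graph mode: a trajectory is
    assigned only when every one of its codes lies in one cluster,
    otherwise it stays UNASSIGNED.
    """
    if mode != clusterset.mode:
        raise ValueError(f"cluster set was built in {clusterset.mode!r} mode, not {mode!r}")
    assignment: dict[int, int] = {}
    if mode == TRAJECTORY_MODE:
        node_cluster = {n: ci for ci, s in enumerate(clusterset.clusters) for n in s}
        for t in trajectories:
            assignment[t.tid] = node_cluster[t.tid]
    else:
        for t in trajectories:
            assignment[t.tid] = UNASSIGNED
            for ci, s in enumerate(clusterset.clusters):
                if set(t.codes) <= s:
                    assignment[t.tid] = ci
                    break
    clusterset.assignment = assignment
    return clusterset


def cluster_trajectories(
    trajectories: list[Trajectory],
    mode: str = TRAJECTORY_MODE,
    inflation: float = 2.0,
    max_iterations: int = 200,
    prune_threshold: float = 1e-5,
) -> ClusterSet:
    """End-to-end clustering in either mode."""
    if mode == TRAJECTORY_MODE:
        graph = build_trajectory_graph(trajectories)
    elif mode == EVENT_MODE:
        graph = build_event_graph(trajectories)
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    cs = mcl(graph, inflation=inflation, max_iterations=max_iterations, prune_threshold=prune_threshold)
    return assign_clusters(trajectories, cs, mode)
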