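"""Correlation-filtered shortest communication paths on a consensus network.

A communication path between two residues is the shortest sequence of
network edges connecting them, with the distance between directly connected
residues taken as 1 (hop metric, Floyd–Warshall).  A path is retained only
when at least one intermediate node is significantly correlated (generalized
correlation at or above a cutoff, default 0.5) with one of the two
end-residues — the coupling between structure network and correlated motions
that distinguishes a communication path from a mere contact chain.

Paths are ranked by their occurrence probability: the fraction of per-window
consensus networks in which every edge of the path is simultaneously
present.  Retained paths directed at a target region are aggregated into an
occurrence-weighted meta-graph whose edge weights are the probability that
the same connection recurs across different paths; the per-node
participation counts of that graph rank mediator residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .exceptions import InvalidArgumentError
from .lmi import DEFAULT_LMI_CUTOFF, CorrelationMatrix
from .psn import PSNGraph

DEFAULT_MIN_OCCURRENCE = 0.15
DEFAULT_MIN_NODE_COUNT = 4  # "length greater than three", counted in nodes
DEFAULT_LONG_RANGE_NODES = 8
_ENUMERATION_BOUND = 10_000


@dataclass
class CommunicationPath:
    """An ordered residue path with its retention metadata."""

    nodes: tuple
    occurrence: float = 0.0
    correlation_ok: bool = False

    def __post_init__(self) -> None:
        self.nodes = tuple(int(n) for n in self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise InvalidArgumentError("path must not repeat nodes")
        if not 0.0 <= self.occurrence <= 1.0:
            raise InvalidArgumentError("occurrence must be in [0, 1]")

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def hop_length(self) -> int:
        return len(self.nodes) - 1

    @property
    def source(self):
        return self.nodes[0]

    @property
    def target(self):
        return self.nodes[-1]

    @property
    def edges(self) -> list:
        return [tuple(sorted(p)) for p in zip(self.nodes, self.nodes[1:])]

    def to_dict(self, labels=None) -> dict:
        d = {
            "nodes": list(self.nodes),
            "node_count": self.node_count,
            "hop_length": self.hop_length,
            "occurrence": self.occurrence,
            "correlation_ok": self.correlation_ok,
        }
        if labels is not None:
            d["labels"] = [labels[n] for n in self.nodes]
        return d


class ShortestPaths:
    """All-pairs hop distances and canonical path reconstruction.

    Distances come from Floyd–Warshall with unit edge weights; reconstruction
    is greedy on the distance matrix and yields, for each pair, the
    lexicographically smallest node sequence among all equal-length shortest
    paths (a reproducible canonical representative).  Full enumeration of
    co-shortest paths is available but bounded to avoid explosion.
    """

    def __init__(self, graph: PSNGraph):
        if len(graph.graph) < 2:
            raise InvalidArgumentError("graph needs at least 2 nodes")
        self._graph = graph
        self._nodes = graph.nodes
        self._index = {n: k for k, n in enumerate(self._nodes)}
        adj = nx.to_scipy_sparse_array(graph.graph, nodelist=self._nodes, weight=None)
        self._dist = _csgraph_shortest_path(
            adj, method="FW", directed=False, unweighted=True
        )

    @property
    def nodes(self) -> list:
        return list(self._nodes)

    def distance(self, u, v) -> float:
        """Hop distance between u and v (inf when disconnected)."""
        return float(self._dist[self._index[u], self._index[v]])

    def distance_matrix(self) -> np.ndarray:
        return self._dist.copy()

    def path(self, u, v):
        """The canonical (lexicographically smallest) shortest path, or None."""
        iu, iv = self._index[u], self._index[v]
        if not np.isfinite(self._dist[iu, iv]):
            return None
        nodes = [u]
        current = u
        while current != v:
            remaining = self._dist[self._index[current], iv]
            nxt = min(
                w
                for w in self._graph.graph.neighbors(current)
                if self._dist[self._index[w], iv] == remaining - 1
            )
            nodes.append(nxt)
            current = nxt
        return tuple(nodes)

    def all_paths(self, u, v, bound: int = _ENUMERATION_BOUND) -> list:
        """All equal-length shortest paths between u and v (bounded)."""
        if not np.isfinite(self._dist[self._index[u], self._index[v]]):
            return []
        out = []
        for p in nx.all_shortest_paths(self._graph.graph, u, v):
            out.append(tuple(p))
            if len(out) >= bound:
                break
        return sorted(out)


def all_pairs_shortest_paths(graph: PSNGraph) -> ShortestPaths:
    """Floyd–Warshall hop distances plus canonical path reconstruction."""
    return ShortestPaths(graph)


def correlation_filter(
    path: CommunicationPath,
    lmi: CorrelationMatrix,
    cutoff: float = DEFAULT_LMI_CUTOFF,
) -> bool:
    """True iff some intermediate node is significantly correlated with an end.

    Direct edges have no intermediates and therefore cannot satisfy the rule;
    they are short-range by construction and handled separately by
    :func:`paths_to_targets`.
    """
    if any(n >= lmi.order or n < 0 for n in path.nodes):
        raise InvalidArgumentError("path node outside correlation matrix order")
    first, last = path.source, path.target
    values = lmi.values
    return any(
        values[mid, first] >= cutoff or values[mid, last] >= cutoff
        for mid in path.nodes[1:-1]
    )


def path_occurrence(path: CommunicationPath, per_window_graphs: list) -> float:
    """Fraction of window networks containing every edge of the path."""
    if not per_window_graphs:
        raise InvalidArgumentError("need at least one window graph")
    hits = sum(
        all(g.has_edge(u, v) for u, v in path.edges) for g in per_window_graphs
    )
    return hits / len(per_window_graphs)


@dataclass
class PathSet:
    """The retained communication paths plus the audit trail of the filters."""

    paths: list
    direct_edges: list = field(default_factory=list)
    rejected: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)


def paths_to_targets(
    graph: PSNGraph,
    lmi: CorrelationMatrix,
    per_window_graphs: list,
    targets,
    min_occurrence: float = DEFAULT_MIN_OCCURRENCE,
    min_node_count: int = DEFAULT_MIN_NODE_COUNT,
    lmi_cutoff: float = DEFAULT_LMI_CUTOFF,
) -> PathSet:
    """Shortest communication paths from every residue to a target region.

    For every non-target residue the canonical shortest path to each target
    residue is computed; per source, the shortest (then highest-occurrence)
    candidate is kept (one path per (source, target-set) pair).  A path is
    retained when it passes the correlation filter, its occurrence is at
    least ``min_occurrence`` and it has at least ``min_node_count`` nodes
    ("length greater than three" in the node-counting convention).  Direct
    source-target edges are reported separately.  The result is sorted by
    occurrence descending, then hop length.
    """
    targets = sorted(set(int(t) for t in targets))
    if not targets:
        raise InvalidArgumentError("target set must be nonempty")
    node_set = set(graph.nodes)
    for t in targets:
        if t not in node_set:
            raise InvalidArgumentError(f"target residue {t} not in graph")
    sp = all_pairs_shortest_paths(graph)
    rejected = Counter()
    retained = []
    direct = []
    for source in graph.nodes:
        if source in targets:
            continue
        candidates = []
        for t in targets:
            nodes = sp.path(source, t)
            if nodes is None:
                rejected["unreachable"] += 1
                continue
            path = CommunicationPath(nodes=nodes)
            path.occurrence = path_occurrence(path, per_window_graphs)
            path.correlation_ok = correlation_filter(path, lmi, lmi_cutoff)
            candidates.append(path)
        if not candidates:
            continue
        # one path per (source, target-set): shortest, then highest occurrence
        best = min(candidates, key=lambda p: (p.hop_length, -p.occurrence, p.nodes))
        if best.hop_length == 1:
            direct.append(best)
            rejected["direct_edge"] += 1
            continue
        if not best.correlation_ok:
            rejected["correlation"] += 1
            continue
        if best.occurrence < min_occurrence:
            rejected["occurrence"] += 1
            continue
        if best.node_count < min_node_count:
            rejected["node_count"] += 1
            continue
        retained.append(best)
    retained.sort(key=lambda p: (-p.occurrence, p.hop_length, p.nodes))
    return PathSet(paths=retained, direct_edges=direct, rejected=dict(rejected))


@dataclass
class LongRangePartition:
    """Paths split by node count into long-range and shorter classes."""

    long_range: list
    shorter: list
    histogram: dict  # node_count -> number of paths
    min_nodes: int

    @property
    def total(self) -> int:
        return len(self.long_range) + len(self.shorter)


def classify_long_range(paths, min_nodes: int = DEFAULT_LONG_RANGE_NODES) -> LongRangePartition:
    """Partition paths into long-range (>= min_nodes nodes) and shorter ones."""
    paths = list(paths)
    long_range = [p for p in paths if p.node_count >= min_nodes]
    shorter = [p for p in paths if p.node_count < min_nodes]
    histogram = dict(sorted(Counter(p.node_count for p in paths).items()))
    return LongRangePartition(
        long_range=long_range, shorter=shorter, histogram=histogram, min_nodes=min_nodes
    )


@dataclass
class PathSetComparison:
    """Exact-sequence comparison of two path sets (e.g. free vs bound)."""

    only_a: list
    only_b: list
    shared: list
    long_range_count_a: int
    long_range_count_b: int

    @property
    def long_range_relative_change(self) -> float:
        """(B - A) / A for long-range path counts; nan when A has none."""
        if self.long_range_count_a == 0:
            return float("nan")
        return (
            self.long_range_count_b - self.long_range_count_a
        ) / self.long_range_count_a


def compare_path_sets(set_a, set_b, long_range_nodes: int = DEFAULT_LONG_RANGE_NODES) -> PathSetComparison:
    """Match paths by exact node sequence and report the set differences."""
    a_paths = {p.nodes: p for p in set_a}
    b_paths = {p.nodes: p for p in set_b}
    only_a = [a_paths[k] for k in sorted(set(a_paths) - set(b_paths))]
    only_b = [b_paths[k] for k in sorted(set(b_paths) - set(a_paths))]
    shared = [a_paths[k] for k in sorted(set(a_paths) & set(b_paths))]
    return PathSetComparison(
        only_a=only_a,
        only_b=only_b,
        shared=shared,
        long_range_count_a=sum(1 for p in a_paths.values() if p.node_count >= long_range_nodes),
        long_range_count_b=sum(1 for p in b_paths.values() if p.node_count >= long_range_nodes),
    )


@dataclass
class MetaGraph:
    """Occurrence-weighted union of retained paths.

    Edge weight = fraction of retained paths containing that connection;
    ``participation`` counts, per node, how many paths traverse it — the
    ranking used to nominate mediator residues.
    """

    graph: nx.Graph
    n_paths: int
    participation: dict
    interior_participation: dict

    @property
    def top_mediators(self) -> list:
        """Nodes ranked by how many paths they mediate (interior positions).

        Endpoints are excluded from the count: every retained path ends at a
        target by construction, so endpoint participation carries no
        information about mediation.  Ties break toward the smaller residue
        index.
        """
        return sorted(
            self.interior_participation,
            key=lambda n: (-self.interior_participation[n], n),
        )


def build_metagraph(paths) -> MetaGraph:
    """Join retained paths into one graph with recurrence-probability weights."""
    paths = list(paths)
    if not paths:
        raise InvalidArgumentError("cannot build a meta-graph from zero paths")
    edge_counts = Counter()
    participation = Counter()
    interior = Counter()
    for p in paths:
        for e in p.edges:
            edge_counts[e] += 1
        for n in p.nodes:
            participation[n] += 1
        for n in p.nodes[1:-1]:
            interior[n] += 1
    g = nx.Graph()
    for (u, v), c in edge_counts.items():
        g.add_edge(u, v, weight=c / len(paths), count=c)
    return MetaGraph(
        graph=g,
        n_paths=len(paths),
        participation=dict(participation),
        interior_participation=dict(interior),
    )
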