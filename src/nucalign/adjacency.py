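"""Gabriel-graph adjacency modeling and missing-adjacency scoring.

Two landmarks are adjacent in the Gabriel sense when the open ball whose
diameter is their connecting segment contains no third landmark.  Gabriel
edges are a subgraph of the Delaunay graph and serve as a cheap proxy for
cell-cell contact.  Edges present in every member of an ensemble of labeled
clouds ("consistent adjacencies") act as structural constraints on candidate
labelings of an anonymous cloud: a labeling is penalized once for every
consistent edge that is not mirrored by an adjacency between the matched
anonymous points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

from .landmarks_io import LandmarkCloud, LineageEvent

logger = logging.getLogger("nucalign")

Node = Hashable
Edge = tuple  # canonical: tuple(sorted((u, v)))


def _edge(u: Node, v: Node) -> Edge:
    try:
        return (u, v) if u <= v else (v, u)
    except TypeError:  # mixed node types: fall back to a stable total order
        return (u, v) if repr(u) <= repr(v) else (v, u)


@dataclass(frozen=True)
class AdjacencyGraph:
    """An undirected graph over identity names or point indices."""

    nodes: frozenset
    edges: frozenset  # of canonical 2-tuples

    def __post_init__(self) -> None:
        nodes = frozenset(self.nodes)
        edges = frozenset(_edge(u, v) for u, v in self.edges)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            if u not in nodes or v not in nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node set")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    def has_edge(self, u: Node, v: Node) -> bool:
        return _edge(u, v) in self.edges

    def degree(self, u: Node) -> int:
        return sum(1 for e in self.edges if u in e)

    def relabel(self, mapping: Mapping[Node, Node]) -> "AdjacencyGraph":
        """Rename nodes; edges collapsing to self-loops are dropped."""
        nodes = frozenset(mapping.get(n, n) for n in self.nodes)
        edges = set()
        for u, v in self.edges:
            u2, v2 = mapping.get(u, u), mapping.get(v, v)
            if u2 != v2:
                edges.add(_edge(u2, v2))
        return AdjacencyGraph(nodes, frozenset(edges))

    def without_node(self, node: Node) -> "AdjacencyGraph":
        return AdjacencyGraph(self.nodes - {node},
                              frozenset(e for e in self.edges if node not in e))


@dataclass(frozen=True)
class EnsembleModel:
    """Labeled clouds + consistent adjacencies + inconsistent-landmark events."""

    labeled_clouds: tuple[LandmarkCloud, ...]
    consistent_edges: AdjacencyGraph
    inconsistent: tuple[LineageEvent, ...]
    stage_label: str = ""
    window_minutes: float = 13.0


@dataclass(frozen=True)
class ViolationScore:
    """Missing-consistent-adjacency counts, globally and per identity."""

    total: int
    per_identity: Mapping[Node, int]

    def worst(self) -> Node | None:
        if not self.per_identity:
            return None
        return max(self.per_identity, key=lambda k: self.per_identity[k])


# ---------------------------------------------------------------------------
# Gabriel graph
# ---------------------------------------------------------------------------

def _candidate_pairs(points: np.ndarray) -> Iterable[tuple[int, int]]:
    """Delaunay edge candidates, falling back to all pairs for degenerate input."""
    n = len(points)
    if n > 4:
        try:
            tri = Delaunay(points)
        except QhullError:
            pass
        else:
            pairs = set()
            for simplex in tri.simplices:
                for a in range(4):
                    for b in range(a + 1, 4):
                        i, j = simplex[a], simplex[b]
                        pairs.add((min(i, j), max(i, j)))
            return sorted(pairs)
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def gabriel_graph(cloud: LandmarkCloud | np.ndarray) -> AdjacencyGraph:
    """Gabriel graph of a cloud: edge (u, v) iff the open ball on segment uv is empty.

    Nodes are identity names for labeled clouds, integer indices otherwise.
    The emptiness test is strict, so witnesses exactly on the diametral sphere
    do not delete an edge.
    """
    if isinstance(cloud, LandmarkCloud):
        points = cloud.points
        labels: Sequence[Node] = cloud.names if cloud.names is not None else range(len(points))
    else:
        points = np.asarray(cloud, dtype=float)
        labels = range(len(points))
    n = len(points)
    if n < 2:
        raise ValueError(f"need >= 2 points for a Gabriel graph; got {n}")
    tree = cKDTree(points)
    dup = tree.query_pairs(r=0.0)
    if dup:
        raise ValueError(f"duplicate points at index pairs {sorted(dup)[:3]}; perturb input")

    labels = list(labels)
    edges = set()
    for i, j in _candidate_pairs(points):
        mid = 0.5 * (points[i] + points[j])
        r2 = 0.25 * np.dot(points[i] - points[j], points[i] - points[j])
        # the two endpoints sit exactly at radius r, so any interior witness
        # ranks before them among the 3 nearest midpoint neighbours
        k = min(3, n)
        dists, idxs = tree.query(mid, k=k)
        dists, idxs = np.atleast_1d(dists), np.atleast_1d(idxs)
        blocked = any(int(w) not in (i, j) and d * d < r2 for d, w in zip(dists, idxs))
        if not blocked:
            edges.add(_edge(labels[i], labels[j]))
    return AdjacencyGraph(frozenset(labels), frozenset(edges))


# ---------------------------------------------------------------------------
# Ensemble consistency
# ---------------------------------------------------------------------------

def consistent_adjacencies(graphs: Sequence[AdjacencyGraph]) -> AdjacencyGraph:
    """Edges present in every graph of the ensemble (strict intersection)."""
    if not graphs:
        raise ValueError("need at least one adjacency graph")
    edges = frozenset.intersection(*(g.edges for g in graphs))
    nodes = frozenset.intersection(*(g.nodes for g in graphs))
    return AdjacencyGraph(nodes, edges)


def consistency_profile(graphs: Sequence[AdjacencyGraph]) -> dict[Edge, float]:
    """For every edge seen in any graph, the fraction of graphs containing it."""
    if not graphs:
        raise ValueError("need at least one adjacency graph")
    counts: dict[Edge, int] = {}
    for g in graphs:
        for e in g.edges:
            counts[e] = counts.get(e, 0) + 1
    return {e: c / len(graphs) for e, c in counts.items()}


def write_profile(profile: Mapping[Edge, float], path: str | Path) -> None:
    rows = [{"idA": u, "idB": v, "frequency": f}
            for (u, v), f in sorted(profile.items(), key=lambda kv: kv[0])]
    pd.DataFrame(rows, columns=["idA", "idB", "frequency"]).to_csv(path, index=False)


def compile_inconsistent(events: Sequence[LineageEvent], stage_time: float,
                         window: float) -> list[LineageEvent]:
    """Events within ``window/2`` of the stage time, divisions first then deaths.

    The returned order (divisions before deaths, each sorted by subject) fixes
    the traversal order of the greedy modification sweep.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    kept = [e for e in events if abs(e.time - stage_time) <= window / 2]
    divisions = sorted((e for e in kept if e.kind == "division"), key=lambda e: e.subject)
    deaths = sorted((e for e in kept if e.kind == "death"), key=lambda e: e.subject)
    return divisions + deaths


def build_ensemble_model(members: Sequence[LandmarkCloud],
                         events: Sequence[LineageEvent], stage_time: float,
                         window_minutes: float = 13.0,
                         stage_label: str = "") -> EnsembleModel:
    """Assemble the anatomy model for one stage from labeled clouds and events."""
    if not members:
        raise ValueError("need at least one labeled member")
    for m in members:
        if m.names is None:
            raise ValueError(f"member {m.source_id!r} has unnamed points")
    graphs = [gabriel_graph(m) for m in members]
    return EnsembleModel(
        labeled_clouds=tuple(members),
        consistent_edges=consistent_adjacencies(graphs),
        inconsistent=tuple(compile_inconsistent(events, stage_time, window_minutes)),
        stage_label=stage_label,
        window_minutes=window_minutes,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_assignment(assignment, consistent: AdjacencyGraph,
                     unlabeled_graph: AdjacencyGraph,
                     aliases: Mapping[Node, tuple[str, ...]] | None = None) -> ViolationScore:
    """Count consistent adjacencies not mirrored in the unlabeled Gabriel graph.

    ``assignment`` maps unlabeled point index -> identity name (an
    :class:`~nucalign.assign.Assignment` or a plain dict).  A consistent edge
    (A, B) is satisfied when some index assigned to A is adjacent to some index
    assigned to B; otherwise it is charged +1 to the total and +1 to each of A
    and B.  Edges whose endpoint identity is unassigned count as missing.

    ``aliases`` optionally maps a constraint-graph node to the concrete cloud
    names standing in for it (e.g. a split parent represented by its two
    co-located daughters); the edge is satisfied if any alias pair is adjacent.
    """
    mapping: Mapping[int, str] = getattr(assignment, "mapping", assignment)
    rev: dict[str, Node] = {}
    for node in consistent.nodes:
        for name in (aliases or {}).get(node, (node,)):
            rev[name] = node
    node_indices: dict[Node, list[int]] = {}
    for idx, name in mapping.items():
        node = rev.get(name, name)
        node_indices.setdefault(node, []).append(idx)

    uedges = unlabeled_graph.edges
    total = 0
    per: dict[Node, int] = {}
    for u, v in consistent.edges:
        ius, ivs = node_indices.get(u, ()), node_indices.get(v, ())
        satisfied = any(_edge(a, b) in uedges for a in ius for b in ivs)
        if not satisfied:
            total += 1
            per[u] = per.get(u, 0) + 1
            per[v] = per.get(v, 0) + 1
    return ViolationScore(total=total, per_identity=per)
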