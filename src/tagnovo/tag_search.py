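"""Exhaustive enumeration of valid residue paths in a sequence graph.

A valid path visits distinct sequence vertices along traversable edges (the
simple-path rule) and may not contain any two vertices joined by a
short-circuit edge (the short-circuit rule), whether or not those vertices
are adjacent on the path.  Enumeration is a depth-first recursion over
every vertex pair, pruning as soon as the partial path picks up a
short-circuit conflict; dynamic programming is deliberately avoided because
the short-circuit rule is a global constraint on the whole path.

Paths additionally have to chain orientations: stepping into a vertex
through one cleavage site must leave through the other, so that the path
reads a strictly alternating series of sites.  Abstract graphs whose edges
carry no orientation information (``orientations=None``) are treated as
unconstrained.

A path and its reversal denote the same tag, so enumeration reports each
undirected path once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .sequence_graph import SequenceEdge, SequenceGraph

#: Per-step record: the site pairing used between consecutive vertices.
StepOrientation = Optional[Tuple[int, int]]


class PathExplosion(RuntimeError):
    """A component exceeded the configured path budget."""


@dataclass(frozen=True)
class SequencePath:
    vertices: Tuple[int, ...]
    orientations: Tuple[StepOrientation, ...]  # one entry per edge step

    def __len__(self) -> int:
        return len(self.vertices)

    def residues(self, graph: SequenceGraph) -> str:
        return "".join(graph.vertices[i].residue for i in self.vertices)

    def canonical_residues(self, graph: SequenceGraph) -> str:
        s = self.residues(graph)
        return min(s, s[::-1])

    def validate(self, graph: SequenceGraph) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("repeated vertex")
        for a_pos in range(len(self.vertices)):
            for b_pos in range(a_pos + 1, len(self.vertices)):
                if graph.has_short_circuit(self.vertices[a_pos], self.vertices[b_pos]):
                    raise ValueError("short-circuit pair inside path")
        for step, (a, b) in enumerate(zip(self.vertices, self.vertices[1:])):
            if not any(w == b for w, _ in graph.traversable_neighbors(a)):
                raise ValueError("consecutive vertices not traversable")
            del step


def _edge_orientations(edge: SequenceEdge, from_vertex: int) -> List[StepOrientation]:
    """Orientations of an edge as (exit site of from_vertex, entry site of
    the neighbor); None when the edge is unconstrained."""
    if edge.orientations is None:
        return [None]
    if from_vertex == edge.u:
        return [(su, sw) for su, sw in edge.orientations]
    return [(sw, su) for su, sw in edge.orientations]


def find_paths_between(
    source: int,
    destination: int,
    graph: SequenceGraph,
    max_paths: Optional[int] = None,
) -> List[SequencePath]:
    """All valid paths from ``source`` to ``destination``.

    Implements the recursive depth-first scheme: grow the vertex list, bail
    out of any branch whose vertex set already contains a short-circuit
    pair, and record the list whenever the destination is reached.  The
    single-vertex path is returned when source equals destination.
    """
    results: List[SequencePath] = []
    path: List[int] = []
    steps: List[StepOrientation] = []
    in_path = set()

    def conflict(v: int) -> bool:
        return any(graph.has_short_circuit(v, u) for u in path)

    def descend(v: int, entry_site: Optional[int]) -> None:
        if conflict(v):
            return
        path.append(v)
        in_path.add(v)
        if v == destination:
            results.append(SequencePath(tuple(path), tuple(steps)))
            if max_paths is not None and len(results) > max_paths:
                raise PathExplosion(f"more than {max_paths} paths")
        else:
            for neighbor, edge in graph.traversable_neighbors(v):
                if neighbor in in_path:
                    continue
                for orientation in _edge_orientations(edge, v):
                    if (
                        orientation is not None
                        and entry_site is not None
                        and orientation[0] == entry_site
                    ):
                        continue  # must leave through the other site
                    steps.append(orientation)
                    descend(
                        neighbor,
                        orientation[1] if orientation is not None else None,
                    )
                    steps.pop()
        in_path.discard(v)
        path.pop()

    descend(source, None)
    # dedupe identical vertex sequences arising from alternative orientations
    seen = set()
    unique: List[SequencePath] = []
    for p in results:
        if p.vertices not in seen:
            seen.add(p.vertices)
            unique.append(p)
    return unique


def enumerate_all_paths(
    graph: SequenceGraph, max_paths: int = 1_000_000
) -> List[SequencePath]:
    """Every valid path in the graph, one direction per undirected path.

    Iterates over all vertex pairs (plus the single-vertex paths) and
    deduplicates reversals.  Raises :class:`PathExplosion` when the number
    of paths exceeds ``max_paths``; callers treat that component as
    unsequenceable.
    """
    paths: List[SequencePath] = []
    n = graph.n_vertices
    budget = max_paths
    for s in range(n):
        for d in range(s, n):
            found = find_paths_between(s, d, graph, max_paths=budget)
            paths.extend(found)
            budget -= len(found)
            if budget < 0:
                raise PathExplosion(f"more than {max_paths} paths")
    # a path s..d with s < d is found once; s == d yields singletons.
    # Reversals can still duplicate when endpoints coincide in index order.
    seen = set()
    unique: List[SequencePath] = []
    for p in paths:
        key = min(p.vertices, p.vertices[::-1])
        if key not in seen:
            seen.add(key)
            unique.append(p)
    unique.sort(key=lambda p: (-len(p), p.canonical_residues(graph), p.vertices))
    return unique
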