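"""Sequence graphs: from typed fragment-ion relationships to residue vertices.

A *sequence vertex* stands for one candidate residue, supported by the
fragment ions on its two flanking cleavage sites.  Each site holds one or
two spectrum vertices (a lone y or b ion, or a complementary pair joined by
a vertical-bar edge); every cross-site ion pair must be joined by a spectrum
edge labeled with the candidate residue.  A vertex therefore bundles two to
four spectrum vertices and between one and six spectrum edges, and each
vertex is grown to be maximal: no further ion can join a site without
breaking the pattern.

Sequence vertices that share fragment ions are connected by a *traversable*
edge when their ion sets can be laid out as two residues sharing a single
cleavage site, and by a *short-circuit* edge otherwise.  Short-circuit edges
mark residue candidates that can never co-occur in one tag, no matter how
far apart; they are the constraint that path search enforces globally.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, IO, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .spectrum_graph import EdgeType, RESIDUE_EDGE_TYPES, SpectrumGraph

Site = FrozenSet[int]
Orientation = Tuple[int, int]  # (site index in u, site index in w) merged


class SequenceEdgeKind(enum.Enum):
    TRAVERSABLE = "traversable"
    SHORT_CIRCUIT = "short_circuit"


@dataclass(frozen=True)
class SequenceVertex:
    residue: str
    sites: Tuple[Site, Site]
    supporting_edges: Tuple[int, ...] = ()

    @property
    def left_site(self) -> Site:
        return self.sites[0]

    @property
    def right_site(self) -> Site:
        return self.sites[1]

    @property
    def spectrum_vertices(self) -> Set[int]:
        return set(self.sites[0]) | set(self.sites[1])

    def validate(self, graph: Optional[SpectrumGraph] = None) -> None:
        a, b = self.sites
        if not (1 <= len(a) <= 2 and 1 <= len(b) <= 2):
            raise ValueError("each site must hold 1 or 2 spectrum vertices")
        if a & b:
            raise ValueError("sites must be disjoint")
        if graph is not None:
            for site in self.sites:
                for x, y in itertools.combinations(sorted(site), 2):
                    if not any(
                        e.edge_type is EdgeType.VERTICAL_BAR
                        for e in graph.edges_between(x, y)
                    ):
                        raise ValueError("within-site pair lacks a vertical-bar edge")
            for x in a:
                for y in b:
                    if not any(
                        e.edge_type in RESIDUE_EDGE_TYPES and e.residue == self.residue
                        for e in graph.edges_between(x, y)
                    ):
                        raise ValueError("cross-site pair lacks a residue-labeled edge")


@dataclass(frozen=True)
class SequenceEdge:
    u: int
    w: int
    kind: SequenceEdgeKind
    # For traversable edges: the site pairings that realize a shared
    # cleavage site.  None means unconstrained (used by abstract graphs in
    # tests); the empty tuple never occurs on a traversable edge.
    orientations: Optional[Tuple[Orientation, ...]] = None


@dataclass
class SequenceGraph:
    vertices: List[SequenceVertex]
    edges: List[SequenceEdge]
    spectrum_graph: Optional[SpectrumGraph] = None
    _adjacency: Dict[int, List[Tuple[int, SequenceEdge]]] = field(
        default_factory=dict, repr=False
    )
    _sc_pairs: Set[Tuple[int, int]] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        self._adjacency = {i: [] for i in range(len(self.vertices))}
        self._sc_pairs = set()
        for e in self.edges:
            if e.u >= len(self.vertices) or e.w >= len(self.vertices):
                raise ValueError("edge endpoint out of range")
            if e.kind is SequenceEdgeKind.TRAVERSABLE:
                self._adjacency[e.u].append((e.w, e))
                self._adjacency[e.w].append((e.u, e))
            else:
                self._sc_pairs.add((min(e.u, e.w), max(e.u, e.w)))

    def traversable_neighbors(self, u: int) -> List[Tuple[int, SequenceEdge]]:
        return self._adjacency[u]

    def has_short_circuit(self, u: int, w: int) -> bool:
        return (min(u, w), max(u, w)) in self._sc_pairs

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def _vb_partners(graph: SpectrumGraph, v: int) -> List[int]:
    partners = []
    for e in graph.edges:
        if e.edge_type is EdgeType.VERTICAL_BAR:
            if e.i == v:
                partners.append(e.j)
            elif e.j == v:
                partners.append(e.i)
    return partners


def _has_residue_edge(graph: SpectrumGraph, a: int, b: int, residue: str) -> bool:
    return any(
        e.edge_type in RESIDUE_EDGE_TYPES and e.residue == residue
        for e in graph.edges_between(a, b)
    )


def _supporting_edges(
    graph: SpectrumGraph, residue: str, site_a: Site, site_b: Site
) -> Tuple[int, ...]:
    indices: List[int] = []
    for site in (site_a, site_b):
        for x, y in itertools.combinations(sorted(site), 2):
            for k in graph.edge_indices_between(x, y):
                if graph.edges[k].edge_type is EdgeType.VERTICAL_BAR:
                    indices.append(k)
    for x in site_a:
        for y in site_b:
            for k in graph.edge_indices_between(x, y):
                e = graph.edges[k]
                if e.edge_type in RESIDUE_EDGE_TYPES and e.residue == residue:
                    indices.append(k)
    return tuple(sorted(set(indices)))


def build_sequence_vertices(graph: SpectrumGraph) -> List[SequenceVertex]:
    """Enumerate all maximal residue vertices supported by the spectrum graph.

    Each residue-labeled spectrum edge seeds a candidate with its endpoints
    on opposite sites; the sites are then extended with vertical-bar
    partners that keep every cross-site pair labeled with the residue.  All
    consistent extensions are enumerated and only set-maximal candidates
    are kept, so the result does not depend on seed order.
    """
    vb_cache: Dict[int, List[int]] = {}

    def partners(v: int) -> List[int]:
        if v not in vb_cache:
            vb_cache[v] = _vb_partners(graph, v)
        return vb_cache[v]

    candidates: Set[Tuple[str, FrozenSet[Site]]] = set()
    for e in graph.edges:
        if e.edge_type not in RESIDUE_EDGE_TYPES:
            continue
        residue = e.residue
        assert residue is not None
        i, j = e.i, e.j
        p_opts: List[Optional[int]] = [None] + [
            p for p in partners(i) if p != j and _has_residue_edge(graph, p, j, residue)
        ]
        q_opts: List[Optional[int]] = [None] + [
            q for q in partners(j) if q != i and _has_residue_edge(graph, i, q, residue)
        ]
        for p in p_opts:
            for q in q_opts:
                if p is not None and q is not None:
                    if p == q or not _has_residue_edge(graph, p, q, residue):
                        continue
                site_a = frozenset({i} | ({p} if p is not None else set()))
                site_b = frozenset({j} | ({q} if q is not None else set()))
                if site_a & site_b:
                    continue
                candidates.add((residue, frozenset({site_a, site_b})))

    # keep only maximal candidates per residue
    def dominated(c: Tuple[str, FrozenSet[Site]], d: Tuple[str, FrozenSet[Site]]) -> bool:
        if c[0] != d[0] or c == d:
            return False
        c_sites = sorted(c[1], key=sorted)
        d_sites = list(d[1])
        if len(c_sites) == 1:  # degenerate; should not happen (sites disjoint)
            return False
        for da, db in itertools.permutations(d_sites, 2):
            if c_sites[0] <= da and c_sites[1] <= db:
                return True
        return False

    maximal = [
        c for c in candidates if not any(dominated(c, d) for d in candidates)
    ]

    vertices: List[SequenceVertex] = []
    for residue, sites in maximal:
        site_list = sorted(sites, key=lambda s: (min(s), sorted(s)))
        if len(site_list) != 2:
            continue
        site_a, site_b = site_list
        vertices.append(
            SequenceVertex(
                residue=residue,
                sites=(site_a, site_b),
                supporting_edges=_supporting_edges(graph, residue, site_a, site_b),
            )
        )
    # deterministic ordering: by smallest spectrum vertex, then residue
    vertices.sort(key=lambda v: (sorted(v.spectrum_vertices), v.residue))
    return vertices


def _merge_orientations(
    graph: SpectrumGraph, u: SequenceVertex, w: SequenceVertex
) -> Tuple[Orientation, ...]:
    """Site pairings under which u and w share one cleavage site."""
    orientations: List[Orientation] = []
    for su in (0, 1):
        for sw in (0, 1):
            merged = u.sites[su] | w.sites[sw]
            if len(merged) > 2:
                continue
            if len(merged) == 2:
                x, y = sorted(merged)
                if not any(
                    e.edge_type is EdgeType.VERTICAL_BAR
                    for e in graph.edges_between(x, y)
                ):
                    continue
            other_u = u.sites[1 - su]
            other_w = w.sites[1 - sw]
            if other_u & other_w or other_u & merged or other_w & merged:
                continue
            orientations.append((su, sw))
    return tuple(orientations)


def build_sequence_edges(
    vertices: Sequence[SequenceVertex], graph: SpectrumGraph
) -> List[SequenceEdge]:
    """Connect every ion-sharing vertex pair: traversable when an orientation
    merges one site of each into a single shared cleavage site, otherwise
    short-circuit."""
    edges: List[SequenceEdge] = []
    for a, b in itertools.combinations(range(len(vertices)), 2):
        u, w = vertices[a], vertices[b]
        if not (u.spectrum_vertices & w.spectrum_vertices):
            continue
        orientations = _merge_orientations(graph, u, w)
        if orientations:
            edges.append(
                SequenceEdge(a, b, SequenceEdgeKind.TRAVERSABLE, orientations)
            )
        else:
            edges.append(SequenceEdge(a, b, SequenceEdgeKind.SHORT_CIRCUIT, None))
    return edges


def build_sequence_graph(graph: SpectrumGraph) -> SequenceGraph:
    vertices = build_sequence_vertices(graph)
    edges = build_sequence_edges(vertices, graph)
    return SequenceGraph(vertices=vertices, edges=edges, spectrum_graph=graph)


def connected_components(graph: SequenceGraph) -> List[SequenceGraph]:
    """Split by traversable-edge connectivity, largest component first.

    Short-circuit edges are retained inside the component containing both
    endpoints; edges spanning components are irrelevant to path validity
    because a path never leaves its component.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_vertices))
    for e in graph.edges:
        if e.kind is SequenceEdgeKind.TRAVERSABLE:
            g.add_edge(e.u, e.w)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))
    result: List[SequenceGraph] = []
    for comp in components:
        index = {old: new for new, old in enumerate(comp)}
        members = set(comp)
        sub_edges = [
            SequenceEdge(index[e.u], index[e.w], e.kind, e.orientations)
            for e in graph.edges
            if e.u in members and e.w in members
        ]
        result.append(
            SequenceGraph(
                vertices=[graph.vertices[i] for i in comp],
                edges=sub_edges,
                spectrum_graph=graph.spectrum_graph,
            )
        )
    return result


def dump(graph: SequenceGraph, stream: IO[str]) -> None:
    """Tab-separated vertex and edge tables for debugging."""
    stream.write("vertex\tresidue\tsite_a\tsite_b\n")
    for i, v in enumerate(graph.vertices):
        a, b = v.sites
        stream.write(
            f"{i}\t{v.residue}\t{','.join(map(str, sorted(a)))}"
            f"\t{','.join(map(str, sorted(b)))}\n"
        )
    stream.write("u\tw\tkind\n")
    for e in graph.edges:
        stream.write(f"{e.u}\t{e.w}\t{e.kind.value}\n")
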