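"""Shared fixtures: residue table, zero-error spectra, abstract graphs."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pytest

from tagnovo.chem import DEFAULT_TABLE
from tagnovo.ms_io import FragmentIon, TandemSpectrum
from tagnovo.sequence_graph import (
    SequenceEdge,
    SequenceEdgeKind,
    SequenceGraph,
    SequenceVertex,
)
from tagnovo.simulate import theoretical_fragments


@pytest.fixture
def table():
    return DEFAULT_TABLE


def make_ladder_spectrum(
    peptide: str,
    scan_id: int = 1,
    charge: int = 2,
    only_sites: Optional[Sequence[int]] = None,
) -> TandemSpectrum:
    """Zero-error spectrum with the complete (or site-restricted) y/b
    ladders of a peptide.  ``only_sites`` selects cleavage sites 1..n-1;
    both the b and the y ion of each selected site are included."""
    n = len(peptide)
    parent = DEFAULT_TABLE.peptide_neutral_mass(peptide)
    b_ladder, y_ladder = theoretical_fragments(peptide)
    masses = []
    for site in range(1, n):
        if only_sites is not None and site not in only_sites:
            continue
        masses.append(b_ladder[site - 1])
        masses.append(y_ladder[n - site - 1])
    masses = sorted(set(masses))
    ions = [FragmentIon(0.0, 100.0, 1)] + [FragmentIon(m, 50.0, 1) for m in masses]
    spectrum = TandemSpectrum(scan_id, parent, charge, ions)
    spectrum.validate()
    return spectrum


def make_abstract_graph(
    n: int,
    traversable: Sequence[Tuple[int, int]],
    short_circuit: Sequence[Tuple[int, int]] = (),
    residues: Optional[str] = None,
) -> SequenceGraph:
    """Sequence graph with dummy vertices and unconstrained orientations,
    for exercising the path-search rules in isolation."""
    residues = residues or ("A" * n)
    vertices = [
        SequenceVertex(
            residue=residues[i],
            sites=(frozenset({2 * i}), frozenset({2 * i + 1})),
        )
        for i in range(n)
    ]
    edges: List[SequenceEdge] = []
    for u, w in traversable:
        edges.append(
            SequenceEdge(min(u, w), max(u, w), SequenceEdgeKind.TRAVERSABLE, None)
        )
    for u, w in short_circuit:
        edges.append(
            SequenceEdge(min(u, w), max(u, w), SequenceEdgeKind.SHORT_CIRCUIT, None)
        )
    return SequenceGraph(vertices=vertices, edges=edges)


def random_abstract_graph(
    rng: np.random.Generator,
    max_vertices: int = 12,
    p_traversable: float = 0.3,
    p_short_circuit: float = 0.15,
) -> SequenceGraph:
    n = int(rng.integers(2, max_vertices + 1))
    traversable = []
    short = []
    for u in range(n):
        for w in range(u + 1, n):
            r = rng.random()
            if r < p_traversable:
                traversable.append((u, w))
            elif r < p_traversable + p_short_circuit:
                short.append((u, w))
    letters = "".join(rng.choice(list("ACDEFGHJK"), size=n))
    return make_abstract_graph(n, traversable, short, residues=letters)


def brute_force_paths(graph: SequenceGraph) -> set:
    """Independent oracle: all simple paths over traversable edges, filtered
    by the short-circuit rule, deduplicated under reversal."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n_vertices))
    for e in graph.edges:
        if e.kind is SequenceEdgeKind.TRAVERSABLE:
            g.add_edge(e.u, e.w)
    found = set()
    for s in range(graph.n_vertices):
        found.add((s,))
        for d in range(s + 1, graph.n_vertices):
            for path in nx.all_simple_paths(g, s, d):
                ok = True
                for i in range(len(path)):
                    for j in range(i + 1, len(path)):
                        if graph.has_short_circuit(path[i], path[j]):
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    t = tuple(path)
                    found.add(min(t, t[::-1]))
    return found
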