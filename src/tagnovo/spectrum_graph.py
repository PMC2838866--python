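"""Typed spectrum graphs for high-mass-accuracy de novo sequencing.

Every deisotoped product ion of a tandem spectrum — including the zero-mass
anchor — is one vertex.  Pairs of vertices are connected by up to four types
of edges, each encoding one arithmetic relationship a pair of y/b fragment
ions flanking a residue can satisfy:

* **arrow** — same-series neighbours: ``|(m_j - m_i) - M(R)| < delta``
* **vertical bar** — complementary pair: ``|(m_j + m_i) - P| < delta``
* **forward slash** — cross-series neighbours: ``|P - (m_j + m_i) - M(R)| < delta``
* **backslash** — cross-series neighbours: ``|(m_j + m_i) - P - M(R)| < delta``

``P`` is the neutral parent mass and ``delta`` the relative-mass-error
tolerance.  Each edge records its relative mass error ``epsilon`` and a
standardized weight in (0, 1] derived from a half-normal model of the error
distribution.  The conditions are purely arithmetic, so coincidental (false)
edges between unrelated ions are expected and are resolved downstream by
path scoring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import IO, Dict, List, Optional, Tuple

from math import erfc, sqrt

from .chem import AminoAcidTable, DEFAULT_TABLE
from .ms_io import TandemSpectrum


class EdgeType(enum.Enum):
    ARROW = "arrow"
    FORWARD_SLASH = "forward_slash"
    BACKSLASH = "backslash"
    VERTICAL_BAR = "vertical_bar"


#: Edge types whose defining condition involves a residue mass.
RESIDUE_EDGE_TYPES = (EdgeType.ARROW, EdgeType.FORWARD_SLASH, EdgeType.BACKSLASH)


@dataclass(frozen=True)
class SpectrumEdge:
    i: int  # lighter vertex (by mass)
    j: int  # heavier vertex
    edge_type: EdgeType
    residue: Optional[str]  # None exactly for vertical-bar edges
    epsilon: float
    weight: float

    def __post_init__(self) -> None:
        if (self.residue is None) != (self.edge_type is EdgeType.VERTICAL_BAR):
            raise ValueError("vertical-bar edges and only they carry no residue")


@dataclass
class SpectrumGraph:
    spectrum: TandemSpectrum
    delta: float
    edges: List[SpectrumEdge]
    table: AminoAcidTable = DEFAULT_TABLE

    def __post_init__(self) -> None:
        self._by_pair: Dict[Tuple[int, int], List[int]] = {}
        for idx, e in enumerate(self.edges):
            self._by_pair.setdefault((e.i, e.j), []).append(idx)

    def edges_between(self, a: int, b: int) -> List[SpectrumEdge]:
        i, j = (a, b) if a < b else (b, a)
        return [self.edges[k] for k in self._by_pair.get((i, j), ())]

    def edge_indices_between(self, a: int, b: int) -> List[int]:
        i, j = (a, b) if a < b else (b, a)
        return list(self._by_pair.get((i, j), ()))

    @property
    def n_vertices(self) -> int:
        return len(self.spectrum.ions)


def edge_weight(epsilon: float, delta: float) -> float:
    """Standardize a relative mass error to an edge weight.

    ``w = 2 * (1 - Phi(epsilon / (delta/2)))`` with Phi the standard normal
    CDF: an error of zero scores 1.00, an error at the tolerance scores
    2*(1 - Phi(2)) ~ 0.05.  Strictly decreasing in epsilon.
    """
    if epsilon < 0 or epsilon > delta:
        raise ValueError("epsilon must lie in [0, delta]")
    # 2 * (1 - Phi(z)) == erfc(z / sqrt(2))
    return erfc(epsilon / (delta / 2.0) / sqrt(2.0))


def classify_pair(
    m_i: float,
    m_j: float,
    parent_mass: float,
    delta: float,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> List[Tuple[EdgeType, Optional[str], float]]:
    """All edge relationships a vertex pair satisfies at tolerance ``delta``.

    Returns ``(edge type, residue or None, epsilon)`` triples; a pair may
    satisfy several conditions simultaneously and each match is reported.
    """
    if m_i >= m_j:
        raise ValueError("requires m_i < m_j")
    results: List[Tuple[EdgeType, Optional[str], float]] = []
    diff = m_j - m_i
    total = m_j + m_i
    eps = abs(total - parent_mass)
    if eps < delta:
        results.append((EdgeType.VERTICAL_BAR, None, eps))
    for residue, mass in table.items():
        eps = abs(diff - mass)
        if eps < delta:
            results.append((EdgeType.ARROW, residue, eps))
        eps = abs(parent_mass - total - mass)
        if eps < delta:
            results.append((EdgeType.FORWARD_SLASH, residue, eps))
        eps = abs(total - parent_mass - mass)
        if eps < delta:
            results.append((EdgeType.BACKSLASH, residue, eps))
    return results


def build_spectrum_graph(
    spectrum: TandemSpectrum,
    delta: float = 0.01,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> SpectrumGraph:
    """Classify every vertex pair of a spectrum into typed, weighted edges."""
    spectrum.validate()
    masses = [ion.neutral_mass for ion in spectrum.ions]
    parent = spectrum.parent_neutral_mass
    edges: List[SpectrumEdge] = []
    n = len(masses)
    for i in range(n):
        for j in range(i + 1, n):
            for edge_type, residue, eps in classify_pair(
                masses[i], masses[j], parent, delta, table
            ):
                edges.append(
                    SpectrumEdge(i, j, edge_type, residue, eps, edge_weight(eps, delta))
                )
    return SpectrumGraph(spectrum=spectrum, delta=delta, edges=edges, table=table)


def dump_edges(graph: SpectrumGraph, stream: IO[str]) -> None:
    """Tab-separated edge list (i, j, type, residue, epsilon, weight)."""
    stream.write("i\tj\ttype\tresidue\tepsilon\tweight\n")
    for e in graph.edges:
        stream.write(
            f"{e.i}\t{e.j}\t{e.edge_type.value}\t{e.residue or '-'}"
            f"\t{e.epsilon:.6f}\t{e.weight:.4f}\n"
        )
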