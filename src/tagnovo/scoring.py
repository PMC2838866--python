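"""Path scoring, tag ranking, residual masses and consensus tags.

A sequence path is scored by the summed weights of all spectrum edges it
covers — the residue-labeled edges across each vertex's two sites plus the
vertical-bar edges within them, each counted once even when shared by
adjacent vertices.  The score therefore rewards cleavage sites confirmed by
complementary ion pairs (up to six edges per residue) far more than lone
ion ladder steps (a single edge per residue).

Residual masses locate a tag inside its peptide: ``mp`` is the fragment
mass from one terminus to the tag's first cleavage site and ``mq`` the
balance ``P - mp - sum of tag residue masses``.  Each ion at a boundary
site can be read directly (a prefix fragment of mass ``m``) or through its
complement (``P - m``); the estimate averages the readings that agree,
which uses all ions along the path instead of a single one.

A consensus tag is the longest residue string that reads contiguously, in
either direction, within both of the spectrum's two top-ranked tags.  It is
correct whenever either parent is, because a substring of a correct tag is
itself a correct tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, List, Optional, Sequence, Set, Tuple

from .config import RunConfig
from .sequence_graph import SequenceGraph
from .tag_search import SequencePath


class InvalidPath(ValueError):
    """A path whose residual masses are negative beyond tolerance."""


@dataclass(frozen=True)
class SequenceTag:
    residues: str
    mp: float
    mq: float
    score: float
    covered_edges: frozenset
    scan_id: int = -1
    # per-position summed supporting-edge weight, aligned with `residues`
    position_scores: Tuple[float, ...] = ()

    def reversed(self) -> "SequenceTag":
        return SequenceTag(
            self.residues[::-1],
            self.mq,
            self.mp,
            self.score,
            self.covered_edges,
            self.scan_id,
            self.position_scores[::-1],
        )


@dataclass(frozen=True)
class ConsensusTag:
    residues: str
    parent_tags: Tuple[SequenceTag, SequenceTag]
    scan_id: int = -1


def covered_spectrum_edges(path: SequencePath, graph: SequenceGraph) -> Set[int]:
    """Union of the spectrum edges supporting each vertex on the path."""
    covered: Set[int] = set()
    for v in path.vertices:
        covered.update(graph.vertices[v].supporting_edges)
    return covered


def score_path(path: SequencePath, graph: SequenceGraph) -> float:
    spectrum_graph = graph.spectrum_graph
    if spectrum_graph is None:
        raise ValueError("sequence graph lacks its spectrum graph")
    return sum(
        spectrum_graph.edges[k].weight for k in covered_spectrum_edges(path, graph)
    )


def _ordered_sites(path: SequencePath, graph: SequenceGraph):
    """Cleavage sites S_0..S_m read along the path's stored orientation."""
    vertices = [graph.vertices[i] for i in path.vertices]
    if len(vertices) == 1:
        return [vertices[0].sites[0], vertices[0].sites[1]]
    sites = []
    first_exit = path.orientations[0]
    if first_exit is None:
        raise ValueError("path lacks orientation information")
    sites.append(vertices[0].sites[1 - first_exit[0]])
    for step, orientation in enumerate(path.orientations):
        exit_site = vertices[step].sites[orientation[0]]
        entry_site = vertices[step + 1].sites[orientation[1]]
        sites.append(frozenset(exit_site | entry_site))
    last_entry = path.orientations[-1][1]
    sites.append(vertices[-1].sites[1 - last_entry])
    # the loop above appends the merged sites; the final element replaces
    # nothing — sites = [S_0, S_1..S_m-1 merged, S_m]
    return sites


def residual_masses(
    path: SequencePath, graph: SequenceGraph, parent_mass: float
) -> Tuple[float, float]:
    """Estimate (mp, mq) for a path by clustering consistent site readings.

    Every ion at site k yields two candidate values for the mass at S_0:
    its mass read as a prefix fragment minus the residue offset to site k,
    or its complement ``P - m`` minus the same offset.  The readings
    belonging to one consistent direction of the tag agree to within the
    accumulated mass tolerance and form the largest cluster; ``mp`` is
    their mean and ``mq`` the balance against the parent mass.
    """
    spectrum_graph = graph.spectrum_graph
    if spectrum_graph is None:
        raise ValueError("sequence graph lacks its spectrum graph")
    masses = spectrum_graph.spectrum.masses
    residues = path.residues(graph)
    offsets = [0.0]
    for r in residues:
        offsets.append(offsets[-1] + spectrum_graph.table.mass(r))
    sites = _ordered_sites(path, graph)
    tolerance = max((len(residues) + 1) * spectrum_graph.delta, 1e-9)
    candidates: List[float] = []
    for k, site in enumerate(sites):
        for ion_index in site:
            m = masses[ion_index]
            candidates.append(m - offsets[min(k, len(offsets) - 1)])
            candidates.append((parent_mass - m) - offsets[min(k, len(offsets) - 1)])
    candidates.sort()
    best_members: List[float] = []
    best_center = None
    for center in candidates:
        members = [c for c in candidates if abs(c - center) <= tolerance]
        if len(members) > len(best_members) or (
            len(members) == len(best_members)
            and (best_center is None or center < best_center)
        ):
            best_members = members
            best_center = center
    mp = sum(best_members) / len(best_members)
    if abs(mp) < 1e-9:
        mp = 0.0
    mq = parent_mass - mp - offsets[-1]
    if abs(mq) < 1e-9:
        mq = 0.0
    if mp < -tolerance or mq < -tolerance:
        raise InvalidPath(
            f"negative residual mass (mp={mp:.4f}, mq={mq:.4f}) beyond tolerance"
        )
    return mp, mq


def _position_scores(path: SequencePath, graph: SequenceGraph) -> Tuple[float, ...]:
    spectrum_graph = graph.spectrum_graph
    assert spectrum_graph is not None
    return tuple(
        sum(spectrum_graph.edges[k].weight for k in graph.vertices[v].supporting_edges)
        for v in path.vertices
    )


def tag_from_path(
    path: SequencePath,
    graph: SequenceGraph,
    parent_mass: float,
    scan_id: int = -1,
) -> SequenceTag:
    """Build a tag in canonical direction (lexicographically smaller string)."""
    mp, mq = residual_masses(path, graph, parent_mass)
    covered = frozenset(covered_spectrum_edges(path, graph))
    spectrum_graph = graph.spectrum_graph
    assert spectrum_graph is not None
    score = sum(spectrum_graph.edges[k].weight for k in covered)
    residues = path.residues(graph)
    tag = SequenceTag(
        residues=residues,
        mp=mp,
        mq=mq,
        score=score,
        covered_edges=covered,
        scan_id=scan_id,
        position_scores=_position_scores(path, graph),
    )
    if tag.residues[::-1] < tag.residues:
        tag = tag.reversed()
    return tag


def rank_tags(
    paths: Iterable[SequencePath],
    graph: SequenceGraph,
    config: Optional[RunConfig] = None,
    parent_mass: Optional[float] = None,
    scan_id: int = -1,
) -> List[SequenceTag]:
    """Score, filter and order all candidate tags of one spectrum.

    Tags shorter than ``config.min_tag_length`` are removed; the remainder
    are sorted by score descending with deterministic tie-breaks (longer
    first, then lexicographic).  Whether the spectrum counts as sequenced
    is decided by comparing the top tag's score against
    ``config.score_cutoff`` (see :func:`is_sequenced`).
    """
    config = config or RunConfig()
    if parent_mass is None:
        if graph.spectrum_graph is None:
            raise ValueError("parent mass unavailable")
        parent_mass = graph.spectrum_graph.spectrum.parent_neutral_mass
    tags: List[SequenceTag] = []
    for path in paths:
        if len(path) < config.min_tag_length:
            continue
        try:
            tags.append(tag_from_path(path, graph, parent_mass, scan_id))
        except InvalidPath:
            continue
    tags.sort(key=lambda t: (-t.score, -len(t.residues), t.residues))
    return tags


def is_sequenced(tags: Sequence[SequenceTag], config: Optional[RunConfig] = None) -> bool:
    config = config or RunConfig()
    return bool(tags) and tags[0].score >= config.score_cutoff


def _common_substrings(a: str, b: str) -> List[Tuple[int, int, int]]:
    """All (length, start_in_a, start_in_b) of maximal common substrings."""
    best: List[Tuple[int, int, int]] = []
    best_len = 0
    table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                table[i][j] = table[i - 1][j - 1] + 1
                length = table[i][j]
                if length > best_len:
                    best_len = length
                    best = [(length, i - length, j - length)]
                elif length == best_len and length > 0:
                    best.append((length, i - length, j - length))
    return best


def consensus_tag(
    top_tag: SequenceTag,
    second_tag: SequenceTag,
    min_len: int = 3,
) -> Optional[ConsensusTag]:
    """Longest common contiguous residue string of the two top tags.

    Both reading directions of each tag are considered.  Ties between
    equally long candidates are broken by the summed per-position score of
    the span in the top tag, then lexicographically on the canonical
    (smaller-direction) string.  Returns None when the best common string
    is shorter than ``min_len``.
    """
    candidates: List[Tuple[float, str]] = []
    for second_string in (second_tag.residues, second_tag.residues[::-1]):
        for length, start_a, _start_b in _common_substrings(
            top_tag.residues, second_string
        ):
            if length < min_len:
                continue
            span = top_tag.residues[start_a : start_a + length]
            if top_tag.position_scores:
                coverage = sum(top_tag.position_scores[start_a : start_a + length])
            else:
                coverage = 0.0
            candidates.append((coverage, span))
    if not candidates:
        return None
    max_len = max(len(span) for _c, span in candidates)
    candidates = [c for c in candidates if len(c[1]) == max_len]
    candidates.sort(key=lambda c: (-c[0], min(c[1], c[1][::-1])))
    _coverage, span = candidates[0]
    canonical = min(span, span[::-1])
    return ConsensusTag(
        residues=canonical,
        parent_tags=(top_tag, second_tag),
        scan_id=top_tag.scan_id,
    )


def write_tag_table(tags: Iterable[SequenceTag], stream: IO[str]) -> None:
    """Tab-separated output: scan, mp, tag, mq, score (masses to 3 decimals,
    scores to 1)."""
    stream.write("scan\tresidual_mass_1\ttag\tresidual_mass_2\tscore\n")
    for tag in tags:
        stream.write(
            f"{tag.scan_id}\t{tag.mp:.3f}\t{tag.residues}\t{tag.mq:.3f}\t{tag.score:.1f}\n"
        )
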