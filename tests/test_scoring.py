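"""Path scoring, residual masses, tag ranking and consensus derivation."""

import pytest

from tagnovo.chem import DEFAULT_TABLE, WATER
from tagnovo.ms_io import FragmentIon, TandemSpectrum
from tagnovo.pipeline import sequence_spectrum
from tagnovo.scoring import (
    SequenceTag,
    consensus_tag,
    covered_spectrum_edges,
    rank_tags,
    residual_masses,
    score_path,
)
from tagnovo.sequence_graph import build_sequence_graph
from tagnovo.spectrum_graph import build_spectrum_graph, edge_weight
from tagnovo.tag_search import enumerate_all_paths

from conftest import make_ladder_spectrum


def spectrum_from_masses(masses, parent):
    ions = [FragmentIon(0.0, 100.0, 1)] + [
        FragmentIon(m, 50.0, 1) for m in sorted(masses)
    ]
    spectrum = TandemSpectrum(1, parent, 2, ions)
    spectrum.validate()
    return spectrum


def graph_and_paths(masses, parent):
    graph = build_sequence_graph(build_spectrum_graph(spectrum_from_masses(masses, parent)))
    return graph, enumerate_all_paths(graph)


MA = DEFAULT_TABLE.mass("A")
MW = DEFAULT_TABLE.mass("W")

#: Complementary ion pairs of one alanine at P = 1000: sites at prefix
#: masses 300 and 300 + M(A).
ONE_RESIDUE_IONS = [300.0, 300.0 + MA, 700.0 - MA, 700.0]
#: Extended by a tryptophan sharing the middle cleavage site.
TWO_RESIDUE_IONS = sorted(
    ONE_RESIDUE_IONS + [300.0 + MA + MW, 700.0 - MA - MW]
)


class TestCoveredEdges:
    def test_single_four_ion_vertex_covers_six(self):
        graph, paths = graph_and_paths(ONE_RESIDUE_IONS, 1000.0)
        singles = [p for p in paths if len(p) == 1]
        assert len(singles) == 1
        assert len(covered_spectrum_edges(singles[0], graph)) == 6
        assert score_path(singles[0], graph) == pytest.approx(6.0, abs=1e-9)

    def test_lone_arrow_covers_one(self):
        graph, paths = graph_and_paths([300.0, 300.0 + MA], 2000.0)
        assert len(paths) == 1
        assert len(covered_spectrum_edges(paths[0], graph)) == 1
        assert score_path(paths[0], graph) == pytest.approx(1.0, abs=1e-9)

    def test_lone_arrow_at_half_tolerance(self):
        graph, paths = graph_and_paths([300.0, 300.0 + MA + 0.005], 2000.0)
        assert len(paths) == 1
        assert score_path(paths[0], graph) == pytest.approx(
            edge_weight(0.005, 0.01), abs=1e-6
        )

    def test_adjacent_four_ion_vertices_cover_eleven(self):
        """The six-ion two-residue pattern has 4 arrows, 3 vertical bars
        and 2+2 slash edges; adjacent vertices share exactly the one
        vertical bar inside the common site, so 6 + 6 - 1 = 11."""
        graph, paths = graph_and_paths(TWO_RESIDUE_IONS, 1000.0)
        pairs = [p for p in paths if len(p) == 2]
        assert len(pairs) == 1
        assert len(covered_spectrum_edges(pairs[0], graph)) == 11

    def test_extension_never_lowers_score(self):
        graph, paths = graph_and_paths(TWO_RESIDUE_IONS, 1000.0)
        by_len = {len(p): score_path(p, graph) for p in paths}
        assert by_len[2] > by_len[1] or len(by_len) == 1


class TestResidualMasses:
    def test_zero_error_identity(self):
        peptide = "TSVWK"
        spectrum = make_ladder_spectrum(peptide)
        graph = build_sequence_graph(build_spectrum_graph(spectrum))
        parent = spectrum.parent_neutral_mass
        for path in enumerate_all_paths(graph):
            mp, mq = residual_masses(path, graph, parent)
            total = mp + sum(
                DEFAULT_TABLE.mass(r) for r in path.residues(graph)
            ) + mq
            assert total == pytest.approx(parent, abs=1e-9)
            assert mp >= 0 and mq >= 0

    def test_anchor_start_gives_zero_mp(self):
        peptide = "TSVWK"
        spectrum = make_ladder_spectrum(peptide)
        result = sequence_spectrum(spectrum)
        top = result.top_tag
        assert top is not None
        assert top.residues in ("TSVW", "WVST")
        assert min(top.mp, top.mq) == pytest.approx(0.0, abs=1e-9)
        assert max(top.mp, top.mq) == pytest.approx(
            DEFAULT_TABLE.mass("K") + WATER, abs=1e-9
        )

    def test_interior_tag_mp_matches_prefix(self):
        peptide = "TSVWKE"
        spectrum = make_ladder_spectrum(peptide, only_sites=(2, 3, 4))
        graph = build_sequence_graph(build_spectrum_graph(spectrum))
        paths = enumerate_all_paths(graph)
        longest = paths[0]
        assert longest.residues(graph) in ("VW", "WV")
        mp, mq = residual_masses(longest, graph, spectrum.parent_neutral_mass)
        prefix = DEFAULT_TABLE.mass("T") + DEFAULT_TABLE.mass("S")
        suffix = DEFAULT_TABLE.mass("K") + DEFAULT_TABLE.mass("E") + WATER
        assert sorted([mp, mq]) == pytest.approx(
            sorted([prefix, suffix]), abs=1e-9
        )


class TestRankTags:
    def test_longer_path_ranks_first(self):
        peptide = "TSVWK"
        spectrum = make_ladder_spectrum(peptide)
        graph = build_sequence_graph(build_spectrum_graph(spectrum))
        tags = rank_tags(enumerate_all_paths(graph), graph)
        assert len(tags) >= 2
        assert len(tags[0].residues) >= len(tags[1].residues)
        assert tags[0].score >= tags[1].score

    def test_min_length_filter(self):
        graph = build_sequence_graph(
            build_spectrum_graph(spectrum_from_masses([300.0, 371.03711], 2000.0))
        )
        tags = rank_tags(enumerate_all_paths(graph), graph)
        assert tags == []  # a single residue is below the default minimum

    def test_score_recomputation(self):
        spectrum = make_ladder_spectrum("TSVWK")
        spectrum_graph = build_spectrum_graph(spectrum)
        graph = build_sequence_graph(spectrum_graph)
        for tag in rank_tags(enumerate_all_paths(graph), graph):
            recomputed = sum(
                edge_weight(spectrum_graph.edges[k].epsilon, spectrum_graph.delta)
                for k in tag.covered_edges
            )
            assert tag.score == pytest.approx(recomputed, abs=1e-9)


def make_tag(residues, score=10.0, position_scores=None):
    return SequenceTag(
        residues=residues,
        mp=100.0,
        mq=200.0,
        score=score,
        covered_edges=frozenset(),
        scan_id=1,
        position_scores=tuple(position_scores or [1.0] * len(residues)),
    )


class TestConsensus:
    def test_nested_tags(self):
        result = consensus_tag(make_tag("SAASGJT"), make_tag("AASGJT"))
        assert result is not None
        assert result.residues == min("AASGJT", "AASGJT"[::-1])

    def test_identity(self):
        result = consensus_tag(make_tag("AGDVK"), make_tag("AGDVK"))
        assert result.residues == min("AGDVK", "KVDGA")

    def test_disjoint_tags_give_none(self):
        assert consensus_tag(make_tag("AGDVK"), make_tag("TPSEW")) is None

    def test_reverse_direction_match(self):
        result = consensus_tag(make_tag("AGDVK"), make_tag("KVDG"))
        assert result is not None
        assert len(result.residues) == 4

    def test_short_overlap_discarded(self):
        assert consensus_tag(make_tag("AGDVK"), make_tag("VKWTT")) is None

    def test_consensus_no_longer_than_parents(self):
        top, second = make_tag("SAASGJT"), make_tag("AASGJV")
        result = consensus_tag(top, second)
        assert result is not None
        assert len(result.residues) < len(top.residues)
        assert len(result.residues) <= len(second.residues)
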