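"""Tag verification, error typing and figures of merit."""

import pytest
from hypothesis import given, settings, strategies as st

from tagnovo.benchmark import (
    ErrorType,
    IdentificationRecord,
    Validity,
    classify_error,
    error_histogram,
    figures_of_merit,
    mass_coverage,
    coverage_bin,
    strip_flanks,
    verify_tag,
    verify_run,
)
from tagnovo.chem import DEFAULT_TABLE, WATER

# Worked nine-scan example: residual mass / tag / residual mass / score /
# validity / identification (None = no confident identification).
SAMPLE_ROWS = [
    (1616, 1001.540, "APAJG", 146.112, 8.7, "correct", "K.RVFNVLTGDAPAIGK.V"),
    (1629, 1069.550, "VJCJQPK", 44.049, 5.3, "n/a", None),
    (1630, 897.447, "QEKEVAAVJ", 128.105, 14.8, "incorrect", "K.KLVAAVEKEGAGFDLGAYR.D"),
    (1635, 980.533, "EJVQ", 146.109, 5.3, "incorrect", "K.MIHFVPRDNIVQK.A"),
    (1636, 358.233, "DGJMVJA", 137.071, 22.1, "correct", "R.HALVMLGDALR.H"),
    (1640, 1219.610, "TSSMG", 589.296, 7.6, "correct", "R.NYAQLGMSSTPFYQSHGVASK.S"),
    (1641, 830.437, "TJFGA", 146.113, 11.5, "correct", "K.IFTTRPDTLFGAK.F"),
    (1643, 888.524, "AGDGAK", 147.079, 10.4, "correct", "R.FKAGDGAIVNGIAFR.S"),
    (1644, 128.096, "JFDVJA", 271.174, 19.3, "correct", "K.KLFDVLAPR.Y"),
]


class TestVerifyTag:
    def test_forward_match(self):
        assert verify_tag("APAJG", "RVFNVLTGDAPAIGK") is Validity.CORRECT

    def test_reverse_match(self):
        assert verify_tag("AGDGAK", "FKAGDGAIVNGIAFR") is Validity.CORRECT

    def test_mismatch(self):
        assert verify_tag("EJVQ", "MIHFVPRDNIVQK") is Validity.INCORRECT

    def test_flanks_are_stripped(self):
        assert verify_tag("APAJG", "K.RVFNVLTGDAPAIGK.V") is Validity.CORRECT

    def test_empty_tag_rejected(self):
        with pytest.raises(ValueError):
            verify_tag("", "PEPTIDEK")

    def test_reversal_invariance(self):
        for _scan, _mp, tag, _mq, _s, _v, peptide in SAMPLE_ROWS:
            if peptide is None:
                continue
            assert verify_tag(tag, peptide) is verify_tag(tag[::-1], peptide)

    def test_sample_rows_reproduce_validity(self):
        for _scan, _mp, tag, _mq, _s, validity, peptide in SAMPLE_ROWS:
            if peptide is None:
                continue
            expected = (
                Validity.CORRECT if validity == "correct" else Validity.INCORRECT
            )
            assert verify_tag(tag, peptide) is expected


class TestClassifyError:
    def test_q_to_ga(self):
        assert (
            classify_error("QEKEVAAVJ", "KLVAAVEKEGAGFDLGAYR")
            is ErrorType.SUBSTITUTION_Q_BY_GA
        )

    def test_adjacent_inversion(self):
        assert classify_error("JQJYR", "FWTDQILYR") is ErrorType.ADJACENT_INVERSION

    def test_end_substitution(self):
        assert classify_error("EJVQ", "MIHFVPRDNIVQK") is ErrorType.END_SUBSTITUTION

    def test_n_to_gg(self):
        # peptide region reads AGGT; the tag collapsed GG into N
        assert classify_error("ANT", "WWAGGTKK") is ErrorType.SUBSTITUTION_N_BY_GG

    def test_internal_substitution(self):
        assert (
            classify_error("AWTDK", "YAYTDKPW") is ErrorType.INTERNAL_SUBSTITUTION
        )

    def test_other(self):
        assert classify_error("WWWW", "GASPKTED") is ErrorType.OTHER

    def test_correct_tag_rejected(self):
        with pytest.raises(ValueError):
            classify_error("APAJG", "RVFNVLTGDAPAIGK")


class TestRunVerification:
    def make_run(self):
        tags = {row[0]: row[2] for row in SAMPLE_ROWS}
        identifications = {
            row[0]: IdentificationRecord(scan_id=row[0], peptide=row[6])
            for row in SAMPLE_ROWS
            if row[6] is not None
        }
        return tags, identifications

    def test_sample_run_counts(self):
        tags, identifications = self.make_run()
        results = verify_run(tags, identifications)
        accuracy, average_length, sequenced = figures_of_merit(results)
        assert sequenced == 9
        with_id = [r for r in results if r.validity is not Validity.NOT_AVAILABLE]
        assert len(with_id) == 8
        assert accuracy == pytest.approx(75.0)

    def test_scan_1630_error_type(self):
        tags, identifications = self.make_run()
        results = {r.scan_id: r for r in verify_run(tags, identifications)}
        assert results[1630].error_type is ErrorType.SUBSTITUTION_Q_BY_GA

    def test_decoy_scans_excluded(self):
        tags = {1: "AGDVK"}
        identifications = {
            1: IdentificationRecord(scan_id=1, peptide="K.AGDVK.A", is_decoy=True)
        }
        results = verify_run(tags, identifications)
        assert results[0].validity is Validity.NOT_AVAILABLE

    def test_all_correct_and_empty_edge_cases(self):
        results = verify_run({1: "AGD"}, {1: IdentificationRecord(1, "K.AGDK.A")})
        accuracy, _length, count = figures_of_merit(results)
        assert accuracy == pytest.approx(100.0)
        assert count == 1
        accuracy, length, count = figures_of_merit([])
        assert accuracy is None and length is None and count == 0

    def test_error_histogram_counts_incorrect_only(self):
        tags, identifications = self.make_run()
        histogram = error_histogram(verify_run(tags, identifications))
        assert sum(histogram.values()) == 2


class TestMassCoverage:
    def test_empty_tag(self):
        assert mass_coverage("", 1000.0) == 0.0

    def test_whole_peptide(self):
        peptide = "GASPK"
        parent = DEFAULT_TABLE.peptide_neutral_mass(peptide)
        expected = 100.0 * (parent - WATER) / parent
        assert mass_coverage(peptide, parent) == pytest.approx(expected)

    def test_bins(self):
        assert coverage_bin(10.0) == 0
        assert coverage_bin(25.0) == 1
        assert coverage_bin(55.0) == 2
        assert coverage_bin(99.0) == 2


PEPTIDE_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@settings(derandomize=True, max_examples=200)
@given(
    peptide=st.text(alphabet=PEPTIDE_LETTERS, min_size=5, max_size=25),
    start=st.integers(min_value=0, max_value=20),
    length=st.integers(min_value=3, max_value=10),
    reverse=st.booleans(),
)
def test_substring_tags_always_verify(peptide, start, length, reverse):
    """Any contiguous J-mapped substring of a peptide, in either direction,
    is a correct tag; verification is invariant under tag reversal."""
    from tagnovo.chem import map_il_to_j

    mapped = map_il_to_j(peptide)
    start = min(start, len(mapped) - 3)
    tag = mapped[start : start + length]
    if len(tag) < 3:
        return
    if reverse:
        tag = tag[::-1]
    assert verify_tag(tag, peptide) is Validity.CORRECT
    assert verify_tag(tag[::-1], peptide) is Validity.CORRECT


@settings(derandomize=True, max_examples=200)
@given(
    tag=st.text(alphabet="ACDEFGHJKMNPQRSTVWY", min_size=3, max_size=8),
    peptide=st.text(alphabet=PEPTIDE_LETTERS, min_size=5, max_size=25),
)
def test_classify_error_repair_really_repairs(tag, peptide):
    """Whatever error type is assigned, applying one change of that type
    must actually produce a verifying tag (re-checked independently)."""
    from tagnovo.benchmark import _single_change_variants

    if verify_tag(tag, peptide) is Validity.CORRECT:
        return
    error_type = classify_error(tag, peptide)
    if error_type is ErrorType.OTHER:
        return
    repaired = [
        variant
        for direction in (tag, tag[::-1])
        for variant in _single_change_variants(direction, error_type)
        if verify_tag(variant, peptide) is Validity.CORRECT
    ]
    assert repaired


def test_strip_flanks():
    assert strip_flanks("K.YRPPAESAASGITVR.N") == "YRPPAESAASGITVR"
    assert strip_flanks("PEPTIDEK") == "PEPTIDEK"
    assert strip_flanks("-.MSTART.K") == "MSTART"
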