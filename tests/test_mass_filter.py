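"""Isotopic distributions, envelope matching and parent-mass filtering."""

import pytest

from tagnovo.benchmark import IdentificationRecord
from tagnovo.chem import ISOTOPE_SPACING
from tagnovo.mass_filter import (
    MassErrorAnnotation,
    MatchedPeak,
    decoy_fdr,
    match_observed,
    normalize_and_filter,
    run_median_error,
    surrounding_full_scans,
    theoretical_isotope_distribution,
    threshold_filter,
    weighted_mass_error,
)
from tagnovo.ms_io import FullScan, RawPeak


class TestTheoreticalDistribution:
    def test_glycine_mono_mz(self):
        dist = theoretical_isotope_distribution("G", 1)
        assert dist.peaks[0][0] == pytest.approx(76.0393, abs=1e-4)
        dist.validate()

    def test_intensities_sum_to_one(self):
        dist = theoretical_isotope_distribution("PEPTIDEK", 2)
        assert sum(i for _m, i in dist.peaks) == pytest.approx(1.0, abs=1e-9)

    def test_a1_ratio_monotone_in_size(self):
        small = theoretical_isotope_distribution("GK", 1)
        large = theoretical_isotope_distribution("WWWWWWWWWWK", 1)
        assert (
            large.peaks[1][1] / large.peaks[0][1]
            > small.peaks[1][1] / small.peaks[0][1]
        )

    def test_charge_scales_spacing(self):
        dist = theoretical_isotope_distribution("PEPTIDEK", 2)
        spacing = dist.peaks[1][0] - dist.peaks[0][0]
        assert spacing == pytest.approx(ISOTOPE_SPACING / 2, abs=1e-6)

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            theoretical_isotope_distribution("GXK", 1)


def scans_with_envelope(peptide, charge, shift_th, scan_ids):
    dist = theoretical_isotope_distribution(peptide, charge)
    peaks = [
        RawPeak(mz + shift_th, 1000.0 * fraction, 30000.0, 0.0, 1.0, charge)
        for mz, fraction in dist.peaks
    ]
    return [FullScan(sid, list(peaks)) for sid in scan_ids], dist


class TestMatching:
    def test_surrounding_scans_split(self):
        scans = [FullScan(i, []) for i in (1, 7, 13, 19, 25, 31, 37)]
        chosen = surrounding_full_scans(scans, 20)
        assert [s.scan_id for s in chosen] == [7, 13, 19, 25, 31, 37]

    def test_shifted_envelope_error(self):
        charge = 2
        scans, dist = scans_with_envelope("PEPTIDEK", charge, 0.005, (1, 7, 13, 19, 25, 31))
        matches = match_observed(dist, scans, ms2_scan_id=20)
        assert matches
        for m in matches:
            assert m.mass_error == pytest.approx(0.005 * charge, abs=1e-9)

    def test_absent_envelope_no_matches(self):
        dist = theoretical_isotope_distribution("PEPTIDEK", 2)
        scans = [FullScan(1, [RawPeak(1500.0, 10.0)])]
        assert match_observed(dist, scans, 2) == []

    def test_nearest_peak_wins(self):
        dist = theoretical_isotope_distribution("PEPTIDEK", 1)
        target = dist.peaks[0][0]
        scans = [
            FullScan(
                1,
                [
                    RawPeak(target + 0.04, 999.0),
                    RawPeak(target + 0.01, 10.0),
                ],
            )
        ]
        matches = match_observed(dist, scans, 2)
        by_expected = [m for m in matches if m.expected_mz == pytest.approx(target)]
        assert by_expected[0].observed_mz == pytest.approx(target + 0.01)


class TestWeightedError:
    def test_single_peak(self):
        m = MatchedPeak(1, 500.0, 500.005, 100.0, 1)
        assert weighted_mass_error([m]) == pytest.approx(0.005)

    def test_equal_intensities(self):
        ms = [
            MatchedPeak(1, 500.0, 500.002, 50.0, 1),
            MatchedPeak(1, 500.5, 500.504, 50.0, 1),
        ]
        assert weighted_mass_error(ms) == pytest.approx(0.003)

    def test_intensity_weighting(self):
        ms = [
            MatchedPeak(1, 500.0, 500.004, 300.0, 1),
            MatchedPeak(1, 500.5, 500.508, 100.0, 1),
        ]
        assert weighted_mass_error(ms) == pytest.approx(0.005)

    def test_invariant_under_intensity_scaling(self):
        ms = [
            MatchedPeak(1, 500.0, 500.004, 300.0, 1),
            MatchedPeak(1, 500.5, 500.508, 100.0, 1),
        ]
        scaled = [
            MatchedPeak(m.scan_id, m.expected_mz, m.observed_mz, m.intensity * 7.5, m.charge)
            for m in ms
        ]
        assert weighted_mass_error(scaled) == pytest.approx(weighted_mass_error(ms))


class TestNormalizeFilter:
    def test_median_removed(self):
        annotations = [
            MassErrorAnnotation(1, 0.010, None, 3),
            MassErrorAnnotation(2, 0.012, None, 3),
            MassErrorAnnotation(3, 0.014, None, 3),
        ]
        normalized, retained = normalize_and_filter(annotations, 0.02)
        assert [a.normalized_error for a in normalized] == pytest.approx(
            [-0.002, 0.0, 0.002]
        )
        assert len(retained) == 3

    def test_boundary_rejection(self):
        annotations = [
            MassErrorAnnotation(1, 0.0, None, 3),
            MassErrorAnnotation(2, 0.021, None, 3),
            MassErrorAnnotation(3, -0.021, None, 3),
        ]
        normalized, retained = normalize_and_filter(annotations, 0.02)
        assert [a.scan_id for a in retained] == [1]

    def test_unmeasured_never_retained(self):
        annotations = [MassErrorAnnotation(1, None, None, 0)]
        _normalized, retained = normalize_and_filter(annotations, 0.02)
        assert retained == []

    def test_run_median(self):
        annotations = [
            MassErrorAnnotation(1, 0.008, None, 1),
            MassErrorAnnotation(2, 0.009, None, 1),
            MassErrorAnnotation(3, None, None, 0),
        ]
        assert run_median_error(annotations) == pytest.approx(0.0085)


class TestDecoyFdr:
    def test_no_decoys(self):
        records = [IdentificationRecord(i, "K.AGDVK.A") for i in range(10)]
        assert decoy_fdr(records) == 0.0

    def test_one_decoy_in_two_thousand(self):
        records = [IdentificationRecord(i, "K.AGDVK.A") for i in range(1999)]
        records.append(IdentificationRecord(3000, "K.KVDGA.A", is_decoy=True))
        assert decoy_fdr(records) == pytest.approx(0.001)

    def test_all_decoys_capped(self):
        records = [
            IdentificationRecord(i, "K.AGDVK.A", is_decoy=True) for i in range(5)
        ]
        assert decoy_fdr(records) == 1.0


def record(scan, charge, xcorr, delcn=0.2, peptide="K.AGDVKR.A", protein="p1"):
    return IdentificationRecord(scan, peptide, charge, xcorr, delcn, protein)


class TestThresholdFilter:
    def test_charge_dependent_xcorr(self):
        kept = threshold_filter(
            [
                record(1, 2, 2.4),
                record(2, 2, 2.6),
                record(3, 2, 2.6, peptide="K.TTTPWR.A"),
            ]
        )
        assert [r.scan_id for r in kept] == [2, 3]

    def test_plus_one_accepted(self):
        kept = threshold_filter(
            [
                record(1, 1, 1.9, 0.09, "K.AGDVKK.A"),
                record(2, 1, 1.9, 0.09, "K.TTTPWR.A"),
            ]
        )
        assert len(kept) == 2

    def test_high_charge_uses_plus_three_threshold(self):
        kept = threshold_filter(
            [
                record(1, 4, 3.4),
                record(2, 4, 3.6),
                record(3, 4, 3.6, peptide="K.TTTPWR.A"),
            ]
        )
        assert [r.scan_id for r in kept] == [2, 3]

    def test_delcn_floor(self):
        kept = threshold_filter(
            [
                record(1, 2, 3.0, 0.05),
                record(2, 2, 3.0, 0.2),
                record(3, 2, 3.0, 0.2, peptide="K.TTTPWR.A"),
            ]
        )
        assert [r.scan_id for r in kept] == [2, 3]

    def test_tryptic_rule(self):
        kept = threshold_filter(
            [
                record(1, 2, 3.0, peptide="A.AGDVKT.A"),  # N-side not after K/R
                record(2, 2, 3.0, peptide="K.AGDVKT.A"),  # C-side not K/R
                record(3, 2, 3.0, peptide="K.AGDVKR.A"),
                record(4, 2, 3.0, peptide="K.AGDVTK.A"),
            ]
        )
        assert [r.scan_id for r in kept] == [3, 4]

    def test_two_peptides_per_protein(self):
        kept = threshold_filter(
            [
                record(1, 2, 3.0, peptide="K.AGDVKR.A", protein="solo"),
                record(2, 2, 3.0, peptide="K.AGDVKR.A", protein="pair"),
                record(3, 2, 3.0, peptide="K.TTTPWR.A", protein="pair"),
            ]
        )
        assert [r.scan_id for r in kept] == [2, 3]
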