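"""Accurate parent-mass annotation and filtering of peptide identifications.

For every identified MS/MS scan the theoretical isotopic distribution of
the peptide is computed from its sequence and charge, matched against the
six full (MS1) scans surrounding the MS/MS scan within ±0.05 Th windows,
and the parent mass error is taken as the intensity-weighted mean of the
matched peaks' errors on the neutral-mass scale.  Run-level systematic
calibration error is removed by shifting the median of the error
distribution to zero; identifications whose normalized error exceeds a
threshold (default 0.02 Da) are discarded.  False discovery rates are
estimated from decoy (reversed-protein) hits in a concatenated
target-decoy search as 2D/(T+D).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .benchmark import IdentificationRecord, strip_flanks
from .chem import (
    ISOTOPE_SPACING,
    PROTON,
    isotope_envelope,
    monoisotopic_mass,
    peptide_composition,
)
from .ms_io import FullScan


@dataclass(frozen=True)
class IsotopeDistribution:
    """Theoretical envelope of a charged peptide: (m/z, fractional
    intensity) pairs ascending in m/z, intensities summing to one."""

    peaks: Tuple[Tuple[float, float], ...]
    charge: int

    def validate(self) -> None:
        total = sum(intensity for _mz, intensity in self.peaks)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("intensities must sum to 1")
        spacing = ISOTOPE_SPACING / self.charge
        for (a, _), (b, _) in zip(self.peaks, self.peaks[1:]):
            if not (0 < b - a < spacing * 1.5):
                raise ValueError("peaks must ascend with isotopic spacing")


@dataclass
class MassErrorAnnotation:
    scan_id: int
    raw_error: Optional[float]  # Da, neutral-mass scale; None when unmatched
    normalized_error: Optional[float] = None
    n_matched_peaks: int = 0


@dataclass(frozen=True)
class FilterCriteria:
    """Database-search acceptance rules applied before mass filtering."""

    xcorr_min: Mapping[int, float] = None  # type: ignore[assignment]
    delcn_min: float = 0.08
    require_tryptic: bool = True
    min_peptides_per_protein: int = 2

    def __post_init__(self) -> None:
        if self.xcorr_min is None:
            object.__setattr__(self, "xcorr_min", {1: 1.8, 2: 2.5, 3: 3.5})

    def xcorr_threshold(self, charge: int) -> float:
        return self.xcorr_min[min(max(charge, 1), max(self.xcorr_min))]


def theoretical_isotope_distribution(
    peptide: str, charge: int, min_relative_intensity: float = 0.01
) -> IsotopeDistribution:
    """Isotopic envelope of a peptide at a charge state.

    The elemental composition is summed from residue formulas plus water
    and convolved over elemental isotope abundances; peaks below
    ``min_relative_intensity`` of the base peak are truncated and the rest
    renormalized to sum to one.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    composition = peptide_composition(strip_flanks(peptide))
    envelope = isotope_envelope(composition)
    mono = monoisotopic_mass(composition)
    base = envelope.max()
    peaks: List[Tuple[float, float]] = []
    for k, abundance in enumerate(envelope):
        if abundance < min_relative_intensity * base:
            continue
        mz = (mono + k * ISOTOPE_SPACING + charge * PROTON) / charge
        peaks.append((mz, float(abundance)))
    total = sum(i for _m, i in peaks)
    peaks = [(m, i / total) for m, i in peaks]
    return IsotopeDistribution(peaks=tuple(peaks), charge=charge)


def surrounding_full_scans(
    full_scans: Sequence[FullScan], ms2_scan_id: int, each_side: int = 3
) -> List[FullScan]:
    """The 6 full scans bracketing an MS/MS scan: 3 before and 3 after in
    scan-number order (fewer at run boundaries)."""
    ordered = sorted(full_scans, key=lambda s: s.scan_id)
    before = [s for s in ordered if s.scan_id < ms2_scan_id][-each_side:]
    after = [s for s in ordered if s.scan_id > ms2_scan_id][:each_side]
    return before + after


@dataclass(frozen=True)
class MatchedPeak:
    scan_id: int
    expected_mz: float
    observed_mz: float
    intensity: float
    charge: int

    @property
    def mass_error(self) -> float:
        """Error on the neutral-mass scale, Da."""
        return (self.observed_mz - self.expected_mz) * self.charge


def match_observed(
    distribution: IsotopeDistribution,
    full_scans: Sequence[FullScan],
    ms2_scan_id: int,
    mz_window: float = 0.05,
) -> List[MatchedPeak]:
    """Find observed isotopic peaks near each expected peak in the
    surrounding full scans; the nearest peak within the ±``mz_window`` Th
    window wins."""
    matches: List[MatchedPeak] = []
    for scan in surrounding_full_scans(full_scans, ms2_scan_id):
        for expected_mz, _intensity in distribution.peaks:
            best: Optional[MatchedPeak] = None
            best_distance = mz_window
            for peak in scan.peaks:
                distance = abs(peak.mz - expected_mz)
                if distance <= best_distance:
                    candidate = MatchedPeak(
                        scan.scan_id,
                        expected_mz,
                        peak.mz,
                        peak.intensity,
                        distribution.charge,
                    )
                    if best is None or distance < best_distance:
                        best, best_distance = candidate, distance
            if best is not None:
                matches.append(best)
    return matches


def weighted_mass_error(matches: Sequence[MatchedPeak]) -> float:
    """Intensity-weighted mean of matched peaks' mass errors (Da)."""
    if not matches:
        raise ValueError("no matched peaks")
    total_intensity = sum(m.intensity for m in matches)
    return sum(m.mass_error * m.intensity for m in matches) / total_intensity


def annotate_run(
    identifications: Iterable[IdentificationRecord],
    full_scans: Sequence[FullScan],
) -> List[MassErrorAnnotation]:
    """Raw parent-mass error annotation for every identification."""
    annotations: List[MassErrorAnnotation] = []
    for record in identifications:
        distribution = theoretical_isotope_distribution(record.core, record.charge)
        matches = match_observed(distribution, full_scans, record.scan_id)
        if matches:
            annotations.append(
                MassErrorAnnotation(
                    record.scan_id, weighted_mass_error(matches), None, len(matches)
                )
            )
        else:
            annotations.append(MassErrorAnnotation(record.scan_id, None, None, 0))
    return annotations


def normalize_and_filter(
    annotations: Sequence[MassErrorAnnotation],
    threshold: float = 0.02,
) -> Tuple[List[MassErrorAnnotation], List[MassErrorAnnotation]]:
    """Median-center the raw errors of a run and apply the threshold.

    Returns (all annotations with normalized errors filled in, the retained
    subset with |normalized error| < threshold).  Annotations without a
    measured error are never retained.
    """
    measured = [a.raw_error for a in annotations if a.raw_error is not None]
    median = statistics.median(measured) if measured else 0.0
    normalized: List[MassErrorAnnotation] = []
    retained: List[MassErrorAnnotation] = []
    for a in annotations:
        if a.raw_error is None:
            normalized.append(MassErrorAnnotation(a.scan_id, None, None, 0))
            continue
        n = MassErrorAnnotation(
            a.scan_id, a.raw_error, a.raw_error - median, a.n_matched_peaks
        )
        normalized.append(n)
        if abs(n.normalized_error) < threshold:
            retained.append(n)
    return normalized, retained


def run_median_error(annotations: Sequence[MassErrorAnnotation]) -> float:
    measured = [a.raw_error for a in annotations if a.raw_error is not None]
    if not measured:
        raise ValueError("no measured errors")
    return statistics.median(measured)


def decoy_fdr(identifications: Sequence[IdentificationRecord]) -> float:
    """Concatenated target-decoy FDR estimate 2D/(T+D), capped at 1."""
    if not identifications:
        raise ValueError("no identifications")
    decoys = sum(1 for r in identifications if r.is_decoy)
    total = len(identifications)
    return min(2.0 * decoys / total, 1.0)


def _is_fully_tryptic(record: IdentificationRecord) -> bool:
    peptide = record.peptide
    if "." in peptide:
        first = peptide.index(".")
        last = peptide.rindex(".")
        left = peptide[:first][-1:] or "-"
        right = peptide[last + 1 :][:1] or "-"
        core = peptide[first + 1 : last]
    else:
        left, right, core = "-", "-", peptide
    n_side = left in ("K", "R", "-")
    c_side = core[-1:] in ("K", "R") or right == "-"
    return n_side and c_side


def threshold_filter(
    identifications: Sequence[IdentificationRecord],
    criteria: Optional[FilterCriteria] = None,
) -> List[IdentificationRecord]:
    """Charge-dependent Xcorr and delCN thresholds, fully-tryptic rule and
    the two-peptides-per-protein rule."""
    criteria = criteria or FilterCriteria()
    passing: List[IdentificationRecord] = []
    for record in identifications:
        if record.xcorr < criteria.xcorr_threshold(record.charge):
            continue
        if record.delcn < criteria.delcn_min:
            continue
        if criteria.require_tryptic and not _is_fully_tryptic(record):
            continue
        passing.append(record)
    if criteria.min_peptides_per_protein > 1:
        by_protein: Dict[str, set] = {}
        for record in passing:
            by_protein.setdefault(record.protein, set()).add(record.core)
        passing = [
            r
            for r in passing
            if len(by_protein[r.protein]) >= criteria.min_peptides_per_protein
        ]
    return passing
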