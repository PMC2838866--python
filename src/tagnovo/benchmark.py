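"""Verification of de novo tags against database-search identifications.

A tag is correct when it, in either reading direction, occurs verbatim in
the identified peptide after the isobaric leucine/isoleucine residues are
collapsed onto J.  Incorrect tags are further classified by whether a
single edit of a known error type repairs them: the compositional
ambiguities Q <-> GA and N <-> GG, inversion of two adjacent residues, and
substitution of an end or internal residue.  The figures of merit are the
accuracy over spectra holding both a tag and an identification, the average
tag length, and the number of sequenced spectra.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import IO, Dict, Iterable, List, Optional, Sequence, Tuple

from .chem import ALPHABET, AminoAcidTable, DEFAULT_TABLE, map_il_to_j


class Validity(enum.Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    NOT_AVAILABLE = "not_available"


class ErrorType(enum.Enum):
    SUBSTITUTION_Q_BY_GA = "substitution_Q_by_GA"
    SUBSTITUTION_N_BY_GG = "substitution_N_by_GG"
    ADJACENT_INVERSION = "adjacent_inversion"
    END_SUBSTITUTION = "end_substitution"
    INTERNAL_SUBSTITUTION = "internal_substitution"
    OTHER = "other"


@dataclass(frozen=True)
class IdentificationRecord:
    """One scan-level peptide identification from a database search."""

    scan_id: int
    peptide: str  # may carry flanking residues, e.g. "K.YRPPAESAASGITVR.N"
    charge: int = 0
    xcorr: float = 0.0
    delcn: float = 0.0
    protein: str = ""
    is_decoy: bool = False

    @property
    def core(self) -> str:
        return strip_flanks(self.peptide)


@dataclass(frozen=True)
class VerificationResult:
    scan_id: int
    validity: Validity
    matched_offset: Optional[int] = None
    tag_length: int = 0
    error_type: Optional[ErrorType] = None


def strip_flanks(peptide: str) -> str:
    """Remove flanking-residue annotation ``X.CORE.Y`` when present."""
    if "." in peptide:
        first = peptide.index(".")
        last = peptide.rindex(".")
        if first != last:
            return peptide[first + 1 : last]
    return peptide


def verify_tag(tag_residues: str, peptide: str) -> Validity:
    """Exact-substring verification of a tag against a peptide, in either
    direction, with I/L mapped to J."""
    if not tag_residues:
        raise ValueError("empty tag")
    target = map_il_to_j(strip_flanks(peptide))
    if tag_residues in target or tag_residues[::-1] in target:
        return Validity.CORRECT
    return Validity.INCORRECT


def match_offset(tag_residues: str, peptide: str) -> Optional[int]:
    target = map_il_to_j(strip_flanks(peptide))
    for candidate in (tag_residues, tag_residues[::-1]):
        pos = target.find(candidate)
        if pos >= 0:
            return pos
    return None


def _single_change_variants(tag: str, error_type: ErrorType) -> Iterable[str]:
    if error_type is ErrorType.SUBSTITUTION_Q_BY_GA:
        for i, r in enumerate(tag):
            if r == "Q":
                yield tag[:i] + "GA" + tag[i + 1 :]
                yield tag[:i] + "AG" + tag[i + 1 :]
    elif error_type is ErrorType.SUBSTITUTION_N_BY_GG:
        for i, r in enumerate(tag):
            if r == "N":
                yield tag[:i] + "GG" + tag[i + 1 :]
    elif error_type is ErrorType.ADJACENT_INVERSION:
        for i in range(len(tag) - 1):
            yield tag[:i] + tag[i + 1] + tag[i] + tag[i + 2 :]
    elif error_type is ErrorType.END_SUBSTITUTION:
        for i in (0, len(tag) - 1):
            for r in ALPHABET:
                if r != tag[i]:
                    yield tag[:i] + r + tag[i + 1 :]
    elif error_type is ErrorType.INTERNAL_SUBSTITUTION:
        for i in range(1, len(tag) - 1):
            for r in ALPHABET:
                if r != tag[i]:
                    yield tag[:i] + r + tag[i + 1 :]


#: Precedence order of single-change repairs.
ERROR_PRECEDENCE = (
    ErrorType.SUBSTITUTION_Q_BY_GA,
    ErrorType.SUBSTITUTION_N_BY_GG,
    ErrorType.ADJACENT_INVERSION,
    ErrorType.END_SUBSTITUTION,
    ErrorType.INTERNAL_SUBSTITUTION,
)


def classify_error(tag_residues: str, peptide: str) -> ErrorType:
    """Assign an incorrect tag to the first error type whose single change
    (applied to the tag in either direction) repairs it."""
    if verify_tag(tag_residues, peptide) is Validity.CORRECT:
        raise ValueError("tag is correct; nothing to classify")
    for error_type in ERROR_PRECEDENCE:
        for direction in (tag_residues, tag_residues[::-1]):
            for variant in _single_change_variants(direction, error_type):
                if verify_tag(variant, peptide) is Validity.CORRECT:
                    return error_type
    return ErrorType.OTHER


def verify_run(
    tags: Dict[int, str],
    identifications: Dict[int, IdentificationRecord],
    exclude_decoys: bool = True,
) -> List[VerificationResult]:
    """Verify every tagged scan; scans without an identification (or whose
    identification is a decoy hit) are reported as not_available."""
    results: List[VerificationResult] = []
    for scan_id in sorted(tags):
        tag = tags[scan_id]
        record = identifications.get(scan_id)
        if record is None or (exclude_decoys and record.is_decoy):
            results.append(
                VerificationResult(scan_id, Validity.NOT_AVAILABLE, None, len(tag))
            )
            continue
        validity = verify_tag(tag, record.peptide)
        error_type = (
            classify_error(tag, record.peptide)
            if validity is Validity.INCORRECT
            else None
        )
        results.append(
            VerificationResult(
                scan_id,
                validity,
                match_offset(tag, record.peptide),
                len(tag),
                error_type,
            )
        )
    return results


def figures_of_merit(
    results: Sequence[VerificationResult],
) -> Tuple[Optional[float], Optional[float], int]:
    """(accuracy %, average tag length, sequenced spectrum count).

    Accuracy is the percentage of correct tags among scans holding both a
    tag and an identification; undefined (None) when that intersection is
    empty.  Average length runs over all tagged scans.
    """
    correct = sum(1 for r in results if r.validity is Validity.CORRECT)
    incorrect = sum(1 for r in results if r.validity is Validity.INCORRECT)
    sequenced = len(results)
    accuracy = (
        100.0 * correct / (correct + incorrect) if (correct + incorrect) else None
    )
    average_length = (
        sum(r.tag_length for r in results) / sequenced if sequenced else None
    )
    return accuracy, average_length, sequenced


def mass_coverage(
    tag_residues: str,
    parent_mass: float,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> float:
    """Percentage of the parent peptide mass explained by the tag residues."""
    if parent_mass <= 0:
        raise ValueError("parent mass must be positive")
    return 100.0 * table.peptide_residue_sum(tag_residues) / parent_mass


COVERAGE_BINS = ((0.0, 20.0), (20.0, 40.0), (40.0, 100.0))


def coverage_bin(coverage_percent: float) -> int:
    """Index of the reporting stratum (0-20 / 20-40 / 40-100%)."""
    for idx, (low, high) in enumerate(COVERAGE_BINS):
        if low <= coverage_percent < high or (idx == 2 and coverage_percent >= low):
            return idx
    return 0


def error_histogram(
    results: Sequence[VerificationResult],
) -> Dict[ErrorType, int]:
    histogram = {error_type: 0 for error_type in ErrorType}
    for r in results:
        if r.validity is Validity.INCORRECT and r.error_type is not None:
            histogram[r.error_type] += 1
    return histogram


def read_identification_table(stream: IO[str]) -> Dict[int, IdentificationRecord]:
    """Tab-separated identification input: scan, charge, peptide, Xcorr,
    delCN, protein, decoy flag (0/1).  A header line is detected and
    skipped."""
    records: Dict[int, IdentificationRecord] = {}
    for line_number, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t")
        if line_number == 1 and not fields[0].isdigit():
            continue
        if len(fields) < 3:
            raise ValueError(f"line {line_number}: expected >= 3 columns")
        records[int(fields[0])] = IdentificationRecord(
            scan_id=int(fields[0]),
            charge=int(fields[1]),
            peptide=fields[2],
            xcorr=float(fields[3]) if len(fields) > 3 else 0.0,
            delcn=float(fields[4]) if len(fields) > 4 else 0.0,
            protein=fields[5] if len(fields) > 5 else "",
            is_decoy=bool(int(fields[6])) if len(fields) > 6 else False,
        )
    return records


def write_identification_table(
    records: Iterable[IdentificationRecord], stream: IO[str]
) -> None:
    stream.write("scan\tcharge\tpeptide\txcorr\tdelcn\tprotein\tdecoy\n")
    for r in sorted(records, key=lambda r: r.scan_id):
        stream.write(
            f"{r.scan_id}\t{r.charge}\t{r.peptide}\t{r.xcorr:.4f}"
            f"\t{r.delcn:.4f}\t{r.protein}\t{int(r.is_decoy)}\n"
        )


def write_report(
    results: Sequence[VerificationResult],
    tags: Dict[int, Tuple[float, str, float, float]],
    identifications: Dict[int, IdentificationRecord],
    stream: IO[str],
) -> None:
    """Verification report: one row per tagged scan plus a summary block.

    ``tags`` maps scan -> (mp, residues, mq, score).
    """
    stream.write("scan\tresidual_mass_1\ttag\tresidual_mass_2\tscore\tvalidity\tidentification\n")
    for r in results:
        mp, residues, mq, score = tags[r.scan_id]
        record = identifications.get(r.scan_id)
        peptide = record.peptide if record is not None else "N/A"
        stream.write(
            f"{r.scan_id}\t{mp:.3f}\t{residues}\t{mq:.3f}\t{score:.1f}"
            f"\t{r.validity.value}\t{peptide}\n"
        )
    accuracy, average_length, sequenced = figures_of_merit(results)
    histogram = error_histogram(results)
    incorrect_total = sum(histogram.values())
    stream.write(f"# sequenced_spectra\t{sequenced}\n")
    stream.write(
        f"# accuracy_percent\t{accuracy:.1f}\n"
        if accuracy is not None
        else "# accuracy_percent\tNA\n"
    )
    stream.write(
        f"# average_tag_length\t{average_length:.2f}\n"
        if average_length is not None
        else "# average_tag_length\tNA\n"
    )
    for error_type in ErrorType:
        count = histogram[error_type]
        percent = 100.0 * count / incorrect_total if incorrect_total else 0.0
        stream.write(f"# error\t{error_type.value}\t{count}\t{percent:.1f}%\n")
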