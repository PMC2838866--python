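"""End-to-end workflows: sequencing runs, benchmarking, mass filtering.

These functions tie the per-spectrum machinery (deisotoping, spectrum and
sequence graph construction, path enumeration, scoring, consensus) into
file-level runs with deterministic, tab-separated outputs.  The
command-line interface in :mod:`tagnovo.cli` is a thin wrapper over this
module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, IO, List, Optional, Sequence, Tuple, Union

from . import benchmark as bm
from . import mass_filter as mf
from .chem import AminoAcidTable, DEFAULT_TABLE
from .config import RunConfig
from .ms_io import (
    DeisotopeConfig,
    ScanHeader,
    SpectrumRejected,
    TandemSpectrum,
    deisotope,
    prepare_spectrum,
    read_ft1,
    read_ft2,
)
from .scoring import (
    ConsensusTag,
    SequenceTag,
    consensus_tag,
    is_sequenced,
    rank_tags,
)
from .sequence_graph import build_sequence_graph, connected_components
from .spectrum_graph import build_spectrum_graph
from .tag_search import PathExplosion, enumerate_all_paths

logger = logging.getLogger(__name__)


@dataclass
class SpectrumResult:
    scan_id: int
    tags: List[SequenceTag]
    consensus: Optional[ConsensusTag]
    sequenced: bool
    failure: Optional[str] = None

    @property
    def top_tag(self) -> Optional[SequenceTag]:
        return self.tags[0] if self.tags else None


def sequence_spectrum(
    spectrum: TandemSpectrum,
    config: Optional[RunConfig] = None,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> SpectrumResult:
    """Run the four sequencing steps on one preprocessed spectrum.

    Paths are enumerated independently per traversable component and the
    resulting tags ranked together; the consensus tag is derived from the
    top two tags when both exist.
    """
    config = config or RunConfig()
    if config.residue_overrides:
        table = table.with_overrides(config.residue_overrides)
    spectrum_graph = build_spectrum_graph(spectrum, config.delta, table)
    sequence_graph = build_sequence_graph(spectrum_graph)
    tags: List[SequenceTag] = []
    try:
        for component in connected_components(sequence_graph):
            paths = enumerate_all_paths(component, max_paths=config.max_paths)
            tags.extend(
                rank_tags(
                    paths,
                    component,
                    config,
                    parent_mass=spectrum.parent_neutral_mass,
                    scan_id=spectrum.scan_id,
                )
            )
    except PathExplosion as exc:
        logger.warning("scan %d: %s; spectrum flagged unsequenced", spectrum.scan_id, exc)
        return SpectrumResult(spectrum.scan_id, [], None, False, failure=str(exc))
    tags.sort(key=lambda t: (-t.score, -len(t.residues), t.residues))
    sequenced = is_sequenced(tags, config)
    consensus = None
    if sequenced and len(tags) >= 2:
        consensus = consensus_tag(tags[0], tags[1], config.min_tag_length)
    return SpectrumResult(spectrum.scan_id, tags, consensus, sequenced)


def consensus_row(
    result: SpectrumResult, table: AminoAcidTable = DEFAULT_TABLE
) -> Optional[Tuple[int, float, str, float, float]]:
    """(scan, mp, tag, mq, score) for the consensus tag, with residual
    masses re-anchored to the consensus span inside the top tag."""
    if result.consensus is None or result.top_tag is None:
        return None
    top = result.top_tag
    span = result.consensus.residues
    for candidate in (span, span[::-1]):
        offset = top.residues.find(candidate)
        if offset >= 0:
            prefix = top.residues[:offset]
            mp = top.mp + table.peptide_residue_sum(prefix)
            mq = (
                top.mp
                + top.mq
                + table.peptide_residue_sum(top.residues)
                - mp
                - table.peptide_residue_sum(candidate)
            )
            return (result.scan_id, mp, span, mq, top.score)
    return None


def process_ft2_records(
    records: Sequence[Tuple[ScanHeader, Sequence]],
    config: Optional[RunConfig] = None,
    deisotope_config: Optional[DeisotopeConfig] = None,
) -> List[SpectrumResult]:
    """Deisotope, prepare and sequence every scan of a parsed FT2 file."""
    config = config or RunConfig()
    results: List[SpectrumResult] = []
    for header, peaks in records:
        try:
            ions = deisotope(peaks, max(header.charge, 1), deisotope_config)
            spectrum = prepare_spectrum(header, ions, config.delta)
        except SpectrumRejected as exc:
            logger.warning("%s", exc)
            results.append(
                SpectrumResult(header.scan_id, [], None, False, failure=str(exc))
            )
            continue
        results.append(sequence_spectrum(spectrum, config))
    return results


def write_run_output(
    results: Sequence[SpectrumResult],
    stream: IO[str],
    config: Optional[RunConfig] = None,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> int:
    """Write the per-spectrum tag table; returns the sequenced count."""
    config = config or RunConfig()
    stream.write("scan\tresidual_mass_1\ttag\tresidual_mass_2\tscore\n")
    written = 0
    for result in results:
        if not result.sequenced:
            continue
        if config.tag_mode == "consensus":
            row = consensus_row(result, table)
            if row is None:
                continue
            scan, mp, tag, mq, score = row
        else:
            top = result.top_tag
            assert top is not None
            scan, mp, tag, mq, score = result.scan_id, top.mp, top.residues, top.mq, top.score
        stream.write(f"{scan}\t{mp:.3f}\t{tag}\t{mq:.3f}\t{score:.1f}\n")
        written += 1
    return written


def run_sequencing(
    ft2_path: Union[str, Path],
    config: Optional[RunConfig] = None,
    out_stream: Optional[IO[str]] = None,
) -> List[SpectrumResult]:
    config = config or RunConfig()
    with open(ft2_path) as handle:
        records = read_ft2(handle)
    results = process_ft2_records(records, config)
    sequenced = sum(1 for r in results if r.sequenced)
    logger.info(
        "%d spectra processed, %d sequenced", len(results), sequenced
    )
    if out_stream is not None:
        write_run_output(results, out_stream, config)
    return results


def read_tag_table(stream: IO[str]) -> Dict[int, Tuple[float, str, float, float]]:
    """Parse the tag table written by :func:`write_run_output`."""
    tags: Dict[int, Tuple[float, str, float, float]] = {}
    for line_number, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if line_number == 1 and not fields[0].isdigit():
            continue
        if len(fields) < 5:
            raise ValueError(f"line {line_number}: expected 5 columns")
        tags[int(fields[0])] = (
            float(fields[1]),
            fields[2],
            float(fields[3]),
            float(fields[4]),
        )
    return tags


def run_benchmark(
    tag_table: Union[str, Path, Dict[int, Tuple[float, str, float, float]]],
    identification_table: Union[str, Path, Dict[int, bm.IdentificationRecord]],
    out_stream: Optional[IO[str]] = None,
) -> List[bm.VerificationResult]:
    """Verify a tag table against an identification table and report."""
    if isinstance(tag_table, (str, Path)):
        with open(tag_table) as handle:
            tags = read_tag_table(handle)
    else:
        tags = tag_table
    if isinstance(identification_table, (str, Path)):
        with open(identification_table) as handle:
            identifications = bm.read_identification_table(handle)
    else:
        identifications = identification_table
    results = bm.verify_run({s: t[1] for s, t in tags.items()}, identifications)
    if out_stream is not None:
        bm.write_report(results, tags, identifications, out_stream)
    return results


def run_mass_filter(
    ft1_path: Union[str, Path],
    identification_table: Union[str, Path, Sequence[bm.IdentificationRecord]],
    threshold: float = 0.02,
    out_stream: Optional[IO[str]] = None,
) -> Tuple[List[mf.MassErrorAnnotation], List[mf.MassErrorAnnotation]]:
    """Annotate parent-mass errors from full scans, normalize, filter, and
    report decoy FDR before and after filtering."""
    with open(ft1_path) as handle:
        full_scans = read_ft1(handle)
    if isinstance(identification_table, (str, Path)):
        with open(identification_table) as handle:
            records = list(bm.read_identification_table(handle).values())
    else:
        records = list(identification_table)
    annotations = mf.annotate_run(records, full_scans)
    normalized, retained = mf.normalize_and_filter(annotations, threshold)
    if out_stream is not None:
        by_scan = {r.scan_id: r for r in records}
        retained_ids = {a.scan_id for a in retained}
        out_stream.write(
            "scan\tcharge\tpeptide\traw_error\tnormalized_error\tn_matched\tretained\n"
        )
        for a in normalized:
            record = by_scan[a.scan_id]
            raw = f"{a.raw_error:.5f}" if a.raw_error is not None else "NA"
            norm = (
                f"{a.normalized_error:.5f}" if a.normalized_error is not None else "NA"
            )
            out_stream.write(
                f"{a.scan_id}\t{record.charge}\t{record.peptide}\t{raw}\t{norm}"
                f"\t{a.n_matched_peaks}\t{int(a.scan_id in retained_ids)}\n"
            )
        fdr_before = mf.decoy_fdr(records) if records else float("nan")
        kept_records = [by_scan[a.scan_id] for a in retained]
        fdr_after = mf.decoy_fdr(kept_records) if kept_records else 0.0
        out_stream.write(f"# fdr_before\t{100*fdr_before:.2f}%\n")
        out_stream.write(f"# fdr_after\t{100*fdr_after:.2f}%\n")
        out_stream.write(f"# retained\t{len(retained)}\tof\t{len(records)}\n")
    return normalized, retained
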