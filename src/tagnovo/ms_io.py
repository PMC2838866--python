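"""Reading, writing and preprocessing of high-resolution MS1/MS2 text data.

The FT1/FT2 dialect handled here is a seven-column extension of the MS1/MS2
formats: ``H`` lines carry free-form header metadata (preserved verbatim),
``S`` lines open a scan (scan number twice, plus the precursor m/z for MS/MS
scans), ``Z`` lines give the precursor charge and its singly-protonated
mass, and peak lines hold m/z, intensity, resolution, baseline, noise and
charge.  A trailing seventh column, present in some exporters, is accepted
and ignored.

Preprocessing converts raw peak lists into deisotoped, charge-assigned
neutral monoisotopic fragment masses — the representation the spectrum
graph is built from.  Deisotoping is greedy, highest-intensity peak first,
testing candidate charges against the expected isotope spacing and an
averagine-predicted envelope shape.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from typing import IO, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .chem import ISOTOPE_SPACING, PROTON, averagine_envelope

logger = logging.getLogger(__name__)
if not logger.handlers:  # scan-level warnings go to stderr by default
    logging.basicConfig(stream=sys.stderr)


class FtParseError(ValueError):
    """Malformed FT1/FT2 content; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class SpectrumRejected(ValueError):
    """Raised for scans that cannot enter sequencing (e.g. charge 0)."""


@dataclass(frozen=True)
class RawPeak:
    """One centroided peak as written by the instrument exporter."""

    mz: float
    intensity: float
    resolution: float = 0.0
    baseline: float = 0.0
    noise: float = 0.0
    charge: int = 0  # 0 = undetermined

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class FragmentIon:
    """A deisotoped product ion: neutral monoisotopic mass and relative
    abundance (percent of the base peak)."""

    neutral_mass: float
    relative_abundance: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.neutral_mass < 0:
            raise ValueError("neutral mass must be non-negative")
        if not (0 < self.relative_abundance <= 100):
            raise ValueError("relative abundance must be in (0, 100]")


@dataclass(frozen=True)
class ScanHeader:
    """Header block of one MS/MS scan in an FT2 file."""

    scan_id: int
    precursor_mz: float
    charge: int
    protonated_mass: float  # singly-protonated parent mass from the Z line

    @property
    def parent_neutral_mass(self) -> float:
        return self.protonated_mass - PROTON


@dataclass
class TandemSpectrum:
    """A preprocessed MS/MS scan ready for graph construction.

    ``ions`` are strictly ascending in neutral mass and begin with the
    zero-mass anchor at 100% relative abundance; the anchor stands for the
    empty fragment so that terminal residues can form edges like any other.
    """

    scan_id: int
    parent_neutral_mass: float
    parent_charge: int
    ions: List[FragmentIon]

    def validate(self) -> None:
        if not self.ions:
            raise ValueError("spectrum has no ions")
        anchor = self.ions[0]
        if anchor.neutral_mass != 0.0 or anchor.relative_abundance != 100.0:
            raise ValueError("first ion must be the (0 Da, 100%) anchor")
        masses = [ion.neutral_mass for ion in self.ions]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("ion masses must be strictly ascending")

    @property
    def masses(self) -> np.ndarray:
        return np.array([ion.neutral_mass for ion in self.ions])


@dataclass
class FullScan:
    """One MS1 scan: raw peaks ascending in m/z."""

    scan_id: int
    peaks: List[RawPeak]


@dataclass
class DeisotopeConfig:
    """Knobs for the greedy envelope search.

    ``min_isotope_peaks`` applies to charge >= 2; singly-charged ions are
    accepted as bare monoisotopic peaks unless ``require_partner`` is set.
    ``mz_tolerance`` is the match window for isotope partners (Th) and
    ``ratio_tolerance`` the allowed multiplicative deviation from the
    averagine-predicted envelope shape.
    """

    mz_tolerance: float = 0.01
    ratio_tolerance: float = 3.0
    min_isotope_peaks: int = 2
    require_partner: bool = False
    merge_tolerance: float = 0.005


# ---------------------------------------------------------------------------
# FT1/FT2 parsing


def _parse_peak(fields: Sequence[str], line_number: int) -> RawPeak:
    if len(fields) not in (6, 7):
        raise FtParseError(
            line_number, f"expected 6 or 7 peak columns, got {len(fields)}"
        )
    try:
        return RawPeak(
            mz=float(fields[0]),
            intensity=float(fields[1]),
            resolution=float(fields[2]),
            baseline=float(fields[3]),
            noise=float(fields[4]),
            charge=int(float(fields[5])),
        )
    except ValueError as exc:
        raise FtParseError(line_number, f"bad peak line: {exc}") from exc


def read_ft2(stream: IO[str]) -> List[Tuple[ScanHeader, List[RawPeak]]]:
    """Parse an FT2 stream into (header, raw peak list) records in file order."""
    records: List[Tuple[ScanHeader, List[RawPeak]]] = []
    scan_id: Optional[int] = None
    precursor_mz = 0.0
    charge = 0
    protonated = 0.0
    peaks: List[RawPeak] = []

    def flush() -> None:
        nonlocal scan_id
        if scan_id is not None:
            header = ScanHeader(scan_id, precursor_mz, charge, protonated)
            records.append((header, peaks.copy()))
        scan_id = None
        peaks.clear()

    for line_number, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("H"):
            continue
        fields = line.split()
        if fields[0] == "S":
            flush()
            if len(fields) < 4:
                raise FtParseError(line_number, "S line needs scan, scan, precursor m/z")
            try:
                scan_id = int(fields[1])
                precursor_mz = float(fields[3])
            except ValueError as exc:
                raise FtParseError(line_number, f"bad S line: {exc}") from exc
            charge = 0
            protonated = 0.0
        elif fields[0] == "Z":
            if scan_id is None:
                raise FtParseError(line_number, "Z line outside a scan")
            if len(fields) < 3:
                raise FtParseError(line_number, "Z line needs charge and M+H mass")
            try:
                charge = int(fields[1])
                protonated = float(fields[2])
            except ValueError as exc:
                raise FtParseError(line_number, f"bad Z line: {exc}") from exc
        else:
            if scan_id is None:
                raise FtParseError(line_number, "peak line outside a scan")
            peaks.append(_parse_peak(fields, line_number))
    flush()
    return records


def write_ft2(records: Iterable[Tuple[ScanHeader, Sequence[RawPeak]]], stream: IO[str]) -> None:
    """Write records in the canonical FT2 layout (read/write round-trips)."""
    for header, peaks in records:
        stream.write(
            f"S\t{header.scan_id}\t{header.scan_id}\t{header.precursor_mz:.5f}\n"
        )
        stream.write(f"Z\t{header.charge}\t{header.protonated_mass:.5f}\n")
        for p in peaks:
            stream.write(
                f"{p.mz:.5f}\t{p.intensity:.2f}\t{p.resolution:.1f}"
                f"\t{p.baseline:.2f}\t{p.noise:.2f}\t{p.charge}\n"
            )


def read_ft1(stream: IO[str]) -> List[FullScan]:
    """Parse an FT1 stream into FullScan records in file order."""
    scans: List[FullScan] = []
    scan_id: Optional[int] = None
    peaks: List[RawPeak] = []

    def flush() -> None:
        nonlocal scan_id
        if scan_id is not None:
            scans.append(FullScan(scan_id, peaks.copy()))
        scan_id = None
        peaks.clear()

    for line_number, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("H"):
            continue
        fields = line.split()
        if fields[0] == "S":
            flush()
            if len(fields) < 2:
                raise FtParseError(line_number, "S line needs a scan number")
            try:
                scan_id = int(fields[1])
            except ValueError as exc:
                raise FtParseError(line_number, f"bad S line: {exc}") from exc
        elif fields[0] == "Z":
            continue
        else:
            if scan_id is None:
                raise FtParseError(line_number, "peak line outside a scan")
            peaks.append(_parse_peak(fields, line_number))
    flush()
    return scans


def write_ft1(scans: Iterable[FullScan], stream: IO[str]) -> None:
    for scan in scans:
        stream.write(f"S\t{scan.scan_id}\t{scan.scan_id}\n")
        for p in scan.peaks:
            stream.write(
                f"{p.mz:.5f}\t{p.intensity:.2f}\t{p.resolution:.1f}"
                f"\t{p.baseline:.2f}\t{p.noise:.2f}\t{p.charge}\n"
            )


def write_dta(spectrum: TandemSpectrum, stream: IO[str]) -> None:
    """Export one spectrum in DTA layout with five-decimal m/z values.

    The first line holds the singly-protonated parent mass and the measured
    charge; subsequent lines hold singly-protonated fragment m/z and
    intensity.
    """
    mh = spectrum.parent_neutral_mass + PROTON
    stream.write(f"{mh:.5f} {spectrum.parent_charge}\n")
    for ion in spectrum.ions:
        if ion.neutral_mass == 0.0:
            continue  # the anchor is an internal construct, not a peak
        mz = ion.neutral_mass + PROTON
        stream.write(f"{mz:.5f} {ion.relative_abundance:.2f}\n")


# ---------------------------------------------------------------------------
# Deisotoping


def _predicted_ratios(neutral_mass: float, n: int) -> np.ndarray:
    env = averagine_envelope(neutral_mass, max_peaks=max(n, 2))
    return env / env[0]


def deisotope(
    raw_peaks: Sequence[RawPeak],
    parent_charge: int,
    config: Optional[DeisotopeConfig] = None,
) -> List[FragmentIon]:
    """Collapse isotopic envelopes to neutral monoisotopic fragment ions.

    Greedy search from the most intense unassigned peak outwards.  For each
    candidate charge (1..parent_charge, or the peak's own charge label when
    present) the envelope is extended peak by peak at spacings of
    1.003355/z Th; a partner must fall within ``config.mz_tolerance`` and
    its intensity must agree with the averagine-predicted envelope within a
    factor of ``config.ratio_tolerance``.  The charge explaining the most
    peaks wins (ties favour the lower charge).  Peaks that join no accepted
    envelope are dropped.
    """
    config = config or DeisotopeConfig()
    if parent_charge < 1:
        raise ValueError("parent charge must be >= 1")
    peaks = sorted(raw_peaks, key=lambda p: p.mz)
    mzs = np.array([p.mz for p in peaks])
    order = sorted(range(len(peaks)), key=lambda i: -peaks[i].intensity)
    assigned = [False] * len(peaks)
    ions: List[Tuple[float, float, int]] = []  # (neutral mass, raw abundance, z)

    def find_partner(mz: float, exclude_assigned: bool = True) -> Optional[int]:
        idx = int(np.searchsorted(mzs, mz))
        best, best_d = None, config.mz_tolerance
        for j in (idx - 1, idx):
            if 0 <= j < len(peaks) and not (exclude_assigned and assigned[j]):
                d = abs(mzs[j] - mz)
                if d < best_d:
                    best, best_d = j, d
        return best

    for seed in order:
        if assigned[seed]:
            continue
        seed_peak = peaks[seed]
        charges = [seed_peak.charge] if seed_peak.charge > 0 else list(
            range(1, max(parent_charge, 1) + 1)
        )
        best_env: Optional[List[int]] = None
        best_z = 0
        for z in charges:
            spacing = ISOTOPE_SPACING / z
            env = [seed]
            # extend towards lower m/z first: the true monoisotopic peak may
            # sit below a more intense seed
            while True:
                j = find_partner(mzs[env[0]] - spacing)
                if j is None:
                    break
                env.insert(0, j)
            approx_mass = (mzs[env[0]] - PROTON) * z
            ratios = _predicted_ratios(max(approx_mass, 50.0), 8)
            # extend towards higher m/z with a shape check
            while len(env) < 8:
                j = find_partner(mzs[env[-1]] + spacing)
                if j is None:
                    break
                k = len(env)
                observed = peaks[j].intensity / peaks[env[0]].intensity
                predicted = ratios[k] if k < len(ratios) else 0.0
                if predicted <= 0:
                    break
                if not (
                    predicted / config.ratio_tolerance
                    <= observed
                    <= predicted * config.ratio_tolerance
                ):
                    break
                env.append(j)
            if best_env is None or len(env) > len(best_env):
                best_env, best_z = env, z
        assert best_env is not None
        if config.require_partner:
            minimum = max(2, config.min_isotope_peaks)
        elif best_z >= 2:
            minimum = config.min_isotope_peaks
        else:
            minimum = 1
        if len(best_env) < minimum:
            assigned[seed] = True  # failed deisotoping: peak removed
            continue
        for j in best_env:
            assigned[j] = True
        mono_mz = mzs[best_env[0]]
        neutral = (mono_mz - PROTON) * best_z
        if neutral <= 0:
            continue
        abundance = sum(peaks[j].intensity for j in best_env)
        ions.append((neutral, abundance, best_z))

    if not ions:
        return []
    ions.sort(key=lambda ion: ion[0])
    # merge near-duplicate neutral masses, keeping the higher abundance
    merged: List[Tuple[float, float, int]] = []
    for ion in ions:
        if merged and ion[0] - merged[-1][0] < config.merge_tolerance:
            if ion[1] > merged[-1][1]:
                merged[-1] = ion
        else:
            merged.append(ion)
    base = max(ion[1] for ion in merged)
    return [
        FragmentIon(neutral, min(100.0, 100.0 * abundance / base), z)
        for neutral, abundance, z in merged
    ]


def prepare_spectrum(
    header: ScanHeader,
    ions: Sequence[FragmentIon],
    mass_tolerance: float = 0.01,
) -> TandemSpectrum:
    """Assemble a TandemSpectrum: anchor prepended, ions sorted ascending,
    fragments heavier than the parent dropped with a warning."""
    if header.charge < 1:
        raise SpectrumRejected(
            f"scan {header.scan_id}: parent charge undetermined, excluded"
        )
    parent = header.parent_neutral_mass
    kept: List[FragmentIon] = []
    for ion in sorted(ions, key=lambda i: i.neutral_mass):
        if ion.neutral_mass > parent + mass_tolerance:
            logger.warning(
                "scan %d: dropping ion at %.5f Da above parent mass %.5f",
                header.scan_id,
                ion.neutral_mass,
                parent,
            )
            continue
        if kept and ion.neutral_mass - kept[-1].neutral_mass < 1e-9:
            continue
        if ion.neutral_mass == 0.0:
            continue
        kept.append(ion)
    anchor = FragmentIon(0.0, 100.0, 1)
    spectrum = TandemSpectrum(header.scan_id, parent, header.charge, [anchor] + kept)
    spectrum.validate()
    return spectrum
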