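"""Ground-truthed synthetic peptides, tandem spectra and full scans.

The generator emulates the data a tryptic shotgun-proteomics run produces:
random tryptic peptides (ending in K or R), y/b fragment ladders with
partial coverage, Gaussian fragment mass error, uniform noise peaks below
the parent mass, and MS1 isotopic envelopes with an optional systematic
calibration offset.  Every emitted fragment carries bookkeeping that maps
it back to its (peptide, ion type, index) identity, so tests can check
recovered tags and mass errors against exact ground truth.

Defaults mirror a well-calibrated Orbitrap-class acquisition: fragment
mass error s.d. of 0.0025 Da — a quarter of the default 0.01-Da edge
tolerance, so nearly all relative errors fall inside ±0.01 Da — roughly
70% fragment-ion coverage per ion type and site, and a handful of noise
peaks per spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .benchmark import IdentificationRecord
from .chem import (
    AminoAcidTable,
    DEFAULT_TABLE,
    ISOTOPE_SPACING,
    PROTON,
    WATER,
    map_il_to_j,
)
from .mass_filter import theoretical_isotope_distribution
from .ms_io import FragmentIon, FullScan, RawPeak, ScanHeader, TandemSpectrum

#: The 20 standard residue letters peptides are drawn from.
PEPTIDE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    n_peptides: int = 100
    length_range: Tuple[int, int] = (7, 20)
    charge_probabilities: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.6, 3: 0.3}
    )
    fragment_mass_error_sd: float = 0.0025  # Da
    ion_coverage: float = 0.7  # per ion type and cleavage site
    noise_peaks: int = 8
    calibration_offset: float = 0.0  # Da (neutral-mass scale) in full scans
    decoy_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ion_coverage <= 1):
            raise ValueError("ion_coverage must be in [0, 1]")
        if self.fragment_mass_error_sd < 0:
            raise ValueError("mass error sd must be >= 0")
        total = sum(self.charge_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("charge probabilities must sum to 1")


@dataclass(frozen=True)
class FragmentTruth:
    ion_type: str  # "y" | "b" | "noise"
    index: int  # ladder index, 0 for noise
    true_mass: float


@dataclass
class SimulatedSpectrum:
    peptide: str
    charge: int
    spectrum: TandemSpectrum
    truth: Dict[int, FragmentTruth]  # ion position in spectrum.ions -> identity

    @property
    def tag_target(self) -> str:
        """The peptide in tag alphabet (I/L collapsed to J)."""
        return map_il_to_j(self.peptide)


def generate_peptides(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> List[str]:
    """Random tryptic-like peptides: uniform residues, K/R C-terminus."""
    rng = rng or np.random.default_rng(config.seed)
    low, high = config.length_range
    peptides = []
    letters = np.array(list(PEPTIDE_ALPHABET))
    for _ in range(config.n_peptides):
        length = int(rng.integers(low, high + 1))
        body = "".join(rng.choice(letters, size=length - 1))
        terminus = "K" if rng.random() < 0.5 else "R"
        peptides.append(body + terminus)
    return peptides


def theoretical_fragments(
    peptide: str, table: AminoAcidTable = DEFAULT_TABLE
) -> Tuple[List[float], List[float]]:
    """Neutral y/b ladders (b_1..b_{n-1}, y_1..y_{n-1}).

    b_k is the sum of the first k residue masses; y_h the sum of the last h
    plus one water; complementary pairs b_k + y_{n-k} equal the neutral
    parent mass.
    """
    residues = map_il_to_j(peptide)
    masses = [table.mass(r) for r in residues]
    b_ladder = list(np.cumsum(masses[:-1]))
    y_ladder = list(np.cumsum(masses[:0:-1]) + WATER)
    return [float(b) for b in b_ladder], [float(y) for y in y_ladder]


def _draw_charge(config: SimulationConfig, rng: np.random.Generator) -> int:
    charges = sorted(config.charge_probabilities)
    probabilities = [config.charge_probabilities[z] for z in charges]
    return int(rng.choice(charges, p=probabilities))


def simulate_spectrum(
    peptide: str,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    charge: Optional[int] = None,
    scan_id: int = 1,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> SimulatedSpectrum:
    """One tandem spectrum with ground truth.

    Each theoretical y/b ion is included with probability
    ``config.ion_coverage``, perturbed by Gaussian mass error; noise peaks
    are uniform in mass below the parent and drawn from the lower quartile
    of signal intensities.
    """
    rng = rng or np.random.default_rng(config.seed)
    if charge is None:
        charge = _draw_charge(config, rng)
    residues = map_il_to_j(peptide)
    parent_mass = table.peptide_neutral_mass(residues)
    b_ladder, y_ladder = theoretical_fragments(residues, table)
    entries: List[Tuple[float, float, FragmentTruth]] = []
    for ion_type, ladder in (("b", b_ladder), ("y", y_ladder)):
        for index, true_mass in enumerate(ladder, start=1):
            if rng.random() >= config.ion_coverage:
                continue
            observed = true_mass + rng.normal(0.0, config.fragment_mass_error_sd)
            intensity = float(rng.uniform(20.0, 100.0))
            entries.append(
                (observed, intensity, FragmentTruth(ion_type, index, true_mass))
            )
    signal_intensities = sorted(i for _m, i, _t in entries) or [20.0]
    noise_ceiling = signal_intensities[max(len(signal_intensities) // 4 - 1, 0)]
    for _ in range(config.noise_peaks):
        mass = float(rng.uniform(57.0, max(parent_mass - 1.0, 60.0)))
        intensity = float(rng.uniform(1.0, noise_ceiling))
        entries.append((mass, intensity, FragmentTruth("noise", 0, mass)))
    entries.sort(key=lambda e: e[0])
    # drop duplicates closer than 1 nDa to keep masses strictly ascending
    deduped: List[Tuple[float, float, FragmentTruth]] = []
    for entry in entries:
        if deduped and entry[0] - deduped[-1][0] < 1e-6:
            continue
        deduped.append(entry)
    base = max((i for _m, i, _t in deduped), default=100.0)
    ions = [FragmentIon(0.0, 100.0, 1)]
    truth: Dict[int, FragmentTruth] = {}
    for position, (mass, intensity, fragment_truth) in enumerate(deduped, start=1):
        ions.append(FragmentIon(mass, min(100.0, 100.0 * intensity / base), 1))
        truth[position] = fragment_truth
    spectrum = TandemSpectrum(scan_id, parent_mass, charge, ions)
    spectrum.validate()
    return SimulatedSpectrum(residues, charge, spectrum, truth)


def simulate_batch(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[SimulatedSpectrum]:
    """A reproducible batch: peptides and one spectrum each."""
    rng = rng or np.random.default_rng(config.seed)
    peptides = generate_peptides(config, rng)
    return [
        simulate_spectrum(peptide, config, rng, scan_id=scan_id)
        for scan_id, peptide in enumerate(peptides, start=1)
    ]


def spectrum_to_ft2_record(
    simulated: SimulatedSpectrum,
) -> Tuple[ScanHeader, List[RawPeak]]:
    """Render a simulated spectrum as raw FT2 peaks (two-peak isotopic
    envelopes at charge 1) so that the full parsing + deisotoping pipeline
    can be exercised end to end."""
    spectrum = simulated.spectrum
    header = ScanHeader(
        scan_id=spectrum.scan_id,
        precursor_mz=(spectrum.parent_neutral_mass + spectrum.parent_charge * PROTON)
        / spectrum.parent_charge,
        charge=spectrum.parent_charge,
        protonated_mass=spectrum.parent_neutral_mass + PROTON,
    )
    peaks: List[RawPeak] = []
    for ion in spectrum.ions:
        if ion.neutral_mass == 0.0:
            continue
        mono_mz = ion.neutral_mass + PROTON
        intensity = ion.relative_abundance * 100.0
        peaks.append(RawPeak(mono_mz, intensity, 7500.0, 0.0, 1.0, 0))
        peaks.append(RawPeak(mono_mz + ISOTOPE_SPACING, intensity * 0.25, 7500.0, 0.0, 1.0, 0))
    peaks.sort(key=lambda p: p.mz)
    return header, peaks


def simulate_full_scans(
    peptides: Sequence[Tuple[str, int]],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    first_scan: int = 1,
) -> Tuple[List[FullScan], List[IdentificationRecord], Dict[int, str]]:
    """MS1 scans with isotopic envelopes plus a paired identification table.

    The acquisition is laid out in cycles of one full scan followed by five
    MS/MS scans.  Every peptide's envelope, shifted by the configured
    calibration offset (neutral-mass scale), is rendered into all full
    scans so that each MS/MS scan finds its six bracketing MS1 scans
    populated.  Decoy identifications are mixed in at ``config.decoy_rate``
    and carry no envelope of their own.  Returns (full scans,
    identification records, scan -> peptide ground truth).
    """
    rng = rng or np.random.default_rng(config.seed)
    n_cycles = (len(peptides) + 4) // 5 + 1
    full_scan_ids = [first_scan + 6 * c for c in range(n_cycles + 1)]
    records: List[IdentificationRecord] = []
    truth: Dict[int, str] = {}
    envelope_peaks: List[RawPeak] = []
    for index, (peptide, charge) in enumerate(peptides):
        cycle, slot = divmod(index, 5)
        ms2_scan = first_scan + 6 * cycle + 1 + slot
        is_decoy = bool(rng.random() < config.decoy_rate)
        records.append(
            IdentificationRecord(
                scan_id=ms2_scan,
                peptide=f"K.{peptide}.A",
                charge=charge,
                xcorr=float(rng.uniform(2.6, 5.0)),
                delcn=float(rng.uniform(0.1, 0.4)),
                protein=f"{'DECOY_' if is_decoy else ''}prot{index // 2}",
                is_decoy=is_decoy,
            )
        )
        truth[ms2_scan] = peptide
        if is_decoy:
            continue  # a false identification has no matching envelope
        distribution = theoretical_isotope_distribution(peptide, charge)
        scale = float(rng.uniform(1e4, 1e6))
        for mz, fraction in distribution.peaks:
            envelope_peaks.append(
                RawPeak(
                    mz + config.calibration_offset / charge,
                    fraction * scale,
                    30000.0,
                    0.0,
                    1.0,
                    charge,
                )
            )
    scans: List[FullScan] = []
    for scan_id in full_scan_ids:
        peaks = sorted(envelope_peaks, key=lambda p: p.mz)
        scans.append(FullScan(scan_id, list(peaks)))
    return scans, records, truth
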