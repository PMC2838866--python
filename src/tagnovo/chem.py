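"""Mass-spectrometric constants, residue masses and isotope arithmetic.

All masses are monoisotopic and expressed in daltons.  Residue masses are
derived from elemental compositions (via :mod:`pyteomics.mass`) so that
compositional identities hold exactly: the mass of glutamine equals the sum
of the glycine and alanine residue masses because Q and G+A have the same
elemental composition, and the Q/K mass gap is the N2H2 vs C2H4 difference
of 0.036 Da.

The isobaric residues leucine and isoleucine are collapsed onto the single
letter ``J`` so that every residue in the working alphabet has a unique mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from pyteomics import mass as _pmass

#: Mass of a proton (charge carrier), Da.
PROTON = 1.00727646688

#: Mass of a water molecule (peptide terminal groups H + OH), Da.
WATER = _pmass.calculate_mass(formula="H2O")

#: C13 - C12 mass difference: the canonical isotopic-envelope spacing, Da.
ISOTOPE_SPACING = 1.003355

#: Residues the sequencing alphabet is built from.  I and L are excluded in
#: favour of J; every member has a unique monoisotopic mass.
ALPHABET = "ACDEFGHJKMNPQRSTVWY"

# Averagine: the average elemental composition of proteinaceous material per
# 111.1254 Da of peptide mass, used to predict envelope shapes when the
# sequence is unknown.
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254


def _residue_composition(letter: str) -> Dict[str, int]:
    source = "L" if letter == "J" else letter
    return dict(_pmass.std_aa_comp[source])


def residue_mass(letter: str) -> float:
    """Monoisotopic residue (= amino acid minus water) mass in Da."""
    source = "L" if letter == "J" else letter
    return _pmass.calculate_mass(composition=_pmass.std_aa_comp[source])


@dataclass(frozen=True)
class AminoAcidTable:
    """The 19-letter residue alphabet with monoisotopic masses.

    The table is immutable; variants (e.g. carbamidomethylated cysteine)
    are produced with :meth:`with_overrides`.
    """

    masses: Mapping[str, float]

    def __post_init__(self) -> None:
        letters = set(self.masses)
        if "J" not in letters or "I" in letters or "L" in letters:
            raise ValueError("residue table must use J for the I/L isobars")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("residue masses must be positive")
        if len(set(self.masses.values())) != len(self.masses):
            raise ValueError("residue masses must be unique")

    @classmethod
    def default(cls) -> "AminoAcidTable":
        return cls(masses={aa: residue_mass(aa) for aa in ALPHABET})

    def with_overrides(self, overrides: Mapping[str, float]) -> "AminoAcidTable":
        merged = dict(self.masses)
        for aa, m in overrides.items():
            if aa not in merged:
                raise KeyError(f"unknown residue {aa!r}")
            merged[aa] = float(m)
        return AminoAcidTable(masses=merged)

    def mass(self, residue: str) -> float:
        return self.masses[residue]

    def peptide_residue_sum(self, residues: str) -> float:
        return sum(self.masses[r] for r in residues)

    def peptide_neutral_mass(self, residues: str) -> float:
        """Neutral monoisotopic peptide mass: residue sum plus one water."""
        return self.peptide_residue_sum(residues) + WATER

    def items(self) -> Iterable[Tuple[str, float]]:
        return self.masses.items()

    def __iter__(self):
        return iter(self.masses)

    def __len__(self) -> int:
        return len(self.masses)


def map_il_to_j(sequence: str) -> str:
    """Collapse I and L onto J, the convention used for tag comparison."""
    return sequence.replace("I", "J").replace("L", "J")


def peptide_composition(peptide: str) -> Dict[str, int]:
    """Elemental composition of a neutral peptide (residues + water)."""
    comp: Dict[str, int] = {"H": 2, "O": 1}
    for letter in peptide:
        if letter in ("I", "L"):
            letter = "L"
        elif letter == "J":
            letter = "L"
        elif letter not in _pmass.std_aa_comp:
            raise KeyError(f"unknown residue {letter!r}")
        for element, count in _residue_composition(letter).items():
            comp[element] = comp.get(element, 0) + count
    return comp


def monoisotopic_mass(composition: Mapping[str, float]) -> float:
    """Monoisotopic mass of an elemental composition (fractional counts
    allowed, for averagine models)."""
    total = 0.0
    for element, count in composition.items():
        mono = _pmass.nist_mass[element][0][0]
        total += count * mono
    return total


def _element_neutron_distribution(element: str) -> Dict[int, float]:
    """Isotope abundance of one atom, keyed by extra neutron count."""
    isotopes = _pmass.nist_mass[element]
    mono_number = min(k for k, (_m, a) in isotopes.items() if k != 0 and a > 0)
    dist: Dict[int, float] = {}
    for number, (_m, abundance) in isotopes.items():
        if number == 0 or abundance == 0.0:
            continue
        dist[number - mono_number] = abundance
    return dist


def isotope_envelope(
    composition: Mapping[str, float], max_peaks: int = 10
) -> np.ndarray:
    """Aggregated isotopic envelope of a molecule.

    Returns relative abundances indexed by extra-neutron count (element 0 is
    the monoisotopic peak), normalised to sum to 1.  Fractional atom counts
    (averagine) are handled by rounding to the nearest integer atom count.

    The aggregation is the standard polynomial convolution of per-element
    isotope distributions; fine structure within one nominal isotope peak is
    not resolved.
    """
    envelope = np.zeros(max_peaks)
    envelope[0] = 1.0
    for element, count in composition.items():
        n = int(round(count))
        if n <= 0:
            continue
        single = np.zeros(max_peaks)
        for extra, abundance in _element_neutron_distribution(element).items():
            if extra < max_peaks:
                single[extra] = abundance
        single /= single.sum()
        # n-fold convolution by exponentiation-by-squaring
        power = single
        remaining = n
        acc = None
        while remaining:
            if remaining & 1:
                acc = power if acc is None else np.convolve(acc, power)[:max_peaks]
            remaining >>= 1
            if remaining:
                power = np.convolve(power, power)[:max_peaks]
        envelope = np.convolve(envelope, acc)[:max_peaks]
    return envelope / envelope.sum()


def averagine_envelope(neutral_mass: float, max_peaks: int = 6) -> np.ndarray:
    """Predicted isotopic envelope for an unknown peptide of a given mass,
    using the averagine average composition."""
    scale = max(neutral_mass, _AVERAGINE_MASS) / _AVERAGINE_MASS
    comp = {el: cnt * scale for el, cnt in _AVERAGINE.items()}
    return isotope_envelope(comp, max_peaks=max_peaks)


# Default table instance shared across the package.
DEFAULT_TABLE: AminoAcidTable = AminoAcidTable.default()
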