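"""Molecular formulas, adduct masses and theoretical isotopologue envelopes.

The screening workflow gates candidate ions on exact mass and isotope
pattern, so this module provides the three chemical primitives everything
else builds on:

* Hill-notation formula parsing into element counts.
* Monoisotopic (principal-isotope) neutral and adduct masses at sub-mDa
  accuracy, with the electron mass handled explicitly -- GC-APCI produces
  both radical cations (M+.) and protonated molecules ([M+H]+), and at a
  2 mDa mass gate the ~0.55 mDa electron term is not negligible.
* Theoretical isotope patterns computed by exact abundance convolution
  over all elements and aggregated into nominal-mass-spaced centroids,
  matching the centroided envelopes a deconvolution tool reports.

Isotope masses and natural abundances come from the NIST table embedded
in :mod:`pyteomics`, so results are reproducible offline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Mapping

from pyteomics.mass import nist_mass

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "AdductKind",
    "IsotopePattern",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_pattern",
    "PROTON_MASS",
    "ELECTRON_MASS",
]

#: Mass of a proton in Da (CODATA).
PROTON_MASS = 1.007276466
#: Mass of an electron in Da (CODATA).
ELECTRON_MASS = 0.000548580

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed or validated."""


def _known_isotopes(element: str) -> list[tuple[int, float, float]]:
    """Naturally occurring isotopes of *element* as (mass number, mass, abundance)."""
    entry = nist_mass.get(element)
    if entry is None:
        return []
    isotopes = [
        (number, mass, abundance)
        for number, (mass, abundance) in entry.items()
        if number != 0 and abundance > 0.0
    ]
    isotopes.sort()
    return isotopes


def _principal_isotope(element: str) -> tuple[int, float, float]:
    """Most abundant naturally occurring isotope of *element*."""
    return max(_known_isotopes(element), key=lambda iso: iso[2])


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition, e.g. ``{"C": 6, "Cl": 6}`` for hexachlorobenzene.

    All element symbols must exist in the embedded isotope table and every
    count must be a positive integer.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("formula must contain at least one atom")
        for element, count in self.element_counts.items():
            if not _known_isotopes(element):
                raise FormulaError(f"unknown element {element!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {element} must be a positive integer, got {count!r}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    def __str__(self) -> str:
        return self.hill_notation()

    def hill_notation(self) -> str:
        """Render in Hill order (C first, H second, others alphabetical)."""
        counts = dict(self.element_counts)
        parts: list[str] = []
        for element in ("C", "H"):
            if element in counts:
                n = counts.pop(element)
                parts.append(element if n == 1 else f"{element}{n}")
        for element in sorted(counts):
            n = counts[element]
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    @property
    def total_atoms(self) -> int:
        return sum(self.element_counts.values())


class AdductKind(Enum):
    """Ion species formed under APCI charge/proton transfer (singly charged)."""

    RADICAL_CATION = "M+."
    PROTONATED = "[M+H]+"
    DEPROTONATED = "[M-H]-"

    @property
    def mass_shift(self) -> float:
        """m/z shift relative to the neutral monoisotopic mass."""
        return _ADDUCT_SHIFTS[self]

    @property
    def sirius_ionization(self) -> str:
        """Ionization label used by external fragmentation scorers."""
        return _SIRIUS_LABELS[self]


_ADDUCT_SHIFTS = {
    # Charge transfer: lose one electron.
    AdductKind.RADICAL_CATION: -ELECTRON_MASS,
    # Proton transfer: gain H+ = H atom minus its electron.
    AdductKind.PROTONATED: PROTON_MASS,
    AdductKind.DEPROTONATED: -PROTON_MASS,
}

_SIRIUS_LABELS = {
    AdductKind.RADICAL_CATION: "[M]+",
    AdductKind.PROTONATED: "[M+H]+",
    AdductKind.DEPROTONATED: "[M-H]-",
}


@dataclass(frozen=True)
class IsotopePattern:
    """A centroided isotopologue envelope.

    ``peaks`` are (m/z, relative intensity) pairs sorted by m/z, with the
    base peak normalised to 100 and all intensities in (0, 100].
    """

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("isotope pattern must contain at least one peak")
        mzs = [mz for mz, _ in self.peaks]
        if sorted(mzs) != mzs:
            raise ValueError("isotope pattern peaks must be sorted by m/z")
        intensities = [ri for _, ri in self.peaks]
        if sum(1 for ri in intensities if abs(ri - 100.0) < 1e-9) != 1:
            raise ValueError("isotope pattern must have exactly one base peak at 100%")
        if any(ri <= 0.0 or ri > 100.0 + 1e-9 for ri in intensities):
            raise ValueError("relative intensities must lie in (0, 100]")

    @property
    def base_peak_mz(self) -> float:
        """m/z of the most abundant isotopologue."""
        return max(self.peaks, key=lambda p: p[1])[0]

    @property
    def is_single_peak(self) -> bool:
        """True for compounds of single-isotope elements only; the isotope
        gate is bypassed for such patterns."""
        return len(self.peaks) == 1


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C6Cl6"``.

    Raises :class:`FormulaError` naming the offending symbol for unknown
    elements, and reporting the character position for malformed input.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.group(1), match.group(2)
        if not _known_isotopes(element):
            raise FormulaError(f"unknown element {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral mass built from each element's most abundant isotope, in Da."""
    return sum(
        count * _principal_isotope(element)[1]
        for element, count in formula.element_counts.items()
    )


def adduct_mz(formula: MolecularFormula, adduct: AdductKind) -> float:
    """Singly charged adduct m/z: neutral monoisotopic mass plus the adduct shift."""
    return monoisotopic_mass(formula) + adduct.mass_shift


# ---------------------------------------------------------------------------
# Isotope pattern by abundance convolution
# ---------------------------------------------------------------------------

_PRUNE = 1e-12  # drop isotopologue probability mass below this during convolution


def _convolve(a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]]
              ) -> dict[int, tuple[float, float]]:
    """Convolve two distributions keyed by total mass number.

    Values are (P, S): total probability and probability-weighted mass sum,
    so the intensity-weighted centroid of a bin is S / P.
    """
    out: dict[int, tuple[float, float]] = {}
    for ka, (pa, sa) in a.items():
        for kb, (pb, sb) in b.items():
            p = pa * pb
            if p < _PRUNE:
                continue
            s = pa * sb + pb * sa
            key = ka + kb
            p0, s0 = out.get(key, (0.0, 0.0))
            out[key] = (p0 + p, s0 + s)
    return out


@lru_cache(maxsize=4096)
def _element_distribution(element: str, count: int) -> tuple[tuple[int, float, float], ...]:
    single = {
        number: (abundance, abundance * mass)
        for number, mass, abundance in _known_isotopes(element)
    }
    dist = {0: (1.0, 0.0)}
    for _ in range(count):
        dist = _convolve(dist, single)
    return tuple((k, p, s) for k, (p, s) in sorted(dist.items()))


def isotope_pattern(
    formula: MolecularFormula,
    adduct: AdductKind = AdductKind.RADICAL_CATION,
    min_rel_intensity: float = 1.0,
    max_peaks: int = 8,
) -> IsotopePattern:
    """Theoretical isotopologue envelope for an adduct ion of *formula*.

    The exact multinomial distribution is computed per element and convolved
    across elements; isotopologues are then aggregated into nominal-mass
    (mass-number) centroids, mirroring the merging of fine structure (e.g.
    13C2 vs 37Cl) in centroided instrument data. Intensities are normalised
    to base = 100, pruned below *min_rel_intensity* percent and limited to
    the *max_peaks* most intense centroids.

    The ionising proton of [M+H]+ is treated as pure 1H: its isotope
    contribution (0.0115%) is far below any practical intensity tolerance,
    so the envelope shape is identical across adducts up to the m/z shift.
    """
    if not 0.0 <= min_rel_intensity < 100.0:
        raise ValueError("min_rel_intensity must lie in [0, 100)")
    if max_peaks < 2:
        raise ValueError("max_peaks must be at least 2")

    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for element, count in sorted(formula.element_counts.items()):
        elem = {k: (p, s) for k, p, s in _element_distribution(element, count)}
        dist = _convolve(dist, elem)

    p_max = max(p for p, _ in dist.values())
    peaks = []
    for _, (p, s) in sorted(dist.items()):
        rel = p / p_max * 100.0
        if rel >= min_rel_intensity and rel > 0.0:
            peaks.append((s / p + adduct.mass_shift, rel))
    if len(peaks) > max_peaks:
        peaks = sorted(sorted(peaks, key=lambda pk: pk[1], reverse=True)[:max_peaks])
    return IsotopePattern(tuple(peaks))
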