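"""Monoisotopic mass bookkeeping for glycopeptide work.

Residue masses of the monosaccharide units are derived from their elemental
compositions using standard monoisotopic atomic masses, so that a modified
unit (e.g. an ammonia-adducted hexose) is always exactly the base unit plus
the adduct's elements.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PROTON",
    "WATER",
    "NH3",
    "HPO3",
    "HEXNAC",
    "ISOTOPE_SPACING",
    "Monosaccharide",
    "MONOSACCHARIDES",
    "residue_mass_of",
    "elemental_mass",
    "UnknownMonosaccharideError",
]

# monoisotopic atomic masses (CODATA / IUPAC 2021)
ELEMENT_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

PROTON = 1.00727646688
WATER = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]
NH3 = ELEMENT_MASS["N"] + 3 * ELEMENT_MASS["H"]
HPO3 = ELEMENT_MASS["H"] + ELEMENT_MASS["P"] + 3 * ELEMENT_MASS["O"]
ISOTOPE_SPACING = 1.00335  # average C13-C12 spacing used for deisotoping


class UnknownMonosaccharideError(KeyError):
    """Raised when a glycan names a symbol absent from the mass table."""


def elemental_mass(composition: dict[str, int]) -> float:
    """Monoisotopic mass of an element->count map."""
    return sum(ELEMENT_MASS[el] * n for el, n in composition.items())


def _merge(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + n
    return out


@dataclass(frozen=True)
class Monosaccharide:
    """One saccharide unit: residue (dehydrated) elemental composition + mass."""

    symbol: str
    elemental_composition: dict[str, int]
    residue_mass: float

    @classmethod
    def from_elements(cls, symbol: str, composition: dict[str, int]) -> "Monosaccharide":
        return cls(symbol, composition, elemental_mass(composition))

    def with_adduct(self, symbol: str, adduct: dict[str, int]) -> "Monosaccharide":
        """Derive a modified unit (same residue + adduct elements)."""
        return Monosaccharide.from_elements(symbol, _merge(self.elemental_composition, adduct))


_HEX = Monosaccharide.from_elements("H", {"C": 6, "H": 10, "O": 5})

#: Built-in unit table.  H=Hex, N=HexNAc, F=Fuc/dHex, A=NeuAc, G=NeuGc,
#: aH=ammonia-adducted Hex, pH=phospho-Hex.
MONOSACCHARIDES: dict[str, Monosaccharide] = {
    m.symbol: m
    for m in (
        _HEX,
        Monosaccharide.from_elements("N", {"C": 8, "H": 13, "N": 1, "O": 5}),
        Monosaccharide.from_elements("F", {"C": 6, "H": 10, "O": 4}),
        Monosaccharide.from_elements("A", {"C": 11, "H": 17, "N": 1, "O": 8}),
        Monosaccharide.from_elements("G", {"C": 11, "H": 17, "N": 1, "O": 9}),
        _HEX.with_adduct("aH", {"N": 1, "H": 3}),
        _HEX.with_adduct("pH", {"H": 1, "P": 1, "O": 3}),
    )
}

#: Fixed symbol order used everywhere a deterministic ordering of
#: monosaccharide counts is needed (subcomposition enumeration, reports).
SYMBOL_ORDER: tuple[str, ...] = ("H", "N", "F", "A", "G", "aH", "pH")

HEXNAC = MONOSACCHARIDES["N"].residue_mass


def residue_mass_of(symbol: str) -> float:
    try:
        return MONOSACCHARIDES[symbol].residue_mass
    except KeyError:
        raise UnknownMonosaccharideError(
            f"unknown monosaccharide symbol {symbol!r}; known: {sorted(MONOSACCHARIDES)}"
        ) from None
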