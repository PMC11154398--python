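"""Element property tables: van der Waals radii, atomic masses, polarity defaults.

Radii are the Bondi (1964) consensus set in Å; masses are IUPAC 2021 standard
atomic weights in g/mol, abridged to the elements that occur in small-molecule
formulation work.
"""

from __future__ import annotations

# Bondi van der Waals radii, Å.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Na": 2.27,
    "Mg": 1.73,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "K": 2.75,
    "Br": 1.85,
    "I": 1.98,
}

# Standard atomic weights, g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Br": 79.904,
    "I": 126.904,
}

# Elements whose atoms are polar under the default element-based rule; a
# hydrogen is polar when bonded to one of these.
POLAR_ELEMENTS: frozenset[str] = frozenset({"N", "O", "S", "P"})

# Elements not counted as heavy atoms.
LIGHT_ELEMENTS: frozenset[str] = frozenset({"H", "D"})

#: Debye per elementary-charge·Å.
DEBYE_PER_E_ANGSTROM = 4.803


def normalize_element(symbol: str) -> str:
    """Canonicalise an element symbol ('CL' -> 'Cl')."""
    s = symbol.strip()
    if not s:
        raise ValueError("empty element symbol")
    return s[0].upper() + s[1:].lower()
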