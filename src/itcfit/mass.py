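"""Monoisotopic mass / m-z calculator for ESI-MS characterisation.

Sums most-abundant-isotope atomic masses over a Hill-style formula and
divides by the charge magnitude.  The electron mass (0.00055 Da per
charge) is deliberately neglected — far below the 0.001 Da precision at
which high-resolution "calcd" values are quoted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["MolecularFormula", "parse_formula", "monoisotopic_mass", "monoisotopic_mz",
           "MONOISOTOPIC_MASS"]

#: Monoisotopic atomic masses, Da (IUPAC/NIST most-abundant isotopes).
MONOISOTOPIC_MASS = {
    "H": 1.0078250319,
    "D": 2.0141017780,
    "B": 11.0093055,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Mg": 23.9850417,
    "Si": 27.9769265327,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "K": 38.9637064864,
    "Ca": 39.9625909,
    "Fe": 55.9349421,
    "Cu": 62.9296011,
    "Zn": 63.9291466,
    "Br": 78.9183376,
    "I": 126.904468,
}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
# a trailing element count and a charge multiplier are ambiguous in flat
# text ("O122+"); accept only the unambiguous spellings: "+", "++", "2 +",
# "2+" after a space, or repeated signs
_CHARGE_RE = re.compile(r"(?:\s+(\d+)\s*)?([+-]+)$")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts plus an overall charge."""

    element_counts: dict
    charge: int = 0

    def __post_init__(self) -> None:
        for sym, n in self.element_counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise ValueError(f"unrecognised element symbol {sym!r}")
            if not isinstance(n, int) or n <= 0:
                raise ValueError(f"count for {sym} must be a positive integer, got {n!r}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``"C100H176Cl3N4O12"`` with an optional trailing charge
    (``+``, ``++``, ``" 2+"``, ``-`` …) into a :class:`MolecularFormula`.

    Malformed input raises ValueError naming the offending position.
    """
    s = text.strip()
    if not s:
        raise ValueError("empty formula")
    charge = 0
    m = _CHARGE_RE.search(s)
    if m:
        signs = m.group(2)
        if len(set(signs)) > 1:
            raise ValueError(f"mixed charge signs in {text!r}")
        mag = int(m.group(1)) if m.group(1) else len(signs)
        charge = mag if signs[0] == "+" else -mag
        s = s[: m.start()]
    counts: dict = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unrecognised element {sym!r} at position {pos}")
        n = int(digits) if digits else 1
        if n == 0:
            raise ValueError(f"zero count for {sym} at position {pos}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if not counts:
        raise ValueError(f"no elements found in {text!r}")
    return MolecularFormula(element_counts=counts, charge=charge)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic mass of the formula, Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[sym] * n
               for sym, n in formula.element_counts.items())


def monoisotopic_mz(formula: MolecularFormula | str, charge: int | None = None) -> float:
    """Monoisotopic m/z: mass divided by |charge|, electron mass neglected."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if charge is None:
        charge = formula.charge
    if charge == 0:
        raise ValueError("charge must be nonzero for an m/z value")
    return monoisotopic_mass(formula) / abs(charge)
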