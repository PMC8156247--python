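"""Monoisotopic mass and molecular-formula arithmetic for linear and cyclic peptides.

All arithmetic is exact integer bookkeeping on element counts plus a fixed
table of monoisotopic element masses.  Reported m/z values round to 4
decimals; internal computation stays at full float precision.
"""

from __future__ import annotations

import enum
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "ELEMENT_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "Formula",
    "WATER",
    "CO",
    "AMMONIA",
    "RESIDUE_FORMULAS",
    "RESIDUE_MASSES",
    "STANDARD_RESIDUES",
    "Topology",
    "Peptide",
    "formula_mass",
    "peptide_formula",
    "peptide_mass",
    "mz_protonated",
    "ppm_delta",
]

# Monoisotopic masses, fixed to 6 decimals for reproducible 4-decimal m/z output.
ELEMENT_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
}

PROTON_MASS: float = 1.007276
ELECTRON_MASS: float = ELEMENT_MASS["H"] - PROTON_MASS  # 0.000549


class Topology(str, enum.Enum):
    LINEAR = "linear"
    CYCLIC = "cyclic"


class Formula(Mapping):
    """Immutable element-count vector.

    Supports element-wise ``+`` and ``-``; subtraction that would drive any
    count negative raises ``ValueError``.  Zero counts are dropped so that
    equal formulas compare equal regardless of construction route.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for elem, n in (counts or {}).items():
            if not isinstance(n, int):
                raise TypeError(f"element count for {elem!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {elem!r}: {n}")
            if n:
                clean[elem] = n
        self._counts = clean

    def __getitem__(self, elem: str) -> int:
        return self._counts[elem]

    def get(self, elem: str, default: int = 0) -> int:
        return self._counts.get(elem, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for elem, n in other.items():
            counts[elem] = counts.get(elem, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for elem, n in other.items():
            new = counts.get(elem, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction drives element {elem!r} negative ({counts.get(elem, 0)} - {n})"
                )
            counts[elem] = new
        return Formula(counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    def hill(self) -> str:
        """Hill-order string: C first, H second, remaining elements alphabetical."""
        parts = []
        for elem in ["C", "H"] + sorted(e for e in self._counts if e not in ("C", "H")):
            n = self._counts.get(elem, 0)
            if n:
                parts.append(f"{elem}{n if n > 1 else ''}")
        return "".join(parts) or ""

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a plain formula string like ``C39H54N10O14S``."""
        import re

        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if m.start() != pos or not m.group(0):
                break
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"unparseable formula at position {pos}: {text!r}")
        return cls(counts)


WATER = Formula({"H": 2, "O": 1})
CO = Formula({"C": 1, "O": 1})
AMMONIA = Formula({"N": 1, "H": 3})

# Residue (amino acid minus one water) formulas for the 20 standard residues.
RESIDUE_FORMULAS: dict[str, Formula] = {
    "G": Formula({"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": Formula({"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": Formula({"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": Formula({"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": Formula({"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": Formula({"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": Formula({"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": Formula({"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": Formula({"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": Formula({"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": Formula({"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": Formula({"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": Formula({"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": Formula({"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": Formula({"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": Formula({"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": Formula({"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": Formula({"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": Formula({"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": Formula({"C": 11, "H": 10, "N": 2, "O": 1}),
}

STANDARD_RESIDUES = frozenset(RESIDUE_FORMULAS)


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of a formula in Da (sum of count x element mass)."""
    total = 0.0
    for elem, n in formula.items():
        try:
            total += n * ELEMENT_MASS[elem]
        except KeyError:
            raise KeyError(f"unknown element symbol: {elem!r}") from None
    return total


# Residue masses derived once from the residue formulas; the two mass routes
# (residue-mass sum vs formula mass) therefore agree to float precision.
RESIDUE_MASSES: dict[str, float] = {
    aa: formula_mass(f) for aa, f in RESIDUE_FORMULAS.items()
}


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence over the 20-letter alphabet with linear or cyclic topology."""

    sequence: str
    topology: Topology = Topology.LINEAR

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        object.__setattr__(self, "topology", Topology(self.topology))
        for i, aa in enumerate(self.sequence):
            if aa not in STANDARD_RESIDUES:
                raise ValueError(
                    f"non-standard residue {aa!r} at position {i} in {self.sequence!r}"
                )
        if self.topology is Topology.CYCLIC and len(self.sequence) < 2:
            raise ValueError("cyclic topology requires length >= 2")

    @classmethod
    def cyclic(cls, sequence: str) -> "Peptide":
        return cls(sequence, Topology.CYCLIC)

    @classmethod
    def linear(cls, sequence: str) -> "Peptide":
        return cls(sequence, Topology.LINEAR)

    def __len__(self) -> int:
        return len(self.sequence)


def peptide_formula(peptide: Peptide) -> Formula:
    """Molecular formula of a peptide.

    Head-to-tail cyclic: element-wise sum of residue formulas.
    Linear: residue sum plus one water (the uncondensed termini).
    """
    total = Formula()
    for aa in peptide.sequence:
        total = total + RESIDUE_FORMULAS[aa]
    if peptide.topology is Topology.LINEAR:
        total = total + WATER
    return total


def peptide_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass in Da, computed by residue-mass summation."""
    total = sum(RESIDUE_MASSES[aa] for aa in peptide.sequence)
    if peptide.topology is Topology.LINEAR:
        total += formula_mass(WATER)
    return total


def mz_protonated(neutral_mass: float, charge: int = 1) -> float:
    """[M + z*H+]^z+ m/z using the proton mass (not the hydrogen-atom mass)."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def ppm_delta(measured: float, theoretical: float) -> float:
    """Signed relative deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical}")
    return (measured - theoretical) / theoretical * 1e6
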