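"""Theoretical MS/MS fragment enumeration for head-to-tail cyclic peptides.

A macrocycle fragments after ring opening: every amide cleavage yields one
rotation of the sequence, which then fragments like a linear peptide.  The
library therefore contains b/y ions for every contiguous arc of the cycle,
immonium ions for every distinct residue, NH3/H2O neutral-loss variants
gated on residue content, and precursor(-loss) ions.  Singly charged only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import (
    AMMONIA,
    CO,
    ELECTRON_MASS,
    ELEMENT_MASS,
    PROTON_MASS,
    RESIDUE_MASSES,
    STANDARD_RESIDUES,
    WATER,
    Peptide,
    Topology,
    formula_mass,
    mz_protonated,
    peptide_mass,
)

__all__ = [
    "ION_KINDS",
    "FragmentIon",
    "FragmentLibrary",
    "immonium_mz",
    "ring_openings",
    "by_series",
    "build_library",
]

NH3_MASS = formula_mass(AMMONIA)
H2O_MASS = formula_mass(WATER)

# Residues whose side chains commonly shed the respective neutral.
NH3_LOSS_RESIDUES = frozenset("KRNQ")
H2O_LOSS_RESIDUES = frozenset("STDE")

ION_KINDS = (
    "immonium",
    "b", "y", "b-NH3", "y-NH3", "b-H2O", "y-H2O",
    "precursor", "precursor-NH3", "precursor-H2O",
)


@dataclass(frozen=True)
class FragmentIon:
    kind: str
    subsequence: str
    mz: float
    label: str
    charge: int = 1

    def __post_init__(self):
        if self.kind not in ION_KINDS:
            raise ValueError(f"unknown ion kind {self.kind!r}")
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


def immonium_mz(residue: str) -> float:
    """m/z of the immonium (iminium) cation H2N+=CH-R of one residue.

    residue mass - CO + H - one electron.
    """
    if residue not in STANDARD_RESIDUES:
        raise ValueError(f"invalid residue {residue!r}")
    return RESIDUE_MASSES[residue] - formula_mass(CO) + ELEMENT_MASS["H"] - ELECTRON_MASS


def ring_openings(core: Peptide) -> list[str]:
    """The n linear forms of a cyclic peptide, one per ring-amide cleavage.

    Opening the bond after position i yields the rotation starting at i+1,
    so index 0 of the result is the rotation starting at position 1.
    """
    if core.topology is not Topology.CYCLIC:
        raise ValueError("ring_openings requires a cyclic peptide")
    s = core.sequence
    n = len(s)
    return [s[(i + 1) % n:] + s[: (i + 1) % n] for i in range(n)]


def _b_mz(arc: str) -> float:
    return sum(RESIDUE_MASSES[aa] for aa in arc) + PROTON_MASS


def _y_mz(arc: str) -> float:
    return sum(RESIDUE_MASSES[aa] for aa in arc) + H2O_MASS + PROTON_MASS


def by_series(linear: Peptide) -> list[FragmentIon]:
    """Singly charged b_i / y_i ions (i = 1..n-1) of a linear peptide."""
    if linear.topology is not Topology.LINEAR:
        raise ValueError("by_series requires a linear peptide")
    s = linear.sequence
    n = len(s)
    ions = []
    for i in range(1, n):
        b_arc, y_arc = s[:i], s[n - i:]
        ions.append(FragmentIon("b", b_arc, _b_mz(b_arc), f"b{i}({b_arc})"))
        ions.append(FragmentIon("y", y_arc, _y_mz(y_arc), f"y{i}({y_arc})"))
    return ions


@dataclass
class FragmentLibrary:
    """Deduplicated theoretical ion set for one cyclic core.

    ``provenance`` maps each retained ion label to the set of arc strings
    (across ring openings) that produced an ion with the same (kind,
    4-decimal m/z) key.
    """

    core: Peptide
    ions: list[FragmentIon] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    @property
    def precursor_mz(self) -> float:
        return mz_protonated(peptide_mass(self.core), 1)

    def find(self, kind: str, composition: str) -> FragmentIon:
        """Look up an ion by kind and residue composition (order-insensitive).

        Raises ``KeyError`` if no arc of that composition exists for the kind.
        """
        want = "".join(sorted(composition))
        for ion in self.ions:
            if ion.kind != kind:
                continue
            for arc in self.provenance[ion.label]:
                if "".join(sorted(arc)) == want:
                    return ion
        raise KeyError(f"no {kind} ion with composition {composition!r} in library")


def _arcs(core: Peptide) -> list[str]:
    """All distinct contiguous arcs (length 1..n-1) of the cycle."""
    s2 = core.sequence * 2
    n = len(core.sequence)
    seen: set[str] = set()
    out: list[str] = []
    for length in range(1, n):
        for start in range(n):
            arc = s2[start:start + length]
            if arc not in seen:
                seen.add(arc)
                out.append(arc)
    return out


def build_library(
    core: Peptide,
    losses: tuple[str, ...] = ("nh3", "h2o"),
) -> FragmentLibrary:
    """Enumerate the theoretical fragment library of a cyclic core.

    Ions are deduplicated on (kind, m/z rounded to 4 decimals); the first
    generating arc provides the label and all generating arcs are recorded
    in the provenance map.
    """
    if core.topology is not Topology.CYCLIC:
        raise ValueError("build_library requires a cyclic core")
    losses = tuple(l.lower() for l in losses)
    lib = FragmentLibrary(core)
    by_key: dict[tuple[str, float], FragmentIon] = {}

    def add(kind: str, arc: str, mz: float, label: str) -> None:
        key = (kind, round(mz, 4))
        if key in by_key:
            lib.provenance[by_key[key].label].add(arc)
        else:
            ion = FragmentIon(kind, arc, mz, label)
            by_key[key] = ion
            lib.provenance[label] = {arc}

    for residue in sorted(set(core.sequence)):
        add("immonium", residue, immonium_mz(residue), f"imm({residue})")

    for arc in _arcs(core):
        b, y = _b_mz(arc), _y_mz(arc)
        add("b", arc, b, f"b({arc})")
        add("y", arc, y, f"y({arc})")
        if "nh3" in losses and set(arc) & NH3_LOSS_RESIDUES:
            add("b-NH3", arc, b - NH3_MASS, f"b({arc})-NH3")
            add("y-NH3", arc, y - NH3_MASS, f"y({arc})-NH3")
        if "h2o" in losses and set(arc) & H2O_LOSS_RESIDUES:
            add("b-H2O", arc, b - H2O_MASS, f"b({arc})-H2O")
            add("y-H2O", arc, y - H2O_MASS, f"y({arc})-H2O")

    seq = core.sequence
    prec = lib.precursor_mz
    add("precursor", seq, prec, "[M+H]+")
    if "nh3" in losses and set(seq) & NH3_LOSS_RESIDUES:
        add("precursor-NH3", seq, prec - NH3_MASS, "[M+H]+-NH3")
    if "h2o" in losses and set(seq) & H2O_LOSS_RESIDUES:
        add("precursor-H2O", seq, prec - H2O_MASS, "[M+H]+-H2O")

    lib.ions = sorted(by_key.values(), key=lambda ion: (ion.mz, ion.kind))
    return lib
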