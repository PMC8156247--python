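"""Bundled reference dataset: the published MSDIN precursor census of a
basal lethal *Amanita* species, with per-copy FPKM values, pathway/housekeeping
gene FPKMs, the known-core catalogue, and the manually annotated fragment-ion
labels for the two novel 6-residue cycles (CylK1/CylK2).

These printed values serve as default inputs for the synthetic-data
generators and as ground truth for acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PrecursorRow",
    "REFERENCE_PRECURSORS",
    "REFERENCE_GENE_FPKM",
    "KNOWN_CORE_CATALOGUE",
    "MEASURED_MZ",
    "THEORETICAL_MZ",
    "CYLK1_PRESET",
    "CYLK2_PRESET",
    "FIG4_PRESETS",
    "reference_fpkm_records",
]


@dataclass(frozen=True)
class PrecursorRow:
    gene_id: str
    leader: str
    core: str
    follower: str
    fpkm: float
    note: str = ""

    @property
    def sequence(self) -> str:
        return self.leader + self.core + self.follower


# 21 precursor copies (leader | core | follower) with FPKM of the displayed
# transcriptome.  Copy structure: 3x IWGIGCNP, 2x FFIIFFIPP, 2x LIFLPPFIPP.
REFERENCE_PRECURSORS: tuple[PrecursorRow, ...] = (
    PrecursorRow("AMA1",     "MSDINATRLP", "IWGIGCNP",   "CVGDDVTTLLTRGEALC",  0.24, "alpha-amanitin"),
    PrecursorRow("AMA2-1",   "MSDINATRLA", "IWGIGCNP",   "CVGDDVTALLTRGEALC",  0.15, "alpha-amanitin"),
    PrecursorRow("AMA2-2",   "MSDINATRLA", "IWGIGCNP",   "CVGDDVTALLTRGEALC",  2.70, "alpha-amanitin"),
    PrecursorRow("AMA3",     "MSDINATRLA", "IWGIGCDP",   "CVGDDVTALLTRGEALC",  0.78, "beta-amanitin"),
    PrecursorRow("CYLK1",    "MSNINALRLP", "GFGFIP",     "YASGDVDYTLTRGESLS", 357.26, "CylK1"),
    PrecursorRow("CYLK2",    "MSDINATRFP", "GKVNPP",     "YVGDDVDDIIIRGEKLC", 113.45, "CylK2"),
    PrecursorRow("MSDIN07",  "MSNINASRLP", "IWAAFFRFP",  "CVGDEVDGILRSGESLC", 38.94),
    PrecursorRow("MSDIN08",  "MTDINATRLP", "FFWILIPP",   "CVDDVDNTVHSGDNLC",   4.63),
    PrecursorRow("MSDIN09",  "MSDINATRFP", "GKVFPP",     "YVGDDVDDIIIRGEK",    2.07),
    PrecursorRow("MSDIN10",  "MSNINATRFP", "GKLFPP",     "YVGDDVDDIIIRGDKLC",  0.93),
    PrecursorRow("MSDIN11",  "MSDINASRLP", "RLLVPRYP",   "CIDEDAEAILRSGECL",   0.90),
    PrecursorRow("MSDIN12",  "MTDINATRLP", "ILFGFFLLP",  "CVDGVDNTLHSGENLC",   0.66),
    PrecursorRow("MSDIN13",  "MSDINSIHLP", "GGYYQNT",    "FVGDDVEGILNRGERLC",  0.61),
    PrecursorRow("MSDIN14",  "MTDINATRLP", "LNILPFHLPP", "CVDDVDNTLHSGENLC",   0.29),
    PrecursorRow("MSDIN15a", "MTDINATRLP", "FFIIFFIPP",  "CVDDVDNTLHSGENLC",   0.25),
    PrecursorRow("MSDIN15b", "MTDINATRLP", "FFIIFFIPP",  "CVDDVDNTLHSGENLC",   0.00),
    PrecursorRow("MSDIN16",  "MTDINATRLP", "WIFFFYPP",   "CVDDVDNTLHSGENLC",   0.09),
    PrecursorRow("MSDIN17a", "MTDINATRLP", "LIFLPPFIPP", "CVDDVDNTLHSGENLC",   0.00),
    PrecursorRow("MSDIN17b", "MTDINATRLP", "LIFLPPFIPP", "CVDDVDNTLHSGENLC",   0.00),
    PrecursorRow("MSDIN18",  "MTDINATRLP", "WFFFFYPP",   "CVDDVDNTLHSGENLC",   0.00),
    PrecursorRow("MSDIN19",  "MTDINATRLP", "FNILPLLLPP", "CVDDVDNTLHSGENLC",   0.00),
)

# Pathway (POPB) and housekeeping (POPA, rbp2) gene FPKMs.
REFERENCE_GENE_FPKM: dict[str, float] = {
    "POPB": 178.43,
    "POPA": 6.99,
    "rbp2": 46.96,
}

# Cores with previously characterized products.
KNOWN_CORE_CATALOGUE: dict[str, str] = {
    "IWGIGCNP": "alpha-amanitin",
    "IWGIGCDP": "beta-amanitin",
    "LNILPFHLPP": "previously-reported",
}

# Measured [M+H]+ of the four detected cyclic peptides.
MEASURED_MZ: dict[str, float] = {
    "IWGIGCNP+amatoxin": 919.3616,
    "IWGIGCDP+amatoxin": 920.3465,
    "GFGFIP": 619.3244,
    "GKVNPP": 593.3411,
}

# Printed theoretical [M+H]+ per candidate (amatoxin state for the two
# W/C-bearing cores, bare macrocycle otherwise), at printed precision.
THEORETICAL_MZ: dict[str, float] = {
    "IWGIGCNP+amatoxin": 919.3614,
    "IWGIGCDP+amatoxin": 920.3455,
    "GFGFIP": 619.3239,
    "GKVNPP": 593.3406,
    "IWAAFFRFP": 1136.604,
    "GGYYQNT": 784.326,
    "RLLVPRYP": 995.6149,
    "LNILPFHLPP": 1142.6721,
    "LIFLPPFIPP": 1135.6914,
    "FFWILIPP": 1014.5811,
    "FFIIFFIPP": 1122.6387,
    "WIFFFYPP": 1098.5448,
    "GKVFPP": 626.3661,
    "GKLFPP": 640.3817,
    "ILFGFFLLP": 1048.623,
    "WFFFFYPP": 1132.5291,
    "FNILPLLLPP": 1118.6972,
}

# Manually annotated daughter ions of the two novel cycles, expressed as
# (kind, residue-composition) requests against the fragment library.
# CylK1 cyclo(GFGFIP): Ile and Phe immonium ions plus y-type arcs.  The
# published "GGI" label is not a contiguous arc of the cycle and is read
# here as the arc IPG (single-letter transposition).
CYLK1_PRESET: tuple[tuple[str, str], ...] = (
    ("immonium", "I"),
    ("immonium", "F"),
    ("y", "GP"),
    ("y", "GF"),
    ("y", "GIP"),   # published label "GGI", see note above
    ("y", "GFP"),
    ("y", "GFGIP"),
    ("y", "GFFIP"),
    ("y", "GGFFP"),
)
# CylK2 cyclo(GKVNPP): Pro immonium, seven y-type arcs, and NH3 loss on the
# three Lys-bearing arcs.  The published "KPP" label is not a contiguous arc
# of the cycle and is read here as the arc NPP (single-letter substitution).
CYLK2_PRESET: tuple[tuple[str, str], ...] = (
    ("immonium", "P"),
    ("y", "GP"),
    ("y", "GK"),
    ("y", "GKP"),
    ("y", "NPP"),   # published label "KPP", see note above
    ("y", "GNPP"),
    ("y", "GKPP"),
    ("y", "GKNPP"),
    ("y-NH3", "GK"),
    ("y-NH3", "GKP"),
    ("y-NH3", "GKPP"),
)

FIG4_PRESETS: dict[str, tuple[tuple[str, str], ...]] = {
    "GFGFIP": CYLK1_PRESET,
    "GKVNPP": CYLK2_PRESET,
}


def reference_fpkm_records() -> list[tuple[str, str, float]]:
    """The reference expression table as (gene_id, class, fpkm) rows.

    MSDIN rows carry their core peptide as the class; pathway/housekeeping
    rows carry their gene symbol.  24 rows total.
    """
    rows = [(p.gene_id, p.core, p.fpkm) for p in REFERENCE_PRECURSORS]
    rows += [(g, g, v) for g, v in REFERENCE_GENE_FPKM.items()]
    return rows
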