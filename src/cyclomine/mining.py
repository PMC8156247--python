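"""Motif-based mining of tripartite precursor peptides (leader/core/follower).

The precursor family is defined by a 10-residue position-specific leader
pattern anchored at Met, a 3-residue follower-start pattern, and length
ranges for core (5-12), follower (15-17, measured to the first stop codon or
sequence end) and whole precursor (30-40).  Stop codons terminate candidate
windows, so mining works directly on six-frame translations of nucleotide
input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "PrecursorModel",
    "DEFAULT_MODEL",
    "MsdinPrecursor",
    "MsdinCensus",
    "translate_six_frames",
    "find_msdin_precursors",
    "mine_nucleotides",
    "deduplicate",
    "classify_cores",
    "DEFAULT_CATALOGUE",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = frozenset("ACGTN")


def _pattern(spec: str) -> tuple[frozenset[str], ...]:
    """Parse 'M,[S|T],[D|N],...' into a tuple of allowed-residue sets."""
    sets = []
    for token in spec.split(","):
        token = token.strip().strip("[]")
        sets.append(frozenset(token.split("|")))
    return tuple(sets)


@dataclass(frozen=True)
class PrecursorModel:
    """Position-specific search model for tripartite precursors."""

    leader_pattern: tuple[frozenset[str], ...] = _pattern(
        "M,[S|T],[D|N],I,N,[A|S],[T|L|S|I],[R|H],[L|F],[P|A]"
    )
    follower_start_pattern: tuple[frozenset[str], ...] = _pattern(
        "[C|Y|F],[V|I|A],[G|S|D|A]"
    )
    core_length_range: tuple[int, int] = (5, 12)
    follower_length_range: tuple[int, int] = (15, 17)
    precursor_length_range: tuple[int, int] = (30, 40)

    @property
    def leader_length(self) -> int:
        return len(self.leader_pattern)

    @classmethod
    def from_config(cls, cfg: dict) -> "PrecursorModel":
        kwargs = {}
        if "leader_pattern" in cfg:
            kwargs["leader_pattern"] = _pattern(cfg["leader_pattern"])
        if "follower_start_pattern" in cfg:
            kwargs["follower_start_pattern"] = _pattern(cfg["follower_start_pattern"])
        for key in ("core_length_range", "follower_length_range", "precursor_length_range"):
            if key in cfg:
                kwargs[key] = tuple(cfg[key])
        return cls(**kwargs)


DEFAULT_MODEL = PrecursorModel()

DEFAULT_CATALOGUE: dict[str, str] = {
    "IWGIGCNP": "alpha-amanitin",
    "IWGIGCDP": "beta-amanitin",
    "LNILPFHLPP": "previously-reported",
}


@dataclass(frozen=True)
class MsdinPrecursor:
    """One mined precursor: 0-based half-open protein coordinates plus the
    leader/core/follower decomposition; frame/strand and forward-strand
    nucleotide coordinates are set when mined from nucleotide input."""

    source_id: str
    start: int
    end: int
    leader: str
    core: str
    follower: str
    frame: int | None = None  # +1..+3 / -1..-3
    nt_start: int | None = None
    nt_end: int | None = None

    @property
    def sequence(self) -> str:
        return self.leader + self.core + self.follower

    @property
    def strand(self) -> str | None:
        if self.frame is None:
            return None
        return "+" if self.frame > 0 else "-"


@dataclass
class MsdinCensus:
    precursors: list[MsdinPrecursor]
    key: str = "core"
    groups: dict[str, list[MsdinPrecursor]] = field(default_factory=dict)
    unique_cores: set[str] = field(default_factory=set)
    novel_cores: set[str] = field(default_factory=set)
    catalogue: dict[str, str] = field(default_factory=dict)

    @property
    def n_precursors(self) -> int:
        return len(self.precursors)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _match(seq: str, pos: int, pattern: tuple[frozenset[str], ...]) -> bool:
    if pos + len(pattern) > len(seq):
        return False
    return all(seq[pos + i] in allowed for i, allowed in enumerate(pattern))


def translate_six_frames(dna: str) -> dict[int, str]:
    """Translate all six reading frames, keyed +1..+3 and -1..-3.

    Negative frame k is frame +k of the reverse complement.  Stop codons are
    rendered '*'; trailing partial codons are dropped.
    """
    dna = dna.upper()
    for i, base in enumerate(dna):
        if base not in NUCLEOTIDES:
            raise ValueError(f"invalid nucleotide {base!r} at position {i}")
    frames: dict[int, str] = {}
    rc = str(Seq(dna).reverse_complement())
    for k in (1, 2, 3):
        for sign, strand_seq in ((1, dna), (-1, rc)):
            sub = strand_seq[k - 1:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sign * k] = str(Seq(sub).translate())
    return frames


def _scan_protein(source_id: str, seq: str, model: PrecursorModel) -> list[MsdinPrecursor]:
    hits: list[MsdinPrecursor] = []
    core_min, core_max = model.core_length_range
    fol_min, fol_max = model.follower_length_range
    pre_min, pre_max = model.precursor_length_range
    llen = model.leader_length

    # Stop codons bound candidate windows: work segment by segment.
    seg_start = 0
    for segment in seq.split("*"):
        seg_end = seg_start + len(segment)
        for i in range(len(segment)):
            if segment[i] != "M" or not _match(segment, i, model.leader_pattern):
                continue
            window_end = len(segment)
            # Leftmost follower start whose implied follower length is in range
            # and that leaves a core of admissible length.
            chosen = None
            for j in range(i + llen + core_min, window_end):
                follower_len = window_end - j
                if follower_len < fol_min:
                    break
                core_len = j - (i + llen)
                if core_len > core_max:
                    break
                if follower_len > fol_max:
                    continue
                if _match(segment, j, model.follower_start_pattern):
                    chosen = j
                    break
            if chosen is None:
                logger.debug(
                    "leader match at %s:%d skipped: no admissible follower boundary",
                    source_id, seg_start + i,
                )
                continue
            total = window_end - i
            if not (pre_min <= total <= pre_max):
                logger.debug(
                    "leader match at %s:%d skipped: precursor length %d out of range",
                    source_id, seg_start + i, total,
                )
                continue
            hits.append(
                MsdinPrecursor(
                    source_id=source_id,
                    start=seg_start + i,
                    end=seg_start + window_end,
                    leader=segment[i:i + llen],
                    core=segment[i + llen:chosen],
                    follower=segment[chosen:window_end],
                )
            )
        seg_start = seg_end + 1  # skip the '*'
    return hits


def find_msdin_precursors(
    proteins: list[tuple[str, str]],
    model: PrecursorModel = DEFAULT_MODEL,
) -> list[MsdinPrecursor]:
    """Scan (id, protein sequence) pairs for precursor windows.

    Output is sorted (source_id, start) regardless of input order.
    """
    hits: list[MsdinPrecursor] = []
    for source_id, seq in proteins:
        seq = seq.upper()
        bad = set(seq) - AMINO_ACIDS - {"*", "X"}
        if bad:
            raise ValueError(
                f"sequence {source_id!r} contains invalid residue(s): {sorted(bad)}"
            )
        hits.extend(_scan_protein(source_id, seq, model))
    hits.sort(key=lambda h: (h.source_id, h.start))
    return hits


def mine_nucleotides(
    contigs: list[tuple[str, str]],
    model: PrecursorModel = DEFAULT_MODEL,
) -> list[MsdinPrecursor]:
    """Six-frame translate contigs and mine each frame; hits carry frame and
    forward-strand 0-based half-open nucleotide coordinates."""
    hits: list[MsdinPrecursor] = []
    for contig_id, dna in contigs:
        length = len(dna)
        for frame, protein in translate_six_frames(dna).items():
            offset = abs(frame) - 1
            for h in _scan_protein(contig_id, protein, model):
                nt_a = offset + 3 * h.start
                nt_b = offset + 3 * h.end
                if frame > 0:
                    nt_start, nt_end = nt_a, nt_b
                else:
                    nt_start, nt_end = length - nt_b, length - nt_a
                hits.append(replace(h, frame=frame, nt_start=nt_start, nt_end=nt_end))
    hits.sort(key=lambda h: (h.source_id, h.nt_start, h.frame))
    return hits


def deduplicate(hits: list[MsdinPrecursor], key: str = "core") -> MsdinCensus:
    """Group hits by core peptide or by full precursor sequence."""
    if key not in ("core", "full_sequence"):
        raise ValueError(f"key must be 'core' or 'full_sequence', got {key!r}")
    groups: dict[str, list[MsdinPrecursor]] = {}
    for h in hits:
        k = h.core if key == "core" else h.sequence
        groups.setdefault(k, []).append(h)
    return MsdinCensus(
        precursors=list(hits),
        key=key,
        groups=groups,
        unique_cores={h.core for h in hits},
    )


def classify_cores(
    census: MsdinCensus,
    catalogue: dict[str, str] | None = None,
) -> MsdinCensus:
    """Mark cores absent from the known-core catalogue as novel."""
    if catalogue is None:
        catalogue = DEFAULT_CATALOGUE
    census.catalogue = dict(catalogue)
    census.novel_cores = census.unique_cores - set(catalogue)
    return census
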