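"""FPKM table loading, expression-tier classification and summary statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

from .mining import MsdinCensus

__all__ = [
    "ExpressionRecord",
    "Tier",
    "TierScheme",
    "DEFAULT_SCHEME",
    "load_expression_table",
    "tier_classify",
    "expression_ratio",
    "census_expression_join",
]


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    gene_class: str  # core peptide sequence, or a gene symbol (POPB, POPA, rbp2, ...)
    fpkm: float

    def __post_init__(self):
        if self.fpkm < 0:
            raise ValueError(f"{self.gene_id}: FPKM must be >= 0, got {self.fpkm}")


@dataclass(frozen=True)
class Tier:
    """Half-open-ish tier [lower, upper] with configurable bound inclusion."""

    label: str
    lower: float
    upper: float  # use inf for the top tier
    include_lower: bool = False
    include_upper: bool = False

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.include_lower and value == self.lower)
        below = value < self.upper or (self.include_upper and value == self.upper)
        return above and below


@dataclass(frozen=True)
class TierScheme:
    """An ordered, disjoint partition of [0, inf)."""

    tiers: tuple[Tier, ...]

    def classify(self, value: float) -> str:
        for tier in self.tiers:
            if tier.contains(value):
                return tier.label
        raise ValueError(f"value {value} falls in no tier")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tiers)


# zero [=0], low (0,1), mid [1,100], high (100, inf)
DEFAULT_SCHEME = TierScheme((
    Tier("zero", 0.0, 0.0, include_lower=True, include_upper=True),
    Tier("low", 0.0, 1.0),
    Tier("mid", 1.0, 100.0, include_lower=True, include_upper=True),
    Tier("high", 100.0, float("inf")),
))


def load_expression_table(path) -> list[ExpressionRecord]:
    """Read a TSV with header gene_id, class, fpkm; duplicate ids rejected."""
    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:3]] != ["gene_id", "class", "fpkm"]:
            raise ValueError(f"expected header 'gene_id<TAB>class<TAB>fpkm', got {header!r}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
            gene_id, gene_class = fields[0].strip(), fields[1].strip()
            try:
                fpkm = float(fields[2])
            except ValueError:
                raise ValueError(f"line {lineno}: unparseable FPKM {fields[2]!r}") from None
            if fpkm < 0:
                raise ValueError(f"line {lineno}: negative FPKM {fpkm}")
            if gene_id in seen:
                raise ValueError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            records.append(ExpressionRecord(gene_id, gene_class, fpkm))
    return records


def tier_classify(
    records: list[ExpressionRecord],
    scheme: TierScheme = DEFAULT_SCHEME,
) -> dict[str, list[ExpressionRecord]]:
    """Partition records into tiers; every record lands in exactly one tier."""
    out: dict[str, list[ExpressionRecord]] = {label: [] for label in scheme.labels}
    for record in records:
        out[scheme.classify(record.fpkm)].append(record)
    return out


def expression_ratio(
    records: list[ExpressionRecord],
    numerator_class: str,
    denominator_class: str,
) -> float:
    """Ratio of FPKM values between two gene classes (single record each)."""

    def pick(cls: str) -> float:
        vals = [r.fpkm for r in records if r.gene_class == cls]
        if not vals:
            raise ValueError(f"class {cls!r} not present in expression table")
        return sum(vals) / len(vals)

    denom = pick(denominator_class)
    if denom == 0:
        raise ZeroDivisionError(f"denominator class {denominator_class!r} has FPKM 0")
    return pick(numerator_class) / denom


def census_expression_join(
    census: MsdinCensus,
    records: list[ExpressionRecord],
    scheme: TierScheme = DEFAULT_SCHEME,
) -> dict:
    """Join a precursor census with expression records keyed by core peptide.

    Duplicate-copy genes are summarized by per-core maximum FPKM (per-copy
    values retained).  Returns per-core rows plus min/max summary over cores
    with expression evidence.
    """
    by_core: dict[str, list[float]] = {}
    for r in records:
        if r.gene_class in census.unique_cores:
            by_core.setdefault(r.gene_class, []).append(r.fpkm)

    rows = []
    for core in sorted(census.unique_cores):
        fpkms = by_core.get(core)
        rows.append({
            "core": core,
            "n_copies": len(census.groups.get(core, [])) if census.key == "core" else None,
            "fpkm_values": fpkms,
            "max_fpkm": max(fpkms) if fpkms else None,
            "tier": scheme.classify(max(fpkms)) if fpkms else "unknown",
            "status": census.catalogue.get(core, "novel" if core in census.novel_cores else "known"),
        })
    with_data = [r["max_fpkm"] for r in rows if r["max_fpkm"] is not None]
    all_values = [v for vals in by_core.values() for v in vals]
    return {
        "rows": rows,
        "fpkm_min": min(all_values) if all_values else None,
        "fpkm_max": max(all_values) if all_values else None,
        "n_cores_with_data": len(with_data),
    }
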