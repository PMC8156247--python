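"""Post-translational modification templates for macrocyclic cores.

A template is an ordered list of named formula deltas, each guarded by a
required-residue predicate on the core sequence.  The built-in ``amatoxin``
template carries the net +5 O, -2 H state (Trp-Cys cross-bridge -2 H, four
hydroxylations +4 O, one sulfoxide +1 O).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .chem import (
    Formula,
    Peptide,
    Topology,
    formula_mass,
    mz_protonated,
    peptide_formula,
)

__all__ = [
    "ModificationDelta",
    "ToxinTemplate",
    "CyclicPeptideCandidate",
    "AMATOXIN_TEMPLATE",
    "PHALLOTOXIN_TEMPLATE",
    "BUILTIN_TEMPLATES",
    "apply_template",
    "candidate_mass_list",
    "load_templates",
]


@dataclass(frozen=True)
class ModificationDelta:
    """A named signed element-count delta with a required-residue guard."""

    name: str
    delta: tuple[tuple[str, int], ...]  # signed element counts, e.g. (("O", 1),)
    required_residues: frozenset[str] = frozenset()

    def check(self, sequence: str) -> None:
        missing = sorted(r for r in self.required_residues if r not in sequence)
        if missing:
            raise ValueError(
                f"modification {self.name!r} requires residue(s) "
                f"{','.join(missing)} absent from core {sequence!r}"
            )

    def gains(self) -> Formula:
        return Formula({e: n for e, n in self.delta if n > 0})

    def losses(self) -> Formula:
        return Formula({e: -n for e, n in self.delta if n < 0})

    @property
    def mass(self) -> float:
        return formula_mass(self.gains()) - formula_mass(self.losses())


@dataclass(frozen=True)
class ToxinTemplate:
    name: str
    deltas: tuple[ModificationDelta, ...] = ()
    enabled: bool = True

    @property
    def net_mass(self) -> float:
        return sum(d.mass for d in self.deltas)


def _delta(name, delta, req=()):
    return ModificationDelta(name, tuple(delta.items()), frozenset(req))


AMATOXIN_TEMPLATE = ToxinTemplate(
    "amatoxin",
    (
        _delta("tryptathionine", {"H": -2}, req="WC"),
        _delta("hydroxylation-x4", {"O": 4}),
        _delta("sulfoxide", {"O": 1}, req="C"),
    ),
)

# Configuration stub only: disabled by default.
PHALLOTOXIN_TEMPLATE = ToxinTemplate(
    "phallotoxin",
    (
        _delta("tryptathionine", {"H": -2}, req="WC"),
        _delta("hydroxylation-x3", {"O": 3}),
    ),
    enabled=False,
)

BUILTIN_TEMPLATES: dict[str, ToxinTemplate] = {
    t.name: t for t in (AMATOXIN_TEMPLATE, PHALLOTOXIN_TEMPLATE)
}


def apply_template(core: Peptide, template: ToxinTemplate) -> Formula:
    """Formula of a cyclic core after applying every delta of a template.

    Raises if the core is not cyclic, a delta's residue requirement fails,
    or a loss would drive an element count negative.
    """
    if core.topology is not Topology.CYCLIC:
        raise ValueError("modification templates apply to cyclic cores only")
    formula = peptide_formula(core)
    for d in template.deltas:
        d.check(core.sequence)
        formula = (formula + d.gains()) - d.losses()
    return formula


@dataclass(frozen=True)
class CyclicPeptideCandidate:
    """A macrocyclized core with a modification state and derived mass values."""

    core: str
    modification: str | None  # template name, or None for the bare cycle
    formula: Formula
    neutral_mass: float
    mz: float  # [M+H]+

    @property
    def name(self) -> str:
        return self.core if self.modification is None else f"{self.core}+{self.modification}"


def _candidate(core: str, template: ToxinTemplate | None) -> CyclicPeptideCandidate:
    pep = Peptide.cyclic(core)
    if template is None:
        formula = peptide_formula(pep)
        modification = None
    else:
        formula = apply_template(pep, template)
        modification = template.name
    mass = formula_mass(formula)
    return CyclicPeptideCandidate(core, modification, formula, mass, mz_protonated(mass, 1))


def candidate_mass_list(
    cores: list[str],
    templates: dict[str, ToxinTemplate] | None = None,
) -> list[CyclicPeptideCandidate]:
    """Expand cores into cyclic candidates with and without modification states.

    Every core yields its unmodified head-to-tail cycle.  For each enabled
    template whose residue requirements are met (the amatoxin template needs
    both W and C), a modified candidate is appended as well.
    """
    if templates is None:
        templates = BUILTIN_TEMPLATES
    out: list[CyclicPeptideCandidate] = []
    for core in cores:
        out.append(_candidate(core, None))
        for template in templates.values():
            if not template.enabled:
                continue
            required = frozenset().union(*(d.required_residues for d in template.deltas)) \
                if template.deltas else frozenset()
            if all(r in core for r in required):
                out.append(_candidate(core, template))
    return out


def load_templates(path) -> dict[str, ToxinTemplate]:
    """Load templates from YAML: list of {name, deltas:[{name, delta, requires}], enabled}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or []
    templates: dict[str, ToxinTemplate] = {}
    for entry in doc:
        deltas = tuple(
            _delta(d["name"], dict(d.get("delta", {})), d.get("requires", ""))
            for d in entry.get("deltas", [])
        )
        t = ToxinTemplate(entry["name"], deltas, bool(entry.get("enabled", True)))
        templates[t.name] = t
    return templates
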