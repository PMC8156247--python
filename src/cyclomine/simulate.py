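"""Seeded generators for every fixture the pipeline needs: decoy proteomes
with embedded precursors, intronless nucleotide contigs, synthetic MGF
spectra, and FPKM tables.  Every generator is byte-deterministic under its
seed and ships machine-readable ground truth."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import Peptide, mz_protonated, peptide_mass
from .fragments import FragmentLibrary, build_library
from .matching import Spectrum, write_mgf
from .refdata import FIG4_PRESETS, REFERENCE_PRECURSORS, reference_fpkm_records

__all__ = [
    "SimConfig",
    "make_proteome",
    "make_contigs",
    "make_spectra",
    "make_fpkm_table",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# One fixed codon per residue (plus stop) for deterministic back-translation.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "*": "TAA",
}


@dataclass
class SimConfig:
    seed: int = 0
    n_decoy_proteins: int = 50
    decoy_length_range: tuple[int, int] = (80, 300)
    embedded_precursors: tuple[str, ...] = tuple(
        p.sequence for p in REFERENCE_PRECURSORS
    )
    spectrum_jitter_ppm: float = 0.0
    n_noise_peaks: int = 20
    noise_mz_range: tuple[float, float] = (500.0, 1700.0)
    gc_range: tuple[float, float] = (0.4, 0.6)

    def __post_init__(self):
        if self.spectrum_jitter_ppm < 0:
            raise ValueError("jitter sigma must be >= 0")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def make_proteome(config: SimConfig, out_dir) -> tuple[Path, dict]:
    """Decoy proteins of uniform residue composition; each embedded precursor
    is inserted at a recorded position followed by a stop ('*'), mirroring
    the translated-ORF input the miner expects.

    Returns (fasta path, ground truth dict).
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = config.decoy_length_range

    proteins: list[tuple[str, str]] = [
        (f"decoy_{i:04d}", _random_protein(rng, int(rng.integers(lo, hi + 1))))
        for i in range(config.n_decoy_proteins)
    ]

    truth: dict = {"embedded": []}
    if config.embedded_precursors:
        if len(proteins) < len(config.embedded_precursors):
            raise ValueError(
                "need at least one decoy host per embedded precursor "
                f"({len(proteins)} < {len(config.embedded_precursors)})"
            )
        # one precursor per host so embeddings cannot clobber each other
        hosts = rng.permutation(len(proteins))[: len(config.embedded_precursors)]
        for precursor, host_idx in zip(config.embedded_precursors, hosts):
            host_id, host_seq = proteins[host_idx]
            insert = precursor + "*"
            if len(insert) > len(host_seq):
                raise ValueError(
                    f"precursor ({len(precursor)} aa) longer than host {host_id}"
                )
            pos = int(rng.integers(0, len(host_seq) - len(insert) + 1))
            host_seq = host_seq[:pos] + insert + host_seq[pos + len(insert):]
            proteins[host_idx] = (host_id, host_seq)
            truth["embedded"].append({
                "source_id": host_id,
                "start": pos,
                "end": pos + len(precursor),
                "sequence": precursor,
            })

    fasta = out_dir / "proteome.fasta"
    with open(fasta, "w") as fh:
        for pid, seq in proteins:
            fh.write(f">{pid}\n{seq}\n")
    truth_path = out_dir / "proteome.truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return fasta, truth


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _revcomp(dna: str) -> str:
    return dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_contigs(config: SimConfig, out_dir) -> tuple[Path, dict]:
    """Random-background contigs with each precursor codon-encoded intronless
    on a random strand; ground truth records strand, frame and forward-strand
    0-based coordinates."""
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gc = float(rng.uniform(*config.gc_range))

    contigs: list[tuple[str, str]] = []
    truth: dict = {"embedded": [], "gc": gc}
    for i, precursor in enumerate(config.embedded_precursors):
        cds = "".join(_CODON[aa] for aa in precursor) + _CODON["*"]
        left = int(rng.integers(60, 200))
        right = int(rng.integers(60, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = cds if strand == "+" else _revcomp(cds)
        seq = _random_dna(rng, left, gc) + insert + _random_dna(rng, right, gc)
        cid = f"contig_{i:03d}"
        contigs.append((cid, seq))
        if strand == "+":
            nt_start, nt_end = left, left + 3 * len(precursor)
        else:
            nt_start, nt_end = left + 3, left + 3 + 3 * len(precursor)
        truth["embedded"].append({
            "source_id": cid,
            "strand": strand,
            "nt_start": nt_start,
            "nt_end": nt_end,
            "sequence": precursor,
        })

    fasta = out_dir / "contigs.fasta"
    with open(fasta, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n{seq}\n")
    (out_dir / "contigs.truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return fasta, truth


def _jitter(rng: np.random.Generator, mz: float, sigma_ppm: float) -> float:
    if sigma_ppm == 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6)


def spectrum_for_core(
    core: str,
    rng: np.random.Generator,
    config: SimConfig,
    ion_requests: tuple[tuple[str, str], ...] | None = None,
) -> tuple[Spectrum, dict]:
    """One synthetic spectrum for a cyclic core.

    ``ion_requests`` selects library ions by (kind, residue composition);
    None means the full library.  Unknown requests raise ``KeyError``.
    True-ion intensities are uniform [0.2, 1.0], noise uniform [0, 0.1].
    """
    library: FragmentLibrary = build_library(Peptide.cyclic(core))
    if ion_requests is None:
        ions = list(library.ions)
    else:
        ions = [library.find(kind, comp) for kind, comp in ion_requests]

    peaks = [
        (_jitter(rng, ion.mz, config.spectrum_jitter_ppm), float(rng.uniform(0.2, 1.0)))
        for ion in ions
    ]
    lo, hi = config.noise_mz_range
    peaks += [
        (float(rng.uniform(lo, hi)), float(rng.uniform(0.0, 0.1)))
        for _ in range(config.n_noise_peaks)
    ]
    precursor = _jitter(rng, mz_protonated(peptide_mass(Peptide.cyclic(core))),
                        config.spectrum_jitter_ppm)
    spectrum = Spectrum(id=f"sim_{core}", precursor_mz=precursor, peaks=peaks)
    truth = {
        "core": core,
        "true_ions": [{"kind": i.kind, "label": i.label, "mz": i.mz} for i in ions],
        "n_true_ions": len(ions),
        "n_noise_peaks": config.n_noise_peaks,
    }
    return spectrum, truth


def make_spectra(
    cores: list[str],
    config: SimConfig,
    out_dir,
    use_presets: bool = True,
) -> tuple[Path, dict]:
    """One MGF spectrum per core.  With ``use_presets``, cores that have a
    published manual annotation (the two novel 6-mers) emit exactly those
    daughter ions; all other cores emit their full library."""
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    spectra, truth = [], {"spectra": []}
    for core in cores:
        requests = FIG4_PRESETS.get(core) if use_presets else None
        spectrum, t = spectrum_for_core(core, rng, config, requests)
        spectra.append(spectrum)
        truth["spectra"].append(t)

    mgf = out_dir / "spectra.mgf"
    write_mgf(spectra, mgf)
    (out_dir / "spectra.truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return mgf, truth


def make_fpkm_table(
    out_dir,
    rows: list[tuple[str, str, float]] | None = None,
) -> tuple[Path, dict]:
    """Write an expression TSV; default rows are the bundled reference table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if rows is None:
        rows = reference_fpkm_records()
    path = out_dir / "fpkm.tsv"
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\tfpkm\n")
        for gene_id, gene_class, fpkm in rows:
            fh.write(f"{gene_id}\t{gene_class}\t{fpkm:.2f}\n")
    truth = {"rows": [list(r) for r in rows]}
    (out_dir / "fpkm.truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return path, truth
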