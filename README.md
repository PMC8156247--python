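# cyclomine

Genome-guided discovery toolkit for macrocyclic RiPP peptides of the MSDIN
family: mine tripartite precursor peptides (10-aa leader / 5–12-aa core /
15–17-aa follower) from protein or nucleotide sequences, predict monoisotopic
masses and molecular formulas of the head-to-tail macrocyclized cores
(including the amatoxin modification state, net +5 O / −2 H), enumerate
theoretical MS/MS fragment ions (immonium, b/y arcs of ring-opened cycles,
NH₃/H₂O neutral losses), match and annotate spectra within ppm tolerances,
and classify gene expression into FPKM tiers.

A published precursor census (21 precursor copies, 17 unique cores, FPKM
values, known-core catalogue, manually annotated daughter ions of the two
novel 6-residue cycles CylK1/CylK2) is bundled in `cyclomine.refdata` and
drives the default fixtures and acceptance checks.

## CLI

```sh
# formula / neutral mass / [M+H]+ of a macrocycle
cyclomine mass GFGFIP                       # -> C33H42N6O6, 619.3239

# mine precursors from protein or nucleotide FASTA (auto-detected)
cyclomine mine --input proteome.fasta --out hits.tsv --cores-fasta cores.fasta

# theoretical fragment library of a cyclic core
cyclomine fragments --core GKVNPP --losses nh3,h2o --out lib.tsv

# precursor screening + MS/MS annotation against MGF spectra
cyclomine match --spectra spectra.mgf --cores cores.fasta \
    --tol-ppm 5 --frag-tol-ppm 10 --out report.tsv

# FPKM tier summary (zero / <1 / 1–100 / >100)
cyclomine expr --table fpkm.tsv

# seeded synthetic fixtures with ground truth
cyclomine simulate proteome --seed 1 --out sim/
cyclomine simulate spectra  --seed 1 --out sim/
```

## Library layout

| module                  | purpose |
|-------------------------|---------|
| `cyclomine.chem`        | element/residue mass tables, `Formula`, peptide mass/formula, [M+H]⁺, ppm |
| `cyclomine.ptm`         | modification templates (`amatoxin` built in), candidate expansion |
| `cyclomine.mining`      | six-frame translation, precursor motif scan, census, known/novel classification |
| `cyclomine.fragments`   | ring openings, b/y series, immonium ions, neutral-loss variants, dedup library |
| `cyclomine.matching`    | MGF/peak-list IO, precursor screening, fragment annotation, report writer |
| `cyclomine.expression`  | FPKM table loading, tier schemes, ratios, census join |
| `cyclomine.simulate`    | seeded generators: decoy proteomes, contigs, MGF spectra, FPKM tables |
| `cyclomine.refdata`     | bundled published reference dataset |

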