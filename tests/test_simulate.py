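import json

import numpy as np
import pytest

from cyclomine.chem import Peptide
from cyclomine.fragments import build_library
from cyclomine.matching import annotate_fragments, read_mgf, screen_precursors
from cyclomine.mining import find_msdin_precursors, mine_nucleotides
from cyclomine.ptm import candidate_mass_list
from cyclomine.simulate import (
    SimConfig,
    make_contigs,
    make_fpkm_table,
    make_proteome,
    make_spectra,
)


def read_fasta(path):
    records, name, chunks = [], None, []
    for line in open(path):
        line = line.strip()
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name, chunks = line[1:], []
        elif line:
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


class TestMakeProteome:
    def test_embedded_precursors_all_recovered(self, tmp_path):
        cfg = SimConfig(seed=3, n_decoy_proteins=40)
        fasta, truth = make_proteome(cfg, tmp_path)
        hits = find_msdin_precursors(read_fasta(fasta))
        assert len(hits) == 21
        embedded = {(e["source_id"], e["start"]): e for e in truth["embedded"]}
        for h in hits:
            e = embedded[(h.source_id, h.start)]
            assert h.sequence == e["sequence"] and h.end == e["end"]

    def test_no_embeddings_no_hits(self, tmp_path):
        cfg = SimConfig(seed=5, n_decoy_proteins=60, embedded_precursors=())
        fasta, truth = make_proteome(cfg, tmp_path)
        assert truth["embedded"] == []
        assert find_msdin_precursors(read_fasta(fasta)) == []

    def test_byte_determinism(self, tmp_path):
        a, _ = make_proteome(SimConfig(seed=9), tmp_path / "a")
        b, _ = make_proteome(SimConfig(seed=9), tmp_path / "b")
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_same_decompositions(self, tmp_path):
        _, ta = make_proteome(SimConfig(seed=1), tmp_path / "a")
        _, tb = make_proteome(SimConfig(seed=2), tmp_path / "b")
        assert {e["sequence"] for e in ta["embedded"]} == {e["sequence"] for e in tb["embedded"]}

    def test_ground_truth_serialized(self, tmp_path):
        make_proteome(SimConfig(seed=0), tmp_path)
        truth = json.loads((tmp_path / "proteome.truth.json").read_text())
        assert len(truth["embedded"]) == 21

    def test_twenty_seed_recovery_with_zero_decoy_hits(self, tmp_path):
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_decoy_proteins=30)
            fasta, truth = make_proteome(cfg, tmp_path / f"s{seed}")
            hits = find_msdin_precursors(read_fasta(fasta))
            assert len(hits) == len(truth["embedded"]) == 21


class TestMakeContigs:
    def test_each_precursor_recovered_with_strand(self, tmp_path):
        cfg = SimConfig(seed=11)
        fasta, truth = make_contigs(cfg, tmp_path)
        hits = mine_nucleotides(read_fasta(fasta))
        by_contig = {h.source_id: h for h in hits}
        assert len(hits) == len(truth["embedded"]) == 21
        for e in truth["embedded"]:
            h = by_contig[e["source_id"]]
            assert h.sequence == e["sequence"]
            assert h.strand == e["strand"]
            assert (h.nt_start, h.nt_end) == (e["nt_start"], e["nt_end"])

    def test_gc_within_bounds(self, tmp_path):
        cfg = SimConfig(seed=2, gc_range=(0.45, 0.55))
        fasta, truth = make_contigs(cfg, tmp_path)
        assert 0.45 <= truth["gc"] <= 0.55

    def test_determinism(self, tmp_path):
        a, _ = make_contigs(SimConfig(seed=4), tmp_path / "a")
        b, _ = make_contigs(SimConfig(seed=4), tmp_path / "b")
        assert a.read_bytes() == b.read_bytes()


class TestMakeSpectra:
    def test_cylk2_preset_matches_eleven(self, tmp_path):
        mgf, truth = make_spectra(["GKVNPP"], SimConfig(seed=0, n_noise_peaks=10), tmp_path)
        (spectrum,) = read_mgf(mgf)
        lib = build_library(Peptide.cyclic("GKVNPP"))
        assert annotate_fragments(spectrum, lib).n_matched == 11
        assert truth["spectra"][0]["n_true_ions"] == 11

    def test_zero_jitter_screens_at_zero_ppm(self, tmp_path):
        mgf, _ = make_spectra(["GFGFIP"], SimConfig(seed=0, spectrum_jitter_ppm=0.0), tmp_path)
        (spectrum,) = read_mgf(mgf)
        hits = screen_precursors([spectrum], candidate_mass_list(["GFGFIP"]), tol_ppm=5.0)
        assert len(hits) == 1
        assert abs(hits[0][2]) <= 0.1  # 4-decimal reporting quantization only

    def test_seeded_jitter_true_ions_within_window(self, tmp_path):
        cfg = SimConfig(seed=42, spectrum_jitter_ppm=2.0, n_noise_peaks=0)
        mgf, truth = make_spectra(["GKVNPP"], cfg, tmp_path)
        (spectrum,) = read_mgf(mgf)
        lib = build_library(Peptide.cyclic("GKVNPP"))
        assert annotate_fragments(spectrum, lib, tol_ppm=10.0).n_matched == 11

    def test_full_library_round_trip_when_presets_off(self, tmp_path):
        mgf, _ = make_spectra(
            ["GKVNPP"], SimConfig(seed=0, n_noise_peaks=0), tmp_path, use_presets=False
        )
        (spectrum,) = read_mgf(mgf)
        lib = build_library(Peptide.cyclic("GKVNPP"))
        match = annotate_fragments(spectrum, lib)
        assert match.n_matched == len(lib.ions)
        assert match.coverage == 1.0

    def test_unknown_request_raises(self, tmp_path):
        from cyclomine.simulate import spectrum_for_core

        rng = np.random.default_rng(0)
        with pytest.raises(KeyError):
            spectrum_for_core("GKVNPP", rng, SimConfig(), (("y", "WWW"),))

    def test_determinism(self, tmp_path):
        cfg = SimConfig(seed=8, spectrum_jitter_ppm=2.0)
        a, _ = make_spectra(["GKVNPP", "GFGFIP"], cfg, tmp_path / "a")
        b, _ = make_spectra(["GKVNPP", "GFGFIP"], cfg, tmp_path / "b")
        assert a.read_bytes() == b.read_bytes()


class TestMakeFpkmTable:
    def test_default_reproduces_reference_tiers(self, tmp_path):
        from cyclomine.expression import load_expression_table, tier_classify

        path, _ = make_fpkm_table(tmp_path)
        records = load_expression_table(path)
        assert len(records) == 24
        tiers = tier_classify(records)
        msdin_high = [r for r in tiers["high"] if r.gene_class not in ("POPB",)]
        assert len(msdin_high) == 2

    def test_all_zero_spec(self, tmp_path):
        from cyclomine.expression import load_expression_table, tier_classify

        rows = [(f"g{i}", f"g{i}", 0.0) for i in range(6)]
        path, _ = make_fpkm_table(tmp_path, rows)
        tiers = tier_classify(load_expression_table(path))
        assert len(tiers["zero"]) == 6

    def test_lognormal_tier_counts_match_tail_probabilities(self, tmp_path):
        # seeded log-normal FPKMs: observed high-tier fraction across 200
        # replicates agrees with the analytic tail probability
        from scipy import stats

        from cyclomine.expression import DEFAULT_SCHEME

        mu, sigma, n = 1.0, 2.0, 50
        p_high = 1 - stats.lognorm.cdf(100.0, s=sigma, scale=np.exp(mu))
        rng = np.random.default_rng(314)
        count = 0
        for _ in range(200):
            values = rng.lognormal(mu, sigma, size=n)
            count += sum(DEFAULT_SCHEME.classify(v) == "high" for v in values)
        observed = count / (200 * n)
        se = np.sqrt(p_high * (1 - p_high) / (200 * n))
        assert abs(observed - p_high) < 5 * se
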