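import pytest

from cyclomine.mining import (
    DEFAULT_CATALOGUE,
    DEFAULT_MODEL,
    PrecursorModel,
    classify_cores,
    deduplicate,
    find_msdin_precursors,
    mine_nucleotides,
    translate_six_frames,
)


class TestTranslateSixFrames:
    def test_two_codons(self):
        assert translate_six_frames("ATGTCA")[1] == "MS"

    def test_reverse_complement_symmetry(self):
        dna = "ATGTCAGATATCAATGCC"
        rc = dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert translate_six_frames(dna)[-1] == translate_six_frames(rc)[1]

    def test_all_six_frames_present(self):
        frames = translate_six_frames("ATGAAATTTGGGCCC")
        assert set(frames) == {1, 2, 3, -1, -2, -3}

    def test_stop_codon_rendered_star(self):
        assert translate_six_frames("ATGTAA")[1] == "M*"

    def test_invalid_character_position_in_error(self):
        with pytest.raises(ValueError, match="position 3"):
            translate_six_frames("ATGQCA")


class TestDefaultModel:
    def test_leader_pattern_matches_all_reference_leaders(self, reference_rows):
        for row in reference_rows:
            assert all(
                row.leader[i] in allowed
                for i, allowed in enumerate(DEFAULT_MODEL.leader_pattern)
            ), row.leader

    def test_follower_starts_match(self, reference_rows):
        for row in reference_rows:
            assert all(
                row.follower[i] in allowed
                for i, allowed in enumerate(DEFAULT_MODEL.follower_start_pattern)
            ), row.follower

    def test_from_config_overrides(self):
        model = PrecursorModel.from_config({"core_length_range": [6, 10]})
        assert model.core_length_range == (6, 10)
        assert model.leader_pattern == DEFAULT_MODEL.leader_pattern


class TestFindPrecursors:
    def test_reference_rows_decompose_exactly(self, reference_proteins, reference_rows):
        hits = find_msdin_precursors(reference_proteins)
        assert len(hits) == 21
        expected = {p.gene_id: p for p in reference_rows}
        for h in hits:
            row = expected[h.source_id]
            assert (h.leader, h.core, h.follower) == (row.leader, row.core, row.follower)
            assert h.start == 0 and h.end == len(row.sequence)

    def test_reconstruction_invariant(self, reference_proteins):
        for h in find_msdin_precursors(reference_proteins):
            src = dict(reference_proteins)[h.source_id]
            assert h.sequence == src[h.start:h.end]

    def test_no_met_no_hits(self):
        assert find_msdin_precursors([("x", "GAVLKWFP" * 10)]) == []

    def test_single_reference_precursor(self):
        seq = "MSNINALRLP" + "GFGFIP" + "YASGDVDYTLTRGESLS"
        (hit,) = find_msdin_precursors([("g", seq)])
        assert hit.core == "GFGFIP"

    def test_internal_follower_like_residue_rejected_by_length(self):
        # IWGIGCNP's internal C would imply a 20-residue follower
        seq = "MSDINATRLP" + "IWGIGCNP" + "CVGDDVTTLLTRGEALC"
        (hit,) = find_msdin_precursors([("g", seq)])
        assert hit.core == "IWGIGCNP"

    def test_stop_codon_terminates_window(self):
        seq = "MSNINALRLP" + "GFG*FIP" + "YASGDVDYTLTRGESLS"
        assert find_msdin_precursors([("g", seq)]) == []

    def test_trailing_tail_breaks_follower_length(self):
        # without a stop, the follower runs to sequence end and exceeds 17
        seq = "MSNINALRLP" + "GFGFIP" + "YASGDVDYTLTRGESLS" + "AAAAAAA"
        assert find_msdin_precursors([("g", seq)]) == []
        assert len(find_msdin_precursors([("g", seq + "*")])) == 0
        with_stop = "MSNINALRLP" + "GFGFIP" + "YASGDVDYTLTRGESLS" + "*AAAAAAA"
        assert len(find_msdin_precursors([("g", with_stop)])) == 1

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            find_msdin_precursors([("x", "MSDIN1ATRLP")])

    def test_deterministic_order(self, reference_proteins):
        forward = find_msdin_precursors(reference_proteins)
        backward = find_msdin_precursors(list(reversed(reference_proteins)))
        assert forward == backward


class TestDeduplicate:
    def test_by_core_gives_17(self, reference_proteins):
        hits = find_msdin_precursors(reference_proteins)
        census = deduplicate(hits, key="core")
        assert len(census.unique_cores) == 17
        assert census.n_groups == 17

    def test_by_full_sequence_gives_18(self, reference_proteins):
        hits = find_msdin_precursors(reference_proteins)
        assert deduplicate(hits, key="full_sequence").n_groups == 18

    def test_empty(self):
        census = deduplicate([])
        assert census.n_precursors == 0 and census.n_groups == 0

    def test_bad_key(self):
        with pytest.raises(ValueError):
            deduplicate([], key="follower")


class TestClassifyCores:
    def test_default_catalogue_gives_14_novel(self, reference_proteins):
        census = deduplicate(find_msdin_precursors(reference_proteins))
        assert len(classify_cores(census).novel_cores) == 14

    def test_catalogue_with_everything(self, reference_proteins):
        census = deduplicate(find_msdin_precursors(reference_proteins))
        full = {c: "known" for c in census.unique_cores}
        assert classify_cores(census, full).novel_cores == set()

    def test_empty_catalogue(self, reference_proteins):
        census = deduplicate(find_msdin_precursors(reference_proteins))
        assert len(classify_cores(census, {}).novel_cores) == 17

    def test_default_catalogue_contents(self):
        assert set(DEFAULT_CATALOGUE) == {"IWGIGCNP", "IWGIGCDP", "LNILPFHLPP"}


class TestNucleotideMining:
    CODON = {
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
        "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
        "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
        "W": "TGG", "Y": "TAT",
    }

    def encode(self, protein):
        return "".join(self.CODON[aa] for aa in protein) + "TAA"

    def test_intronless_cds_found_in_exactly_one_frame(self):
        precursor = "MSNINALRLP" + "GFGFIP" + "YASGDVDYTLTRGESLS"
        dna = "GGGG" + self.encode(precursor) + "CCCC"
        hits = mine_nucleotides([("c", dna)])
        assert len(hits) == 1
        (h,) = hits
        assert h.core == "GFGFIP" and h.frame == 2 and h.strand == "+"
        assert dna[h.nt_start:h.nt_end] == self.encode(precursor)[:-3]

    def test_minus_strand_coordinates(self):
        precursor = "MSDINATRFP" + "GKVNPP" + "YVGDDVDDIIIRGEKLC"
        cds = self.encode(precursor)
        rc = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        dna = "AAAAA" + rc + "GGGGG"
        hits = mine_nucleotides([("c", dna)])
        assert len(hits) == 1
        (h,) = hits
        assert h.core == "GKVNPP" and h.strand == "-"
        fwd = dna[h.nt_start:h.nt_end]
        back = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert back == cds[:-3]

    def test_mid_precursor_stop_kills_hit(self):
        precursor = "MSNINALRLP" + "GFGFIP" + "YASGDVDYTLTRGESLS"
        cds = self.encode(precursor)
        broken = cds[:30] + "TAA" + cds[33:]  # replace codon 11 with a stop
        assert mine_nucleotides([("c", broken)]) == []
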