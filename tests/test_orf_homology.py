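"""Translated search layer: frames, ORFs, alignment, genome screening."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from cyanophot.io_formats import GenomeBin, SequenceRecord, reverse_complement
from cyanophot.orf_homology import (
    PanelEntry,
    call_orfs,
    global_align,
    local_align,
    rescore_alignment,
    screen_genome,
    six_frame_translate,
)
from cyanophot.references import reference_protein
from cyanophot.synthetic_data import mutate_protein, reverse_translate

from _oracles import brute_orfs, gotoh_score

AA = list("ACDEFGHIKLMNPQRSTVWY")


class TestSixFrameTranslate:
    def test_forward_frame(self):
        assert six_frame_translate("ATGAAA")[1] == "MK"

    def test_reverse_frame_is_translation_of_rc(self):
        # revcomp of ATGAAA is TTTCAT -> F H
        assert six_frame_translate("ATGAAA")[-1] == "FH"

    def test_too_short_yields_empty_frames(self):
        assert all(p == "" for p in six_frame_translate("AT").values())

    def test_frames_cover_all_offsets(self):
        out = six_frame_translate("ATGAAAGGG")
        assert set(out) == {1, 2, 3, -1, -2, -3}
        assert out[2] == six_frame_translate("TGAAAGGG")[1]


class TestCallOrfs:
    def test_simple_plus_one_orf(self):
        orfs = call_orfs("ATGAAATAA", min_aa=2)
        plus = [o for o in orfs if o.frame == 1]
        assert len(plus) == 1 and plus[0].protein == "MK"
        assert (plus[0].start, plus[0].end) == (0, 6)

    def test_min_aa_threshold_excludes_short_frames(self):
        # 50 stop-free codons: no frame can reach 60 aa in a 150 nt contig
        seq = reverse_translate("M" * 50, np.random.default_rng(0))
        assert call_orfs(seq, min_aa=60) == []

    def test_contig_ends_are_open(self):
        # stop-free sequence: the whole frame is one ORF without stops
        seq = "ATGGCA" * 10
        orfs = [o for o in call_orfs(seq, min_aa=10) if o.frame == 1]
        assert len(orfs) == 1
        assert orfs[0].start == 0 and orfs[0].end == len(seq)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_frame_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 300))
        got = {(o.start, o.end, o.frame, o.protein) for o in call_orfs(seq, min_aa=5)}
        assert got == brute_orfs(seq, 5)


class TestAlignment:
    def test_self_alignment_scores_diagonal(self):
        mat = substitution_matrices.load("BLOSUM62")
        res = local_align("MKWVT", "MKWVT")
        assert res.identity == 1.0
        assert res.query_cov == 1.0
        assert res.score == sum(mat[a, a] for a in "MKWVT")

    def test_unalignable_pair_scores_zero(self):
        res = local_align("AAAA", "CCCC")
        assert res.score == 0.0 and res.aligned_query == ""

    def test_global_identical_strings(self):
        res = global_align("MKWVT", "MKWVT")
        assert res.identity == 1.0 and "-" not in res.aligned_query

    def test_global_single_gap_column(self):
        res = global_align("MK", "MAK")
        assert res.aligned_query.count("-") == 1
        assert res.aligned_target.count("-") == 0

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MK")
        with pytest.raises(ValueError):
            local_align("MK", "")

    def test_scores_match_independent_dp_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            q = "".join(rng.choice(AA, rng.integers(1, 13)))
            t = "".join(rng.choice(AA, rng.integers(1, 13)))
            assert local_align(q, t).score == gotoh_score(q, t, "local")
            assert global_align(q, t).score == gotoh_score(q, t, "global")

    def test_scores_recomputable_from_gapped_strings(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q = "".join(rng.choice(AA, 40))
            t = "".join(rng.choice(AA, 40))
            res = global_align(q, t)
            assert rescore_alignment(res.aligned_query, res.aligned_target) == res.score


def _mag_with_insert(protein: str, rng, revcomp: bool = False) -> GenomeBin:
    bg1 = "".join(rng.choice(list("ACGT"), 600))
    bg2 = "".join(rng.choice(list("ACGT"), 600))
    cassette = "TAA" + reverse_translate(protein, rng) + "TAA"
    if revcomp:
        cassette = reverse_complement(cassette)
    return GenomeBin(
        "M1", "C01", [SequenceRecord("ctg1", bg1 + cassette + bg2)]
    )


class TestScreenGenome:
    def test_planted_exact_copy_recovered(self, rng):
        prot = reference_protein("pufM")
        mag = _mag_with_insert(prot, rng)
        panel = [PanelEntry("REF1", "pufM", prot)]
        hits = screen_genome(mag, panel)
        assert len(hits) == 1
        assert hits[0].gene_label == "pufM"
        assert hits[0].alignment.identity == 1.0
        assert hits[0].orf.strand == "+"

    def test_reverse_strand_insert_same_score(self, rng):
        prot = reference_protein("pufM")
        panel = [PanelEntry("REF1", "pufM", prot)]
        fwd = screen_genome(_mag_with_insert(prot, np.random.default_rng(5)), panel)
        rev = screen_genome(
            _mag_with_insert(prot, np.random.default_rng(5), revcomp=True), panel
        )
        assert len(fwd) == len(rev) == 1
        assert fwd[0].alignment.score == rev[0].alignment.score
        assert rev[0].orf.frame < 0

    def test_heavily_mutated_insert_rejected(self, rng):
        prot = reference_protein("pufM")
        # mutate in rounds until the measured identity falls below the
        # screen's identity threshold, then confirm rejection
        mutant = prot
        while global_align(prot, mutant).identity >= 0.25:
            mutant = mutate_protein(mutant, 0.5, rng)
        assert global_align(prot, mutant).identity < 0.30
        mag = _mag_with_insert(mutant, rng)
        hits = screen_genome(mag, [PanelEntry("REF1", "pufM", prot)])
        assert hits == []

    def test_strand_symmetry_of_hit_sets(self, rng):
        prot = reference_protein("bchC")
        mag = _mag_with_insert(prot, rng)
        flipped = GenomeBin(
            mag.mag_id,
            mag.metagenome_id,
            [SequenceRecord(c.id, reverse_complement(c.seq)) for c in mag.contigs],
        )
        panel = [PanelEntry("REF1", "bchC", prot)]
        h1 = screen_genome(mag, panel)
        h2 = screen_genome(flipped, panel)
        assert len(h1) == len(h2) == 1
        n = len(mag.contigs[0].seq)
        f1, f2 = h1[0].to_feature(), h2[0].to_feature()
        assert (f1.start, f1.end) == (n - f2.end, n - f2.start)
        assert h1[0].alignment.score == h2[0].alignment.score

    def test_empty_mag_warns(self, caplog):
        mag = GenomeBin("M1", "C01", [])
        with caplog.at_level("WARNING", logger="cyanophot"):
            assert screen_genome(mag, [PanelEntry("R", "x", "MKWVT" * 20)]) == []

    def test_empty_panel_rejected(self, rng):
        mag = _mag_with_insert(reference_protein("pufM"), rng)
        with pytest.raises(ValueError):
            screen_genome(mag, [])
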