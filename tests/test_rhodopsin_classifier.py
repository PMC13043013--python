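"""Rhodopsin classification: anchor mapping, residues, subtree, operon, call."""

import numpy as np
import pytest

from cyanophot.io_formats import GeneFeature
from cyanophot.rhodopsin_classifier import (
    DiagnosticProfile,
    anchor_map,
    assign_subtree,
    call_function,
    extract_profile,
    operon_context,
)
from cyanophot.references import rhodopsin_anchor, rhodopsin_reference_panel
from cyanophot.synthetic_data import mutate_protein

ANCHOR = rhodopsin_anchor("I")
PANEL = rhodopsin_reference_panel()


def _profile(**kw) -> DiagnosticProfile:
    base = dict(res85="D", res89="T", res96="E", res156="G", retinal_lysine="K")
    base.update(kw)
    return DiagnosticProfile(**base)


class TestAnchorMap:
    def test_identity_mapping(self):
        m = anchor_map(ANCHOR, ANCHOR)
        assert all(
            m.pairs[p] == (p, ANCHOR[p - 1]) for p in range(1, len(ANCHOR) + 1)
        )

    def test_insertion_shifts_downstream_positions(self):
        hit = ANCHOR[:10] + "W" + ANCHOR[10:]
        m = anchor_map(hit, ANCHOR)
        for p in range(1, 11):
            assert m.pairs[p] == (p, ANCHOR[p - 1])
        # positions past the insertion map one residue further right
        for p in (50, 85, 292):
            assert m.pairs[p] == (p + 1, ANCHOR[p - 1])

    def test_truncation_gives_null_positions(self):
        hit = ANCHOR[:80]  # ends before anchor position 85
        m = anchor_map(hit, ANCHOR)
        profile = extract_profile(m)
        assert profile.res85 is None
        assert not profile.has_DTE
        assert not profile.has_retinal_K

    def test_unrelated_sequence_rejected(self):
        # a short unrelated fragment cannot cover the anchor: identity over
        # the global alignment columns drops below the reliability guard
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
        with pytest.raises(ValueError, match="anchor mapping unreliable"):
            anchor_map(junk, ANCHOR)


class TestExtractProfile:
    def test_canonical_flags(self):
        p = extract_profile(anchor_map(ANCHOR, ANCHOR))
        assert p.has_DTE and p.has_G156 and p.has_retinal_K
        assert not p.na_pump_motif

    def test_e96q_keeps_retinal_lysine(self):
        hit = ANCHOR[:95] + "Q" + ANCHOR[96:]
        p = extract_profile(anchor_map(hit, ANCHOR))
        assert not p.has_DTE
        assert p.has_retinal_K

    def test_k292a_loses_retinal_lysine(self):
        hit = ANCHOR[:291] + "A" + ANCHOR[292:]
        p = extract_profile(anchor_map(hit, ANCHOR))
        assert not p.has_retinal_K


class TestAssignSubtree:
    @pytest.mark.parametrize("subtree", ["I", "II", "III"])
    def test_panel_reference_classifies_as_itself(self, subtree):
        label, margin, low = assign_subtree(rhodopsin_anchor(subtree), PANEL)
        assert label == subtree
        assert margin > 0 and not low

    def test_mutated_subtree_iii_sequence_stays_iii(self):
        rng = np.random.default_rng(1)
        mutant = mutate_protein(rhodopsin_anchor("III"), 0.10, rng)
        label, _, low = assign_subtree(mutant, PANEL)
        assert label == "III" and not low

    def test_chimera_raises_low_confidence_flag(self):
        a, c = rhodopsin_anchor("I"), rhodopsin_anchor("III")
        chimera = a[: len(a) // 2] + c[len(c) // 2 :]
        _, margin, low = assign_subtree(chimera, PANEL)
        assert low

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            assign_subtree(ANCHOR, [])


def _feat(start, end, label, contig="ctg1"):
    return GeneFeature(contig_id=contig, start=start, end=end, strand="+", label=label)


class TestOperonContext:
    def test_adjacent_operon(self):
        rhod = _feat(1000, 1900, "rhodopsin")
        feats = [rhod, _feat(2000, 2600, "crtY"), _feat(2700, 3500, "brp_blh")]
        ctx = operon_context(rhod, feats, _profile())
        assert ctx.brp_blh_adjacent and ctx.brp_blh_in_genome
        assert ctx.crt_genes == frozenset({"crtY"})

    def test_full_xanthorhodopsin_operon_crt_census(self):
        rhod = _feat(1000, 1900, "rhodopsin")
        feats = [
            rhod,
            _feat(2000, 2600, "crtE"),
            _feat(2700, 3300, "crtB"),
            _feat(3400, 4000, "crtY"),
            _feat(4100, 4900, "brp_blh"),
        ]
        ctx = operon_context(rhod, feats, _profile())
        assert ctx.crt_genes == frozenset({"crtE", "crtB", "crtY"})
        assert ctx.brp_blh_adjacent

    def test_brp_blh_on_other_contig_counts_genome_wide_only(self):
        rhod = _feat(1000, 1900, "rhodopsin")
        feats = [rhod, _feat(500, 1300, "brp_blh", contig="ctg2")]
        ctx = operon_context(rhod, feats, _profile())
        assert not ctx.brp_blh_adjacent
        assert ctx.brp_blh_in_genome

    def test_window_boundary(self):
        rhod = _feat(1000, 1900, "rhodopsin")
        far = _feat(1900 + 5000, 1900 + 5600, "brp_blh")
        ctx = operon_context(rhod, [rhod, far], _profile(), window_bp=5000)
        assert not ctx.brp_blh_adjacent and ctx.brp_blh_in_genome

    def test_hit_must_be_in_feature_set(self):
        rhod = _feat(1000, 1900, "rhodopsin")
        with pytest.raises(ValueError):
            operon_context(rhod, [_feat(0, 10, "crtY")], _profile())


class TestCallFunction:
    def _ctx(self, profile, adjacent=False, in_genome=False):
        return operon_context(
            _feat(1000, 1900, "rhodopsin"),
            [_feat(1000, 1900, "rhodopsin")]
            + ([_feat(2000, 2800, "brp_blh")] if adjacent else [])
            + ([_feat(0, 800, "brp_blh", contig="ctg9")] if in_genome and not adjacent else []),
            profile,
        )

    def test_bona_fide_pump_with_antenna(self):
        call, antenna = call_function("III", _profile(), self._ctx(_profile(), adjacent=True))
        assert call == "bona_fide_pump" and antenna

    def test_ndq_is_excluded_as_na_pump(self):
        p = _profile(res85="N", res89="D", res96="Q")
        call, _ = call_function("II", p, self._ctx(p, adjacent=True))
        assert call == "na_pump_excluded"

    def test_missing_retinal_lysine_is_divergent(self):
        p = _profile(retinal_lysine="A")
        call, _ = call_function("I", p, self._ctx(p, adjacent=True))
        assert call == "divergent_unknown"

    def test_e96_divergence_does_not_disqualify(self):
        p = _profile(res96="Q")
        call, antenna = call_function("II", p, self._ctx(p, in_genome=True))
        assert call == "bona_fide_pump"
        assert not antenna  # subtree II never gets the antenna prediction

    def test_pump_without_genomic_brp_blh_stays_candidate(self):
        call, _ = call_function("I", _profile(), self._ctx(_profile()))
        assert call == "candidate_pump"

    def test_removing_brp_blh_only_demotes_bona_fide(self):
        """brp/blh removal must demote the call and change nothing else."""
        p = _profile()
        with_blh = call_function("III", p, self._ctx(p, adjacent=True))
        without = call_function("III", p, self._ctx(p))
        assert with_blh == ("bona_fide_pump", True)
        assert without == ("candidate_pump", True)
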