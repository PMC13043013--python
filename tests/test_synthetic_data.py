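"""Generator determinism, GC targeting, planted-feature bookkeeping."""

import numpy as np
import pytest

from cyanophot.orf_homology import global_align
from cyanophot.references import rhodopsin_anchor
from cyanophot.synthetic_data import (
    NA_PUMP_OVERRIDES,
    CollectionConfig,
    PlantSpec,
    build_mag,
    default_feature_mix,
    generate_background,
    generate_collection,
    invert_block,
    mutate_protein,
    mutation_series,
    plant_feature,
    reverse_translate,
    write_collection,
)


class TestBackground:
    def test_deterministic_for_fixed_seed(self):
        a = generate_background(500, 0.5, 99).seq
        b = generate_background(500, 0.5, 99).seq
        assert a == b

    def test_gc_within_binomial_tolerance(self):
        # target 0.69 over 1e5 bases: binomial 3-sigma is well under 0.02
        seq = generate_background(100_000, 0.69, 1).seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.69) < 0.02

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.2])
    def test_out_of_range_gc_rejected(self, gc):
        with pytest.raises(ValueError):
            generate_background(100, gc, 0)


class TestMutation:
    def test_reverse_translation_round_trips(self):
        from Bio.Seq import Seq

        prot = "MKWVTAGELRRIFD"
        nt = reverse_translate(prot, np.random.default_rng(0))
        assert str(Seq(nt).translate(table=11)) == prot

    def test_rate_zero_is_identity(self):
        prot = rhodopsin_anchor("I")
        assert mutate_protein(prot, 0.0, np.random.default_rng(0)) == prot

    def test_overrides_applied_last(self):
        prot = rhodopsin_anchor("I")
        out = mutate_protein(prot, 0.0, np.random.default_rng(0),
                             overrides=dict(NA_PUMP_OVERRIDES))
        assert out[84] == "N" and out[88] == "D" and out[95] == "Q"

    def test_rate_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            mutate_protein("MKWVT", 0.9, 0)

    def test_mutation_series_identity_non_increasing(self):
        prot = rhodopsin_anchor("II")
        rates = [0.0, 0.2, 0.4, 0.7]
        series = mutation_series(prot, rates, 5)
        idents = [global_align(prot, m).identity for m in series]
        assert series[0] == prot
        assert all(a >= b for a, b in zip(idents, idents[1:]))


class TestPlanting:
    def test_contig_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            plant_feature("ACGT" * 10, PlantSpec(kind="brp_blh_only"), 0, at=1000)

    def test_operon_gene_order_and_spacing(self):
        spec = PlantSpec(kind="rhodopsin_operon", subtree="III",
                         operon_genes=("rhodopsin", "crtY", "brp_blh"))
        genome = generate_background(4000, 0.5, 3).seq
        _, feats = plant_feature(genome, spec, 4, at=2000)
        assert [f.gene_label for f in feats] == ["rhodopsin", "crtY", "brp_blh"]
        starts = [f.start for f in feats]
        assert starts == sorted(starts)

    def test_na_pump_expectation_recorded(self):
        spec = PlantSpec(kind="na_pump", subtree="II",
                         overrides=dict(NA_PUMP_OVERRIDES))
        _, feats = build_mag("M", "C01", [spec], 6000, 0.5, np.random.default_rng(0))
        rhod = [f for f in feats if f.gene_label == "rhodopsin"][0]
        assert rhod.expected_call == "na_pump_excluded"

    def test_k292a_expectation_recorded(self):
        spec = PlantSpec(kind="solitary_rhodopsin", subtree="I",
                         overrides={292: "A"})
        _, feats = build_mag("M", "C01", [spec], 6000, 0.5, np.random.default_rng(0))
        assert feats[0].expected_call == "divergent_unknown"

    def test_pump_without_blh_expected_candidate(self):
        spec = PlantSpec(kind="solitary_rhodopsin", subtree="I")
        _, feats = build_mag("M", "C01", [spec], 6000, 0.5, np.random.default_rng(0))
        assert feats[0].expected_call == "candidate_pump"

    def test_blh_elsewhere_makes_pump_bona_fide_but_not_adjacent(self):
        specs = [PlantSpec(kind="solitary_rhodopsin", subtree="III"),
                 PlantSpec(kind="brp_blh_only")]
        _, feats = build_mag("M", "C01", specs, 12000, 0.5, np.random.default_rng(0))
        rhod = [f for f in feats if f.gene_label == "rhodopsin"][0]
        assert rhod.expected_call == "bona_fide_pump"
        assert rhod.expected_brp_adjacent is False

    def test_invert_block_shape(self):
        assert invert_block(5, 2, 4) == (1, -4, -3, -2, 5)


class TestCollection:
    def test_mag_counts_in_configured_range(self, collection):
        per_meta = {}
        for mag in collection.mags:
            per_meta.setdefault(mag.metagenome_id, []).append(mag)
        cfg = CollectionConfig()
        assert len(per_meta) == cfg.n_metagenomes
        for mags in per_meta.values():
            assert cfg.mags_per_metagenome[0] <= len(mags) <= cfg.mags_per_metagenome[1]
            assert sum(m.is_host for m in mags) == 1

    def test_coverage_qc_taxonomy_cover_every_mag(self, collection):
        ids = {m.mag_id for m in collection.mags}
        assert set(collection.coverage["mag_id"]) == ids
        assert set(collection.qc["mag_id"]) == ids
        assert set(collection.taxonomy["mag_id"]) == ids

    def test_truth_intervals_lie_within_contigs(self, collection):
        by_id = {m.mag_id: m for m in collection.mags}
        for f in collection.truth.features:
            contig = by_id[f.mag_id].contig(f.contig_id)
            assert 0 <= f.start < f.end <= len(contig)

    def test_expected_venn_matches_stated_mix(self, collection):
        venn = collection.truth.expected_venn()
        # the default feature mix plants, by construction:
        # 5 PGC-positive MAGs (1 dual), 6 rhodopsin MAGs with a pump or
        # candidate call, 5 of them bona fide, 1 host per metagenome
        assert venn["cyano"] == 14
        assert venn["pgc_total"] == 5
        assert venn["rhodopsin_total"] == 6
        assert venn["rhodopsin_bona_fide"] == 5
        assert venn["dual"] == 1

    def test_fixed_seed_reproduces_output_tree(self, tmp_path):
        cfg = CollectionConfig(n_metagenomes=2)
        mix = {1: default_feature_mix()[6]}
        a = generate_collection(
            CollectionConfig(n_metagenomes=2, feature_mix=mix), rng_seed=3
        )
        b = generate_collection(
            CollectionConfig(n_metagenomes=2, feature_mix=mix), rng_seed=3
        )
        write_collection(a, tmp_path / "a")
        write_collection(b, tmp_path / "b")
        for rel in ["manifest.tsv", "coverage.tsv", "qc.tsv", "taxonomy.tsv",
                    "truth_manifest.tsv", "truth_manifest.json"]:
            assert (tmp_path / "a" / rel).read_bytes() == (
                tmp_path / "b" / rel
            ).read_bytes()
        fa = sorted(p.name for p in (tmp_path / "a" / "fasta").iterdir())
        fb = sorted(p.name for p in (tmp_path / "b" / "fasta").iterdir())
        assert fa == fb
        for name in fa:
            assert (tmp_path / "a" / "fasta" / name).read_bytes() == (
                tmp_path / "b" / "fasta" / name
            ).read_bytes()
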