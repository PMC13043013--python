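"""Synthetic MAG collections with planted, manifest-recorded phototrophy.

Emulates the structure of a per-culture cyanobacterial metagenome: each
synthetic metagenome holds one high-coverage "host" genome (the
cyanobacterium, GC-rich) plus associated genomes, some of which carry
planted features — complete, rearranged, partial or split photosynthesis
gene clusters (PGCs); rhodopsin operons with or without the brp/blh
retinal gene; residue variants (E96Q, K292A, the NDQ Na-pump decoy); or
a lone brp/blh. Every planted feature is recorded in a truth manifest
together with the subtree, functional call and per-MAG phototrophy mode
the pipeline is expected to recover, so the generator doubles as the
ground truth for end-to-end tests.

Planted proteins are reverse-translated with uniform synonymous codon
choice (bacterial code) and inserted in frame between stop codons;
features never overlap and keep at least 1 kb of background spacing.
All output is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import GenomeBin, SequenceRecord, write_fasta
from .references import (
    AMINO_ACIDS,
    BRP_BLH_LABEL,
    DIAGNOSTIC_POSITIONS,
    PGC_REFERENCE_GENES,
    RHODOPSIN_LABEL,
    reference_protein,
    rhodopsin_anchor,
)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()

#: diagnostic anchor positions protected from random mutation (0-based)
_PROTECTED = {p - 1 for p in DIAGNOSTIC_POSITIONS.values()}

MIN_SPACING_BP = 1000


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_background(length: int, gc: float, rng_seed) -> SequenceRecord:
    """I.i.d. nucleotide background at a target GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = _as_rng(rng_seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("AGCT"), size=length, p=probs))
    return SequenceRecord(id="background", seq=seq)


def reverse_translate(protein: str, rng_seed) -> str:
    """Uniform-synonymous-codon reverse translation (bacterial code)."""
    rng = _as_rng(rng_seed)
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def mutate_protein(
    protein: str,
    rate: float,
    rng_seed,
    protected: set[int] | None = None,
    overrides: dict[int, str] | None = None,
) -> str:
    """Substitute residues i.i.d. at ``rate``, then apply fixed overrides.

    ``protected`` holds 0-based positions exempt from random mutation;
    ``overrides`` maps 1-based positions to forced residues (applied
    last, e.g. E96Q or the NDQ triad).
    """
    if not 0 <= rate <= 0.7:
        raise ValueError(f"mutation rate must be in [0, 0.7], got {rate}")
    rng = _as_rng(rng_seed)
    seq = list(protein)
    protected = protected or set()
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != seq[i]]
            seq[i] = choices[int(rng.integers(len(choices)))]
    for pos, residue in (overrides or {}).items():
        if not 1 <= pos <= len(seq):
            raise ValueError(f"override position {pos} outside protein")
        seq[pos - 1] = residue
    return "".join(seq)


def mutation_series(protein: str, rates: Sequence[float], rng_seed) -> list[str]:
    """Nested mutants: positions mutated at a lower rate stay mutated at
    every higher rate, so per-protein identity is non-increasing in rate."""
    rng = _as_rng(rng_seed)
    u = rng.random(len(protein))
    new_residues = [
        [a for a in AMINO_ACIDS if a != c][int(rng.integers(19))] for c in protein
    ]
    out = []
    for rate in rates:
        if not 0 <= rate <= 0.7:
            raise ValueError(f"mutation rate must be in [0, 0.7], got {rate}")
        out.append(
            "".join(
                new_residues[i] if u[i] < rate else c for i, c in enumerate(protein)
            )
        )
    return out


# ---------------------------------------------------------------------------
# Plant specifications
# ---------------------------------------------------------------------------

PGC_SYMBOLS = tuple(sym for sym, _ in PGC_REFERENCE_GENES)


@dataclass(frozen=True)
class PlantSpec:
    """One feature to plant into a synthetic genome.

    kinds: ``pgc``, ``rhodopsin_operon``, ``solitary_rhodopsin``,
    ``na_pump``, ``brp_blh_only``.
    """

    kind: str
    subtree: str = "I"  # source anchor for rhodopsin kinds
    operon_genes: tuple[str, ...] | None = None  # rhodopsin operon layout
    pgc_genes: tuple[str, ...] | None = None  # None = full reference list
    pgc_rearrangement: tuple[int, ...] | None = None  # signed positions into pgc_genes
    mutation_rate: float = 0.0
    overrides: dict | None = None  # 1-based anchor position -> residue
    strand: str = "+"
    split_across_contigs: bool = False

    def gene_layout(self) -> tuple[str, ...]:
        if self.kind == "pgc":
            genes = self.pgc_genes if self.pgc_genes is not None else PGC_SYMBOLS
            if self.pgc_rearrangement is not None:
                return tuple(genes[abs(i) - 1] for i in self.pgc_rearrangement)
            return tuple(genes)
        if self.kind == "rhodopsin_operon":
            return self.operon_genes or (RHODOPSIN_LABEL, "crtY", BRP_BLH_LABEL)
        if self.kind in {"solitary_rhodopsin", "na_pump"}:
            return (RHODOPSIN_LABEL,)
        if self.kind == "brp_blh_only":
            return (BRP_BLH_LABEL,)
        raise ValueError(f"unknown plant kind {self.kind!r}")

    def gene_strands(self) -> tuple[str, ...]:
        genes = self.gene_layout()
        if self.kind == "pgc" and self.pgc_rearrangement is not None:
            flip = {"+": "-", "-": "+"}
            return tuple(
                self.strand if i > 0 else flip[self.strand]
                for i in self.pgc_rearrangement
            )
        return tuple(self.strand for _ in genes)


NA_PUMP_OVERRIDES = {85: "N", 89: "D", 96: "Q"}


def invert_block(n: int, i: int, j: int) -> tuple[int, ...]:
    """Signed permutation of 1..n with block [i, j] (1-based) inverted."""
    order = list(range(1, n + 1))
    block = [-x for x in reversed(order[i - 1 : j])]
    return tuple(order[: i - 1] + block + order[j:])


@dataclass(frozen=True)
class PlantedFeature:
    """Truth-manifest row for one planted gene."""

    mag_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    kind: str
    gene_label: str
    expected_subtree: str | None = None
    expected_call: str | None = None
    expected_antenna: bool | None = None
    expected_brp_adjacent: bool | None = None
    mutation_rate: float = 0.0


@dataclass
class TruthManifest:
    features: list[PlantedFeature] = field(default_factory=list)
    mag_modes: dict[str, str] = field(default_factory=dict)  # mag_id -> expected mode
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def expected_venn(self) -> dict[str, int]:
        modes = self.mag_modes
        rhodopsin_mags = {
            f.mag_id
            for f in self.features
            if f.gene_label == RHODOPSIN_LABEL
            and f.expected_call in {"bona_fide_pump", "candidate_pump"}
        }
        return {
            "total_mags": len(modes),
            "cyano": sum(1 for m in modes.values() if m == "cyano_oxygenic"),
            "pgc_total": sum(1 for m in modes.values() if m in {"pgc_only", "dual"}),
            "rhodopsin_total": len(rhodopsin_mags),
            "rhodopsin_bona_fide": len(
                {
                    f.mag_id
                    for f in self.features
                    if f.gene_label == RHODOPSIN_LABEL
                    and f.expected_call == "bona_fide_pump"
                }
            ),
            "dual": sum(1 for m in modes.values() if m == "dual"),
            "none": sum(1 for m in modes.values() if m == "none"),
        }

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "mag_id": f.mag_id,
                "contig_id": f.contig_id,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "kind": f.kind,
                "gene_label": f.gene_label,
                "expected_subtree": f.expected_subtree or ".",
                "expected_call": f.expected_call or ".",
                "expected_antenna": "." if f.expected_antenna is None else int(f.expected_antenna),
                "expected_brp_adjacent": "."
                if f.expected_brp_adjacent is None
                else int(f.expected_brp_adjacent),
                "mutation_rate": f.mutation_rate,
            }
            for f in self.features
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "mag_id", "contig_id", "start", "end", "strand", "kind",
                "gene_label", "expected_subtree", "expected_call",
                "expected_antenna", "expected_brp_adjacent", "mutation_rate",
            ],
        )


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _source_protein(spec: PlantSpec, gene: str) -> str:
    if gene == RHODOPSIN_LABEL:
        return rhodopsin_anchor(spec.subtree)
    return reference_protein(gene)


def _gene_cassette(spec: PlantSpec, gene: str, strand: str, rng: np.random.Generator):
    """In-frame cassette TAA + CDS + TAA for one gene; returns
    (nucleotides, relative coding interval on the cassette's forward strand)."""
    protein = _source_protein(spec, gene)
    if gene == RHODOPSIN_LABEL:
        protein = mutate_protein(
            protein, spec.mutation_rate, rng, protected=_PROTECTED,
            overrides=spec.overrides,
        )
    else:
        protein = mutate_protein(protein, spec.mutation_rate, rng)
    nt = "TAA" + reverse_translate(protein, rng) + "TAA"
    if strand == "-":
        from .io_formats import reverse_complement

        nt = reverse_complement(nt)
    # coding region excludes the two flanking stops regardless of strand
    return nt, (3, len(nt) - 3)


def plant_feature(
    genome: str,
    spec: PlantSpec,
    rng_seed,
    at: int | None = None,
    mag_id: str = "mag",
    contig_id: str = "contig",
) -> tuple[str, list[PlantedFeature]]:
    """Insert one planted feature into a background sequence.

    Genes of an operon are laid out in order with short intergenic gaps.
    Returns the grown sequence and per-gene truth rows (expected calls
    are filled in later at the MAG level, once genomic brp/blh presence
    is known).
    """
    rng = _as_rng(rng_seed)
    genes = spec.gene_layout()
    strands = spec.gene_strands()
    pieces: list[str] = []
    rel_feats: list[tuple[str, str, int, int]] = []
    cursor = 0
    for idx, (gene, strand) in enumerate(zip(genes, strands)):
        if idx:
            gap = generate_background(30, 0.5, rng).seq
            pieces.append(gap)
            cursor += 30
        nt, (c0, c1) = _gene_cassette(spec, gene, strand, rng)
        rel_feats.append((gene, strand, cursor + c0, cursor + c1))
        pieces.append(nt)
        cursor += len(nt)
    cassette = "".join(pieces)
    if at is None:
        at = len(genome) // 2
    if at > len(genome):
        raise ValueError(
            f"contig too short: insertion point {at} beyond background of "
            f"{len(genome)} bp"
        )
    new_genome = genome[:at] + cassette + genome[at:]
    feats = [
        PlantedFeature(
            mag_id=mag_id,
            contig_id=contig_id,
            start=at + s,
            end=at + e,
            strand=strand,
            kind=spec.kind,
            gene_label=gene,
            mutation_rate=spec.mutation_rate,
        )
        for gene, strand, s, e in rel_feats
    ]
    return new_genome, feats


def _expected_rhodopsin_outcome(
    spec: PlantSpec, brp_in_genome: bool, brp_adjacent: bool
) -> tuple[str, str, bool]:
    """(subtree, call, antenna) a correct pipeline should produce for a
    planted rhodopsin, derived from the spec's override table."""
    residues = {p: rhodopsin_anchor(spec.subtree)[p - 1] for p in (85, 89, 96, 156, 292)}
    residues.update(spec.overrides or {})
    if residues[85] == "N" and residues[89] == "D" and residues[96] == "Q":
        call = "na_pump_excluded"
    elif residues[292] != "K":
        call = "divergent_unknown"
    elif brp_in_genome:
        call = "bona_fide_pump"
    else:
        call = "candidate_pump"
    antenna = residues[156] == "G" and spec.subtree in {"I", "III"}
    return spec.subtree, call, antenna


def build_mag(
    mag_id: str,
    metagenome_id: str,
    specs: Sequence[PlantSpec],
    background_bp: int,
    gc: float,
    rng_seed,
    is_host: bool = False,
) -> tuple[GenomeBin, list[PlantedFeature]]:
    """Assemble one synthetic MAG with its planted features and truth rows."""
    rng = _as_rng(rng_seed)
    # one contig per planted feature (so "elsewhere in the genome" plants are
    # genuinely non-adjacent), two contigs for a PGC asked to be split
    contig_plans: list[list[PlantSpec]] = []
    spec_of_plan: list[PlantSpec | None] = []
    for spec in specs:
        if spec.kind == "pgc" and spec.split_across_contigs:
            genes = spec.gene_layout()
            half = len(genes) // 2
            for part in (genes[:half], genes[half:]):
                contig_plans.append(
                    [replace(spec, pgc_genes=part, pgc_rearrangement=None,
                             split_across_contigs=False)]
                )
                spec_of_plan.append(spec)
        else:
            contig_plans.append([spec])
            spec_of_plan.append(spec)
    if not contig_plans:
        contig_plans = [[]]
        spec_of_plan = [None]
    contigs: list[SequenceRecord] = []
    features: list[PlantedFeature] = []
    spec_of_feature: dict[int, PlantSpec] = {}
    for ci, plan in enumerate(contig_plans, start=1):
        contig_id = f"{mag_id}_ctg{ci}"
        bg_len = max(background_bp // len(contig_plans), 2 * MIN_SPACING_BP + 500)
        seq = generate_background(bg_len, gc, rng).seq
        for spec in plan:
            seq, feats = plant_feature(
                seq, spec, rng, at=MIN_SPACING_BP, mag_id=mag_id, contig_id=contig_id
            )
            for f in feats:
                spec_of_feature[id(f)] = spec
            features.extend(feats)
        contigs.append(SequenceRecord(id=contig_id, seq=seq))
    # fill in expected outcomes now that genomic brp/blh presence is known
    brp_in_genome = any(f.gene_label == BRP_BLH_LABEL for f in features)
    resolved: list[PlantedFeature] = []
    for f in features:
        if f.gene_label == RHODOPSIN_LABEL:
            spec = spec_of_feature[id(f)]
            adjacent = any(
                g.gene_label == BRP_BLH_LABEL
                and g.contig_id == f.contig_id
                and g.start < f.end + 5000
                and g.end > f.start - 5000
                for g in features
            )
            subtree, call, antenna = _expected_rhodopsin_outcome(
                spec, brp_in_genome, adjacent
            )
            resolved.append(
                replace(
                    f,
                    expected_subtree=subtree,
                    expected_call=call,
                    expected_antenna=antenna,
                    expected_brp_adjacent=adjacent,
                )
            )
        else:
            resolved.append(f)
    mag = GenomeBin(
        mag_id=mag_id, metagenome_id=metagenome_id, contigs=contigs, is_host=is_host
    )
    return mag, resolved


def expected_mode(specs: Sequence[PlantSpec], features: Sequence[PlantedFeature],
                  is_host: bool) -> str:
    """Phototrophy mode a correct pipeline should call for this MAG."""
    if is_host:
        return "cyano_oxygenic"
    pgc_symbols = {
        f.gene_label for f in features if f.kind == "pgc"
    }
    has_pgc = (
        {"pufL", "pufM"} <= pgc_symbols
        and len(pgc_symbols) / len(PGC_SYMBOLS) >= 0.5
    )
    has_pump = any(
        f.expected_call == "bona_fide_pump"
        for f in features
        if f.gene_label == RHODOPSIN_LABEL
    ) or any(
        f.expected_subtree == "III" and f.expected_brp_adjacent
        for f in features
        if f.gene_label == RHODOPSIN_LABEL
    )
    if has_pgc and has_pump:
        return "dual"
    if has_pgc:
        return "pgc_only"
    if has_pump:
        return "rhodopsin_only"
    return "none"


# ---------------------------------------------------------------------------
# Collection generation
# ---------------------------------------------------------------------------

@dataclass
class CollectionConfig:
    """Study-shaped defaults, scaled to desk size.

    Fourteen metagenomes mirror the fourteen cultures; each holds one
    GC-rich host genome plus a handful of associated MAGs. Genome sizes
    are tens of kb rather than Mb so that the exact-DP screen stays
    fast; coverage is log-normal with the host drawn at a configurable
    multiple of the associated-MAG median.
    """

    n_metagenomes: int = 14
    mags_per_metagenome: tuple[int, int] = (3, 6)  # inclusive range incl. host
    background_bp: tuple[int, int] = (9000, 15000)
    host_background_bp: int = 12000
    host_gc: float = 0.69
    associated_gc: tuple[float, float] = (0.40, 0.62)
    coverage_sigma: float = 1.0
    coverage_median: float = 20.0
    host_multiplier: float = 5.0
    feature_mix: dict | None = None  # metagenome index (1-based) -> [PlantSpec]


def default_feature_mix() -> dict[int, list[PlantSpec]]:
    """One stated planted-feature plan per metagenome.

    Covers every variant class the classifier distinguishes: complete /
    rearranged / partial / puf-less / split PGCs, PR and XR operons, the
    E96Q and K292A variants, the NDQ Na-pump decoy, a pump without any
    retinal gene, and a solitary rhodopsin with brp/blh elsewhere in the
    genome.
    """
    xr_operon = PlantSpec(kind="rhodopsin_operon", subtree="III",
                          operon_genes=(RHODOPSIN_LABEL, "crtY", BRP_BLH_LABEL))
    return {
        1: [PlantSpec(kind="pgc"), xr_operon],  # dual phototroph
        2: [PlantSpec(kind="pgc")],  # complete PGC
        3: [PlantSpec(kind="pgc",
                      pgc_rearrangement=invert_block(len(PGC_SYMBOLS), 12, 21))],
        4: [PlantSpec(kind="pgc", pgc_genes=PGC_SYMBOLS[10:31])],  # partial, passes
        5: [PlantSpec(kind="pgc",
                      pgc_genes=tuple(s for s in PGC_SYMBOLS
                                      if not s.startswith("puf")))],  # no puf -> no PGC
        6: [PlantSpec(kind="rhodopsin_operon", subtree="I",
                      operon_genes=(RHODOPSIN_LABEL, BRP_BLH_LABEL))],
        7: [PlantSpec(kind="rhodopsin_operon", subtree="III",
                      operon_genes=(RHODOPSIN_LABEL, "crtE", "crtB", "crtY",
                                    BRP_BLH_LABEL))],
        8: [PlantSpec(kind="rhodopsin_operon", subtree="II",
                      operon_genes=(RHODOPSIN_LABEL, BRP_BLH_LABEL),
                      overrides={96: "Q"})],  # E96Q still pumps
        9: [PlantSpec(kind="solitary_rhodopsin", subtree="I",
                      overrides={292: "A"})],  # K292A -> divergent
        10: [PlantSpec(kind="na_pump", subtree="II", overrides=dict(NA_PUMP_OVERRIDES))],
        11: [PlantSpec(kind="solitary_rhodopsin", subtree="I")],  # no blh anywhere
        12: [PlantSpec(kind="solitary_rhodopsin", subtree="III"),
             PlantSpec(kind="brp_blh_only")],  # blh elsewhere in the genome
        13: [PlantSpec(kind="pgc", split_across_contigs=True)],
        14: [],
    }


@dataclass
class SyntheticCollection:
    mags: list[GenomeBin]
    coverage: pd.DataFrame  # mag_id, metagenome_id, mapped_bases
    qc: pd.DataFrame  # mag_id, completeness, contamination
    taxonomy: pd.DataFrame  # mag_id, lineage
    truth: TruthManifest

    @property
    def hosts(self) -> dict[str, str]:
        """metagenome_id -> host mag_id."""
        return {m.metagenome_id: m.mag_id for m in self.mags if m.is_host}


_HOST_LINEAGE = (
    "Bacteria;Cyanobacteriota;Cyanophyceae;Oscillatoriales;"
    "Coleofasciculaceae;Coleofasciculus;Coleofasciculus sp."
)
_COMMON_LINEAGE = (
    "Bacteria;Pseudomonadota;Alphaproteobacteria;Rhodobacterales;"
    "Roseobacteraceae;Marinovum;Marinovum sp. SYN"
)
#: the designated common housemate occurs in this many metagenomes
COMMON_TAXON_METAGENOMES = 12

_PHYLA = ("Pseudomonadota", "Bacteroidota", "Planctomycetota", "Actinomycetota")


def _filler_lineage(rng: np.random.Generator, mag_id: str) -> str:
    phylum = _PHYLA[int(rng.integers(len(_PHYLA)))]
    genus = f"Genus{int(rng.integers(1, 9))}"
    return (
        f"Bacteria;{phylum};Class_{phylum[:4]};Order_{phylum[:4]};"
        f"Family_{phylum[:4]};{genus};{genus} sp. {mag_id}"
    )


def generate_collection(
    config: CollectionConfig | None = None, rng_seed: int = 0
) -> SyntheticCollection:
    """Generate a full synthetic MAG collection with coverage/QC/taxonomy
    tables and the truth manifest. Deterministic in (config, seed)."""
    cfg = config or CollectionConfig()
    mix = cfg.feature_mix if cfg.feature_mix is not None else default_feature_mix()
    root = np.random.SeedSequence(rng_seed)
    mags: list[GenomeBin] = []
    truth = TruthManifest(seed=rng_seed, params={"n_metagenomes": cfg.n_metagenomes})
    cov_rows = []
    qc_rows = []
    tax_rows = []
    for mi in range(1, cfg.n_metagenomes + 1):
        meta_id = f"C{mi:02d}"
        rng = np.random.default_rng(root.spawn(1)[0])
        specs_here = list(mix.get(mi, []))
        n_mags = int(rng.integers(cfg.mags_per_metagenome[0],
                                  cfg.mags_per_metagenome[1] + 1))
        n_mags = max(n_mags, 1 + (1 if specs_here else 0))
        # host
        host_id = f"H1-{meta_id}-01"
        host, host_feats = build_mag(
            host_id, meta_id, [], cfg.host_background_bp, cfg.host_gc, rng,
            is_host=True,
        )
        mags.append(host)
        truth.mag_modes[host_id] = "cyano_oxygenic"
        tax_rows.append({"mag_id": host_id, "lineage": _HOST_LINEAGE})
        # associated MAGs; the first carries this metagenome's planted features
        for ai in range(2, n_mags + 1):
            mag_id = f"A{ai - 1}-{meta_id}-{ai:02d}"
            specs = specs_here if ai == 2 else []
            bg = int(rng.integers(cfg.background_bp[0], cfg.background_bp[1] + 1))
            gc = float(rng.uniform(*cfg.associated_gc))
            mag, feats = build_mag(mag_id, meta_id, specs, bg, gc, rng)
            mags.append(mag)
            truth.features.extend(feats)
            truth.mag_modes[mag_id] = expected_mode(specs, feats, is_host=False)
            if ai == 3 and mi <= COMMON_TAXON_METAGENOMES:
                tax_rows.append({"mag_id": mag_id, "lineage": _COMMON_LINEAGE})
            else:
                tax_rows.append({"mag_id": mag_id, "lineage": _filler_lineage(rng, mag_id)})
        # coverage: log-normal around the median, host at a multiple
        for mag in mags:
            if mag.metagenome_id != meta_id:
                continue
            if mag.is_host:
                coverage = cfg.coverage_median * cfg.host_multiplier
            else:
                coverage = float(
                    cfg.coverage_median
                    * np.exp(rng.normal(0.0, cfg.coverage_sigma))
                )
            cov_rows.append(
                {
                    "mag_id": mag.mag_id,
                    "metagenome_id": meta_id,
                    "mapped_bases": coverage * mag.genome_size,
                }
            )
            qc_rows.append(
                {
                    "mag_id": mag.mag_id,
                    "completeness": round(float(rng.uniform(82, 99)), 2),
                    "contamination": round(float(rng.uniform(0, 8)), 2),
                }
            )
    return SyntheticCollection(
        mags=mags,
        coverage=pd.DataFrame(cov_rows),
        qc=pd.DataFrame(qc_rows),
        taxonomy=pd.DataFrame(tax_rows),
        truth=truth,
    )


def write_collection(collection: SyntheticCollection, outdir: str | Path) -> Path:
    """Write the collection as the file set the pipeline consumes."""
    outdir = Path(outdir)
    (outdir / "fasta").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for mag in collection.mags:
        fasta = outdir / "fasta" / f"{mag.mag_id}.fna"
        write_fasta(mag.contigs, fasta)
        manifest_rows.append(
            {
                "mag_id": mag.mag_id,
                "metagenome_id": mag.metagenome_id,
                "fasta_path": str(Path("fasta") / fasta.name),
                "is_host": int(mag.is_host),
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    collection.coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    collection.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    collection.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    collection.truth.to_table().to_csv(outdir / "truth_manifest.tsv", sep="\t", index=False)
    with open(outdir / "truth_manifest.json", "w") as fh:
        json.dump(
            {
                "seed": collection.truth.seed,
                "mag_modes": collection.truth.mag_modes,
                "expected_venn": collection.truth.expected_venn(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return outdir
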