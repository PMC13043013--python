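"""Translated homology screening of MAG contigs against protein panels.

This is the package's stand-in for a TBLASTN screen: contigs are
translated in all six frames, maximal stop-to-stop open reading frames
are extracted, and each ORF is aligned against every reference protein
of a panel with exact affine-gap dynamic programming (Smith–Waterman
locally, Needleman–Wunsch globally) under BLOSUM62. Hits pass on
identity, query coverage and raw score rather than E-values: no database
size is well defined for a single MAG, so fixed thresholds substitute.

The reference protein is always the *query*: identity and coverage are
measured on the reference, as in a TBLASTN search driven by a bait
protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import GeneFeature, GenomeBin, SequenceRecord, reverse_complement

logger = logging.getLogger("cyanophot")

#: default screen thresholds — conventional remote-homology working point
DEFAULT_MIN_IDENTITY = 0.30
DEFAULT_MIN_QUERY_COV = 0.50
DEFAULT_MIN_SCORE = 60
DEFAULT_MIN_ORF_AA = 60
DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

GENETIC_CODE_TABLE = 11  # bacterial


@dataclass(frozen=True)
class ORF:
    """A maximal stop-to-stop reading frame on a contig.

    ``start``/``end`` are nucleotide coordinates on the forward strand
    (0-based half-open); ``frame`` is +1..+3 on the forward strand and
    -1..-3 on the reverse complement. The protein excludes the stop and
    contains no internal stop.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if len(self.protein) != (self.end - self.start) // 3:
            raise ValueError("protein length inconsistent with nucleotide span")
        if "*" in self.protein:
            raise ValueError("ORF protein contains an internal stop")


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float
    query_cov: float
    query_span: tuple[int, int]  # 0-based half-open on the query
    target_span: tuple[int, int]
    aligned_query: str
    aligned_target: str


@dataclass(frozen=True)
class ProteinHit:
    """A reference protein matched on a MAG contig through an ORF."""

    reference_id: str
    mag_id: str
    contig_id: str
    orf: ORF
    alignment: AlignmentResult
    gene_label: str

    def to_feature(self) -> GeneFeature:
        """Genomic footprint of the aligned target region, forward-strand coords."""
        t0, t1 = self.alignment.target_span
        if self.orf.strand == "+":
            start = self.orf.start + 3 * t0
            end = self.orf.start + 3 * t1
        else:
            end = self.orf.end - 3 * t0
            start = self.orf.end - 3 * t1
        return GeneFeature(
            contig_id=self.contig_id,
            start=start,
            end=end,
            strand=self.orf.strand,
            label=self.gene_label,
            source="predicted",
        )


# ---------------------------------------------------------------------------
# Translation and ORF calling
# ---------------------------------------------------------------------------

def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate ``seq`` in all six frames (bacterial code, stops as ``*``).

    Frames +1..+3 read the forward strand from offsets 0..2; frames
    -1..-3 read the reverse complement from offsets 0..2. Trailing
    partial codons are dropped; short sequences yield empty frames.
    """
    out: dict[int, str] = {}
    rc = reverse_complement(seq)
    for offset in range(3):
        for frame_sign, s in ((1, seq), (-1, rc)):
            sub = s[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frame = frame_sign * (offset + 1)
            out[frame] = str(Seq(sub).translate(table=GENETIC_CODE_TABLE)) if sub else ""
    return out


def call_orfs(seq: str, contig_id: str = "contig", min_aa: int = DEFAULT_MIN_ORF_AA) -> list[ORF]:
    """Extract maximal stop-to-stop ORFs of at least ``min_aa`` residues.

    Contig ends are treated as open: a reading frame running into the end
    of the contig counts as an ORF without requiring a stop codon.
    Coordinates are reported on the forward strand.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(seq)
    orfs: list[ORF] = []
    for frame, protein in six_frame_translate(seq).items():
        if not protein:
            continue
        offset = abs(frame) - 1
        # split on stops, keeping track of codon indices
        segment_start = 0  # codon index of current segment start
        for i, ch in enumerate(protein + "*"):
            if ch != "*":
                continue
            seg = protein[segment_start:i]
            if len(seg) >= min_aa:
                # codon indices [segment_start, i) within this frame
                if frame > 0:
                    start = offset + 3 * segment_start
                    end = offset + 3 * i
                else:
                    # frame on reverse complement: codon j covers rc[offset+3j : offset+3j+3],
                    # which is seq[n-offset-3j-3 : n-offset-3j] on the forward strand
                    end = n - offset - 3 * segment_start
                    start = n - offset - 3 * i
                orfs.append(
                    ORF(
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        strand="+" if frame > 0 else "-",
                        frame=frame,
                        protein=seg,
                    )
                )
            segment_start = i + 1
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def _make_aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = mode
    # affine cost: first gapped residue costs gap_open, each further one gap_extend
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _result_from_alignment(alignment, query: str, target: str) -> AlignmentResult:
    aq, at = alignment[0], alignment[1]
    matches = sum(1 for a, b in zip(aq, at) if a == b and a != "-")
    ncols = len(aq)
    identity = matches / ncols if ncols else 0.0
    q0, q1 = int(alignment.coordinates[0][0]), int(alignment.coordinates[0][-1])
    t0, t1 = int(alignment.coordinates[1][0]), int(alignment.coordinates[1][-1])
    return AlignmentResult(
        score=float(alignment.score),
        identity=identity,
        query_cov=(q1 - q0) / len(query) if query else 0.0,
        query_span=(q0, q1),
        target_span=(t0, t1),
        aligned_query=str(aq),
        aligned_target=str(at),
    )


def local_align(
    query: str,
    target: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment with affine gap penalties.

    Among co-optimal alignments the aligner's first traceback is taken,
    which is deterministic across runs and platforms. Unknown residues
    score through the matrix's X column. A query/target pair with no
    positive-scoring alignment yields a zero-score empty result.
    """
    if not query or not target:
        raise ValueError("local_align requires nonempty query and target")
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)
    alignments = aligner.align(query, target)
    if alignments.score <= 0:
        return AlignmentResult(0.0, 0.0, 0.0, (0, 0), (0, 0), "", "")
    return _result_from_alignment(alignments[0], query, target)


def global_align(
    query: str,
    target: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Needleman–Wunsch global alignment, end gaps penalized."""
    if not query or not target:
        raise ValueError("global_align requires nonempty query and target")
    aligner = _make_aligner("global", matrix, gap_open, gap_extend)
    alignments = aligner.align(query, target)
    return _result_from_alignment(alignments[0], query, target)


def rescore_alignment(
    aligned_query: str,
    aligned_target: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Recompute the affine-gap score of a gapped alignment pair.

    Used by tests to check that every reported score is reproducible from
    its own gapped strings.
    """
    mat = substitution_matrices.load(matrix)
    score = 0.0
    in_gap_q = in_gap_t = False
    for a, b in zip(aligned_query, aligned_target):
        if a == "-":
            score -= gap_open if not in_gap_q else gap_extend
            in_gap_q, in_gap_t = True, False
        elif b == "-":
            score -= gap_open if not in_gap_t else gap_extend
            in_gap_t, in_gap_q = True, False
        else:
            score += mat[a, b]
            in_gap_q = in_gap_t = False
    return score


# ---------------------------------------------------------------------------
# Genome screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelEntry:
    """A reference protein with its gene-family label (header ``id|label``)."""

    reference_id: str
    gene_label: str
    protein: str


def load_panel(records: Sequence[SequenceRecord]) -> list[PanelEntry]:
    """Interpret protein FASTA records with ``<accession>|<gene_label>`` headers."""
    panel = []
    for rec in records:
        if "|" in rec.id:
            acc, label = rec.id.split("|", 1)
        else:
            acc, label = rec.id, rec.id
        panel.append(PanelEntry(reference_id=acc, gene_label=label, protein=rec.seq))
    return panel


@dataclass
class ScreenThresholds:
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_query_cov: float = DEFAULT_MIN_QUERY_COV
    min_score: float = DEFAULT_MIN_SCORE
    min_orf_aa: int = DEFAULT_MIN_ORF_AA
    matrix: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND


def screen_genome(
    mag: GenomeBin,
    panel: Sequence[PanelEntry],
    thresholds: ScreenThresholds | None = None,
) -> list[ProteinHit]:
    """Screen every ORF of a MAG against every panel protein.

    A hit is kept when identity >= min_identity AND query coverage >=
    min_query_cov AND score >= min_score. Overlapping hits to the same
    gene family on the same strand are dereplicated keeping the best
    score. Scores are computed for every (ORF, reference) pair with a
    score-only pass; the full alignment is only built for pairs that
    clear min_score.
    """
    if not panel:
        raise ValueError("reference panel must be nonempty")
    th = thresholds or ScreenThresholds()
    if not mag.contigs:
        logger.warning("screen_empty_mag mag_id=%s", mag.mag_id)
        return []
    score_aligner = _make_aligner("local", th.matrix, th.gap_open, th.gap_extend)
    hits: list[ProteinHit] = []
    for contig in mag.contigs:
        orfs = call_orfs(contig.seq, contig_id=contig.id, min_aa=th.min_orf_aa)
        for orf in orfs:
            for entry in panel:
                score = score_aligner.score(entry.protein, orf.protein)
                if score < th.min_score:
                    continue
                aln = local_align(
                    entry.protein, orf.protein, th.matrix, th.gap_open, th.gap_extend
                )
                if aln.identity >= th.min_identity and aln.query_cov >= th.min_query_cov:
                    hits.append(
                        ProteinHit(
                            reference_id=entry.reference_id,
                            mag_id=mag.mag_id,
                            contig_id=contig.id,
                            orf=orf,
                            alignment=aln,
                            gene_label=entry.gene_label,
                        )
                    )
    return dereplicate_hits(hits)


def dereplicate_hits(hits: Sequence[ProteinHit]) -> list[ProteinHit]:
    """Within each gene family, drop hits overlapping a better-scoring hit."""
    kept: list[ProteinHit] = []
    by_family: dict[str, list[ProteinHit]] = {}
    for h in hits:
        by_family.setdefault(h.gene_label, []).append(h)
    for family_hits in by_family.values():
        family_hits.sort(
            key=lambda h: (-h.alignment.score, h.contig_id, h.to_feature().start)
        )
        chosen: list[ProteinHit] = []
        for h in family_hits:
            feat = h.to_feature()
            if not any(feat.overlaps(c.to_feature()) for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.mag_id, h.contig_id, h.to_feature().start, h.gene_label))
    return kept


def hits_to_table(hits: Sequence[ProteinHit]):
    """Hit list as a pandas DataFrame matching the TSV export schema."""
    import pandas as pd

    rows = []
    for h in hits:
        feat = h.to_feature()
        rows.append(
            {
                "mag_id": h.mag_id,
                "contig_id": h.contig_id,
                "reference_id": h.reference_id,
                "gene_label": h.gene_label,
                "start": feat.start,
                "end": feat.end,
                "strand": h.orf.strand,
                "frame": h.orf.frame,
                "score": h.alignment.score,
                "identity": round(h.alignment.identity, 4),
                "query_cov": round(h.alignment.query_cov, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id",
            "contig_id",
            "reference_id",
            "gene_label",
            "start",
            "end",
            "strand",
            "frame",
            "score",
            "identity",
            "query_cov",
        ],
    )
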