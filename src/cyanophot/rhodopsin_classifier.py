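"""Classification of rhodopsin hits as light-driven proton pumps.

Each rhodopsin hit found by the translated screen is (i) assigned to one
of three proteorhodopsin/xanthorhodopsin subtrees by its nearest labeled
reference, (ii) profiled at diagnostic anchor positions — the D/T/E
proton-transfer triad at 85/89/96, the carotenoid-antenna glycine at
156, and the retinal-binding lysine at 292 — and (iii) placed in its
operon context (adjacent brp/blh retinal-production gene and carotenoid
biosynthesis genes). The functional call combines all three lines of
evidence:

* an N/D/Q triad marks a Na-pumping rhodopsin and excludes the record;
* a missing retinal-binding lysine marks a fast-evolving homolog of
  unknown function;
* otherwise a subtree-assigned rhodopsin whose genome also encodes
  brp/blh is a bona fide proton pump — a divergent position 96 alone
  does not disqualify (the *E. sibiricum*-branch pumps lack it);
* a pump candidate without genomic brp/blh stays a candidate.

A carotenoid antenna is predicted for subtree I/III records that retain
G-156. Positions are anchor-relative: numbering is defined by the
configured anchor sequence of the assigned subtree, not by any absolute
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GeneFeature
from .orf_homology import ProteinHit, global_align
from .references import (
    BRP_BLH_LABEL,
    RHODOPSIN_LABEL,
    RHODOPSIN_OPERON_CRT,
    rhodopsin_reference_panel,
)

logger = logging.getLogger("cyanophot")

DEFAULT_POSITIONS = {"res85": 85, "res89": 89, "res96": 96, "res156": 156, "res292": 292}
DEFAULT_WINDOW_BP = 5000
MIN_ANCHOR_IDENTITY = 0.15
LOW_CONFIDENCE_MARGIN = 0.05  # fraction of the best score


@dataclass(frozen=True)
class ResidueMap:
    """Anchor-position -> (hit position, residue) mapping from a global alignment.

    Anchor positions are 1-based over the full anchor; positions whose
    anchor column aligns to a gap in the hit map to ``None``. Hit
    positions are 1-based and strictly increasing over mapped entries.
    """

    anchor_id: str
    pairs: dict[int, tuple[int, str] | None]

    def residue_at(self, anchor_pos: int) -> str | None:
        entry = self.pairs.get(anchor_pos)
        return entry[1] if entry else None


@dataclass(frozen=True)
class DiagnosticProfile:
    res85: str | None
    res89: str | None
    res96: str | None
    res156: str | None
    retinal_lysine: str | None

    @property
    def has_DTE(self) -> bool:
        return self.res85 == "D" and self.res89 == "T" and self.res96 == "E"

    @property
    def has_retinal_K(self) -> bool:
        return self.retinal_lysine == "K"

    @property
    def has_G156(self) -> bool:
        return self.res156 == "G"

    @property
    def na_pump_motif(self) -> bool:
        """NDQ triad at 85/89/96 — the established Na-pump motif."""
        return self.res85 == "N" and self.res89 == "D" and self.res96 == "Q"


@dataclass(frozen=True)
class OperonContext:
    neighbors: tuple[GeneFeature, ...]
    brp_blh_adjacent: bool
    brp_blh_in_genome: bool
    crt_genes: frozenset[str]
    na_pump_motif: bool


@dataclass(frozen=True)
class RhodopsinRecord:
    hit: ProteinHit
    subtree: str  # {"I", "II", "III"}
    subtree_margin: float
    low_confidence: bool
    profile: DiagnosticProfile
    context: OperonContext
    call: str  # {bona_fide_pump, candidate_pump, na_pump_excluded, divergent_unknown}
    carotenoid_antenna_predicted: bool


# ---------------------------------------------------------------------------
# Anchor mapping and residue profiling
# ---------------------------------------------------------------------------

def anchor_map(hit_protein: str, anchor_reference: str, anchor_id: str = "anchor") -> ResidueMap:
    """Map anchor positions onto a hit protein via global alignment."""
    if not hit_protein or not anchor_reference:
        raise ValueError("anchor_map requires nonempty sequences")
    aln = global_align(anchor_reference, hit_protein)
    if aln.identity < MIN_ANCHOR_IDENTITY:
        raise ValueError(
            f"anchor mapping unreliable: identity {aln.identity:.3f} < "
            f"{MIN_ANCHOR_IDENTITY}"
        )
    pairs: dict[int, tuple[int, str] | None] = {}
    anchor_pos = 0  # 1-based after increment
    hit_pos = 0
    for a, h in zip(aln.aligned_query, aln.aligned_target):
        if h != "-":
            hit_pos += 1
        if a != "-":
            anchor_pos += 1
            pairs[anchor_pos] = (hit_pos, h) if h != "-" else None
    # columns before/after the aligned span (global: none, but be safe)
    for p in range(1, len(anchor_reference) + 1):
        pairs.setdefault(p, None)
    return ResidueMap(anchor_id=anchor_id, pairs=pairs)


def extract_profile(
    residue_map: ResidueMap, positions: Mapping[str, int] | None = None
) -> DiagnosticProfile:
    """Read the diagnostic residues off a residue map."""
    pos = dict(DEFAULT_POSITIONS if positions is None else positions)
    return DiagnosticProfile(
        res85=residue_map.residue_at(pos["res85"]),
        res89=residue_map.residue_at(pos["res89"]),
        res96=residue_map.residue_at(pos["res96"]),
        res156=residue_map.residue_at(pos["res156"]),
        retinal_lysine=residue_map.residue_at(pos["res292"]),
    )


# ---------------------------------------------------------------------------
# Subtree assignment
# ---------------------------------------------------------------------------

def assign_subtree(
    hit_protein: str,
    reference_panel: Sequence[tuple[str, str]] | None = None,
) -> tuple[str, float, bool]:
    """Nearest-reference subtree label.

    ``reference_panel`` is a sequence of (subtree label, protein) pairs
    with at least one reference per subtree. Returns (label, margin,
    low_confidence); margin is best minus second-best score across
    *different* labels, and the low-confidence flag is raised when the
    margin is below 5% of the best score (e.g. for chimeric sequences).
    """
    panel = list(reference_panel) if reference_panel is not None else rhodopsin_reference_panel()
    if not panel:
        raise ValueError("subtree reference panel is empty")
    best_by_label: dict[str, float] = {}
    for label, prot in panel:
        score = global_align(hit_protein, prot).score
        if label not in best_by_label or score > best_by_label[label]:
            best_by_label[label] = score
    ranked = sorted(best_by_label.items(), key=lambda kv: (-kv[1], kv[0]))
    label, best = ranked[0]
    margin = best - ranked[1][1] if len(ranked) > 1 else float("inf")
    low_conf = best <= 0 or (len(ranked) > 1 and margin < LOW_CONFIDENCE_MARGIN * best)
    return label, margin, low_conf


# ---------------------------------------------------------------------------
# Operon context
# ---------------------------------------------------------------------------

def operon_context(
    hit_feature: GeneFeature,
    features: Sequence[GeneFeature],
    profile: DiagnosticProfile,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> OperonContext:
    """Neighborhood of a rhodopsin gene within ``window_bp``, any strand.

    ``features`` must contain the hit feature itself and should span the
    whole MAG, so the genome-wide brp/blh clause can be evaluated.
    """
    if hit_feature not in features:
        raise ValueError("hit feature absent from the MAG feature set")
    neighbors = tuple(
        f
        for f in features
        if f != hit_feature
        and f.contig_id == hit_feature.contig_id
        and f.start < hit_feature.end + window_bp
        and f.end > hit_feature.start - window_bp
    )
    neighbor_labels = {f.label for f in neighbors}
    brp_adjacent = BRP_BLH_LABEL in neighbor_labels
    brp_in_genome = brp_adjacent or any(f.label == BRP_BLH_LABEL for f in features)
    crt = frozenset(neighbor_labels & set(RHODOPSIN_OPERON_CRT))
    return OperonContext(
        neighbors=neighbors,
        brp_blh_adjacent=brp_adjacent,
        brp_blh_in_genome=brp_in_genome,
        crt_genes=crt,
        na_pump_motif=profile.na_pump_motif,
    )


# ---------------------------------------------------------------------------
# Functional call
# ---------------------------------------------------------------------------

def call_function(
    subtree: str, profile: DiagnosticProfile, context: OperonContext
) -> tuple[str, bool]:
    """Combine subtree, residues and operon context into a functional call."""
    antenna = profile.has_G156 and subtree in {"I", "III"}
    if context.na_pump_motif:
        return "na_pump_excluded", antenna
    if not profile.has_retinal_K:
        return "divergent_unknown", antenna
    if subtree and context.brp_blh_in_genome:
        return "bona_fide_pump", antenna
    return "candidate_pump", antenna


def classify_rhodopsins(
    hits: Sequence[ProteinHit],
    mag_features: Sequence[GeneFeature],
    reference_panel: Sequence[tuple[str, str]] | None = None,
    positions: Mapping[str, int] | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[RhodopsinRecord]:
    """Classify every rhodopsin hit of one MAG.

    ``hits`` are this MAG's protein hits (only ``rhodopsin``-labeled ones
    are classified); ``mag_features`` is the full predicted/annotated
    feature set of the MAG including the rhodopsin features themselves.
    """
    panel = list(reference_panel) if reference_panel is not None else rhodopsin_reference_panel()
    anchors = {label: prot for label, prot in panel}
    records: list[RhodopsinRecord] = []
    for hit in hits:
        if hit.gene_label != RHODOPSIN_LABEL:
            continue
        t0, t1 = hit.alignment.target_span
        protein = hit.orf.protein[t0:t1]
        subtree, margin, low_conf = assign_subtree(protein, panel)
        rmap = anchor_map(protein, anchors[subtree], anchor_id=subtree)
        profile = extract_profile(rmap, positions)
        context = operon_context(hit.to_feature(), mag_features, profile, window_bp)
        call, antenna = call_function(subtree, profile, context)
        records.append(
            RhodopsinRecord(
                hit=hit,
                subtree=subtree,
                subtree_margin=margin,
                low_confidence=low_conf,
                profile=profile,
                context=context,
                call=call,
                carotenoid_antenna_predicted=antenna,
            )
        )
    return records


def records_to_table(records: Sequence[RhodopsinRecord]):
    """Per-hit classification table matching the TSV export schema."""
    import pandas as pd

    rows = []
    for r in records:
        feat = r.hit.to_feature()
        rows.append(
            {
                "mag_id": r.hit.mag_id,
                "contig_id": r.hit.contig_id,
                "reference_id": r.hit.reference_id,
                "subtree": r.subtree,
                "res85": r.profile.res85 or ".",
                "res89": r.profile.res89 or ".",
                "res96": r.profile.res96 or ".",
                "res156": r.profile.res156 or ".",
                "resK": r.profile.retinal_lysine or ".",
                "call": r.call,
                "antenna": int(r.carotenoid_antenna_predicted),
                "brp_blh_adjacent": int(r.context.brp_blh_adjacent),
                "brp_blh_in_genome": int(r.context.brp_blh_in_genome),
                "crt_genes": ",".join(sorted(r.context.crt_genes)) or ".",
                "low_confidence": int(r.low_confidence),
                "start": feat.start,
                "end": feat.end,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id", "contig_id", "reference_id", "subtree",
            "res85", "res89", "res96", "res156", "resK",
            "call", "antenna", "brp_blh_adjacent", "brp_blh_in_genome",
            "crt_genes", "low_confidence", "start", "end",
        ],
    )
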