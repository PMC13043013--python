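"""Photosynthesis gene cluster (PGC) inventory and synteny comparison.

A PGC is the ~45 kb cluster encoding bacteriochlorophyll biosynthesis
(*bch*), carotenoid biosynthesis (*crt*), reaction-center/light-
harvesting (*puf*/*puh*) genes and cytochrome c2 (*cycA*). Genes found
in a MAG are numbered against an ordered reference cluster (D. shibae
DFL 12 symbols); rearrangements between two clusters are counted as
signed adjacency breakpoints — an adjacency of two genes in one
cluster, taken with strand, that is not conserved in the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import GeneFeature, GenomeBin
from .orf_homology import ProteinHit
from .references import PGC_REFERENCE_GENES

DEFAULT_COMPLETENESS_FLOOR = 0.5
DEFAULT_MAX_SPAN_BP = 80_000


@dataclass(frozen=True)
class PGCReference:
    """Ordered reference gene list with per-gene class and 1-based index."""

    genes: tuple[tuple[str, str], ...]  # (symbol, class) in reference order

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(sym for sym, _ in self.genes)

    def index_of(self, symbol: str) -> int:
        return self.symbols.index(symbol) + 1

    def gene_class(self, symbol: str) -> str:
        for sym, cls in self.genes:
            if sym == symbol:
                return cls
        return "nonconserved"

    def __len__(self) -> int:
        return len(self.genes)


DEFAULT_PGC_REFERENCE = PGCReference(genes=PGC_REFERENCE_GENES)


@dataclass
class PGCInventory:
    mag_id: str
    genes_found: list[GeneFeature]  # sorted by (contig, start)
    completeness: float
    has_pgc: bool
    contiguous: bool
    span: tuple[str, int, int] | None  # (contig, start, end) when contiguous
    order_vector: list[int]  # signed 1-based reference indices in genomic order
    class_tallies: dict[str, int]
    reference: PGCReference = DEFAULT_PGC_REFERENCE


@dataclass
class SyntenyComparison:
    mag_a: str
    mag_b: str
    shared_genes: int
    breakpoints: int | None  # None when no shared genes
    rearranged_blocks: int | None


# ---------------------------------------------------------------------------
# Inventory
# ---------------------------------------------------------------------------

def inventory_pgc(
    hits: Sequence[ProteinHit],
    mag: GenomeBin,
    reference: PGCReference = DEFAULT_PGC_REFERENCE,
    completeness_floor: float = DEFAULT_COMPLETENESS_FLOOR,
    max_span_bp: int = DEFAULT_MAX_SPAN_BP,
) -> PGCInventory:
    """Build the PGC inventory of one MAG from its dereplicated hits.

    A MAG "has a PGC" when both reaction-center genes *pufL* and *pufM*
    are present and the fraction of reference genes found reaches the
    completeness floor. The cluster is contiguous when all its genes lie
    on one contig within ``max_span_bp``.
    """
    ref_symbols = set(reference.symbols)
    feats = [
        h.to_feature() for h in hits if h.mag_id == mag.mag_id and h.gene_label in ref_symbols
    ]
    feats.sort(key=lambda f: (f.contig_id, f.start))
    found_symbols = {f.label for f in feats}
    completeness = len(found_symbols) / len(reference) if len(reference) else 0.0
    has_pgc = (
        {"pufL", "pufM"} <= found_symbols and completeness >= completeness_floor
    )
    contigs = {f.contig_id for f in feats}
    span = None
    contiguous = False
    if feats and len(contigs) == 1:
        start = min(f.start for f in feats)
        end = max(f.end for f in feats)
        if end - start <= max_span_bp:
            contiguous = True
            span = (next(iter(contigs)), start, end)
    order_vector = [
        reference.index_of(f.label) * (1 if f.strand == "+" else -1) for f in feats
    ]
    tallies: dict[str, int] = {}
    for sym in found_symbols:
        cls = reference.gene_class(sym)
        tallies[cls] = tallies.get(cls, 0) + 1
    return PGCInventory(
        mag_id=mag.mag_id,
        genes_found=feats,
        completeness=completeness,
        has_pgc=has_pgc,
        contiguous=contiguous,
        span=span,
        order_vector=order_vector,
        class_tallies=tallies,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

def _canonical_adjacency(x: int, y: int) -> tuple[int, int]:
    """Signed adjacency up to reading direction: (x, y) == (-y, -x)."""
    return min((x, y), (-y, -x))


def signed_adjacencies(order: Sequence[int]) -> set[tuple[int, int]]:
    return {_canonical_adjacency(x, y) for x, y in zip(order, order[1:])}


def breakpoint_count(order_a: Sequence[int], order_b: Sequence[int]) -> int:
    """Signed adjacencies of ``order_a`` absent from ``order_b``.

    Both orders must be signed permutations of the same element set.
    """
    return len(signed_adjacencies(order_a) - signed_adjacencies(order_b))


def synteny_compare(a: PGCInventory, b: PGCInventory) -> SyntenyComparison:
    """Compare two PGC inventories restricted to their shared gene symbols."""
    syms_a = {abs(i) for i in a.order_vector}
    syms_b = {abs(i) for i in b.order_vector}
    shared = syms_a & syms_b
    if not shared:
        return SyntenyComparison(a.mag_id, b.mag_id, 0, None, None)
    order_a = [i for i in a.order_vector if abs(i) in shared]
    order_b = [i for i in b.order_vector if abs(i) in shared]
    bp = breakpoint_count(order_a, order_b)
    # maximal runs of a whose internal adjacencies are all conserved in b
    adj_b = signed_adjacencies(order_b)
    blocks = 1
    for x, y in zip(order_a, order_a[1:]):
        if _canonical_adjacency(x, y) not in adj_b:
            blocks += 1
    return SyntenyComparison(a.mag_id, b.mag_id, len(shared), bp, blocks)


def export_synteny_plot_data(
    comparison: SyntenyComparison, inventories: Sequence[PGCInventory]
) -> pd.DataFrame:
    """Plot-ready per-gene table for a synteny figure.

    One row per gene and MAG with its class color key, genomic interval,
    strand and reference index; deterministic ordering by (mag, contig,
    start).
    """
    rows = []
    for inv in inventories:
        for feat in inv.genes_found:
            cls = inv.reference.gene_class(feat.label)
            rows.append(
                {
                    "mag_id": inv.mag_id,
                    "symbol": feat.label,
                    "gene_class": cls,
                    "contig": feat.contig_id,
                    "start": feat.start,
                    "end": feat.end,
                    "strand": feat.strand,
                    "ref_index": inv.reference.index_of(feat.label)
                    if feat.label in inv.reference.symbols
                    else 0,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "mag_id", "symbol", "gene_class", "contig",
            "start", "end", "strand", "ref_index",
        ],
    )
    if not df.empty:
        df = df.sort_values(["mag_id", "contig", "start"], kind="mergesort").reset_index(
            drop=True
        )
    return df


def inventory_to_table(inventories: Sequence[PGCInventory]) -> pd.DataFrame:
    rows = []
    for inv in inventories:
        for feat in inv.genes_found:
            rows.append(
                {
                    "mag_id": inv.mag_id,
                    "symbol": feat.label,
                    "gene_class": inv.reference.gene_class(feat.label),
                    "contig": feat.contig_id,
                    "start": feat.start,
                    "end": feat.end,
                    "strand": feat.strand,
                    "ref_index": inv.reference.index_of(feat.label),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id", "symbol", "gene_class", "contig",
            "start", "end", "strand", "ref_index",
        ],
    )
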