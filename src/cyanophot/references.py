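"""Synthetic reference panels: PGC gene families and rhodopsin anchors.

The published reference material for this analysis — the PufM bait
protein, one rhodopsin reference per phylogenetic subtree, and the
*Dinoroseobacter shibae* DFL 12 photosynthesis gene cluster (PGC) used
for gene numbering — are database sequences that the package does not
redistribute. This module generates deterministic **synthetic stand-in**
reference proteins keyed to the same gene symbols, so the whole pipeline
is exercisable offline; users supply their own protein FASTA panels
(headers ``<accession>|<gene_label>``) to run against real references.

The rhodopsin anchors are built on a shared scaffold so the three
subtrees are mutually ~70% identical, with the canonical diagnostic
residues fixed at anchor positions 85/89/96 (D/T/E proton-transfer
triad), 156 (G, carotenoid-antenna site) and 292 (retinal-binding K).
"""

from __future__ import annotations

import zlib

import numpy as np

from .io_formats import SequenceRecord
from .orf_homology import PanelEntry

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: diagnostic anchor positions (1-based, anchor-relative)
DIAGNOSTIC_POSITIONS = {"d85": 85, "t89": 89, "e96": 96, "g156": 156, "k292": 292}

#: ordered gene list of the reference PGC, keyed to D. shibae DFL 12 symbols.
#: Classes: bch = bacteriochlorophyll biosynthesis, crt = carotenoid
#: biosynthesis, puf = light harvesting / reaction center (incl. puh),
#: cycA = cytochrome c2, other_conserved = conserved non-pigment genes.
#: Synthetic stand-in ordering (canonical Rhodobacterales PGC layout).
PGC_REFERENCE_GENES: tuple[tuple[str, str], ...] = (
    ("bchI", "bch"),
    ("bchD", "bch"),
    ("bchO", "bch"),
    ("crtA", "crt"),
    ("crtI", "crt"),
    ("crtB", "crt"),
    ("tspO", "other_conserved"),
    ("crtC", "crt"),
    ("crtD", "crt"),
    ("crtE", "crt"),
    ("crtF", "crt"),
    ("bchC", "bch"),
    ("bchX", "bch"),
    ("bchY", "bch"),
    ("bchZ", "bch"),
    ("pufQ", "puf"),
    ("pufB", "puf"),
    ("pufA", "puf"),
    ("pufL", "puf"),
    ("pufM", "puf"),
    ("pufC", "puf"),
    ("bchF", "bch"),
    ("bchN", "bch"),
    ("bchB", "bch"),
    ("bchH", "bch"),
    ("bchL", "bch"),
    ("bchM", "bch"),
    ("lhaA", "other_conserved"),
    ("puhA", "puf"),
    ("puhB", "puf"),
    ("puhC", "puf"),
    ("acsF", "other_conserved"),
    ("puhE", "puf"),
    ("ppsR", "other_conserved"),
    ("bchG", "bch"),
    ("bchP", "bch"),
    ("pucC", "other_conserved"),
    ("cycA", "cycA"),
)

#: carotenoid genes that may accompany a rhodopsin operon
RHODOPSIN_OPERON_CRT = ("crtE", "crtB", "crtI", "crtY")

RHODOPSIN_LABEL = "rhodopsin"
BRP_BLH_LABEL = "brp_blh"

_SEED_SALT = 745991  # fixed: reference proteins are a stable, versioned artifact


def _symbol_rng(symbol: str) -> np.random.Generator:
    return np.random.default_rng(_SEED_SALT + zlib.crc32(symbol.encode()))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def reference_protein(symbol: str) -> str:
    """Deterministic synthetic reference protein for a gene-family symbol."""
    rng = _symbol_rng(symbol)
    length = int(rng.integers(180, 320))
    return _random_protein(rng, length)


def _rhodopsin_scaffold() -> str:
    rng = _symbol_rng("rhodopsin_scaffold")
    seq = list(_random_protein(rng, 300))
    seq[84] = "D"   # position 85
    seq[88] = "T"   # position 89
    seq[95] = "E"   # position 96
    seq[155] = "G"  # position 156
    seq[291] = "K"  # position 292
    return "".join(seq)


def rhodopsin_anchor(subtree: str) -> str:
    """Anchor/reference protein for subtree ``I``, ``II`` or ``III``.

    Each subtree diverges from a common scaffold at ~30% of non-diagnostic
    positions, giving realistic between-subtree identities while keeping
    the diagnostic residues intact.
    """
    if subtree not in {"I", "II", "III"}:
        raise ValueError(f"unknown rhodopsin subtree {subtree!r}")
    scaffold = list(_rhodopsin_scaffold())
    protected = {p - 1 for p in DIAGNOSTIC_POSITIONS.values()}
    rng = _symbol_rng(f"rhodopsin_subtree_{subtree}")
    for i in range(len(scaffold)):
        if i in protected:
            continue
        if rng.random() < 0.30:
            choices = [a for a in AMINO_ACIDS if a != scaffold[i]]
            scaffold[i] = choices[int(rng.integers(len(choices)))]
    return "".join(scaffold)


SUBTREE_REFERENCE_IDS = {
    "I": "SYNPR1.1",   # stand-in for the subtree-I proteorhodopsin reference
    "II": "SYNPR2.1",  # stand-in for the subtree-II (E. sibiricum branch) reference
    "III": "SYNXR3.1",  # stand-in for the subtree-III xanthorhodopsin reference
}

PUFM_REFERENCE_ID = "SYNPUFM.1"  # stand-in for the PufM bait


def rhodopsin_reference_panel() -> list[tuple[str, str]]:
    """(subtree label, protein) pairs spanning the three subtrees."""
    return [(st, rhodopsin_anchor(st)) for st in ("I", "II", "III")]


def default_panel() -> list[PanelEntry]:
    """Full screening panel: PGC gene families, rhodopsins, brp/blh, crtY.

    All three rhodopsin references carry the same gene label so that one
    genomic rhodopsin locus yields a single dereplicated hit; the subtree
    is assigned downstream by nearest reference.
    """
    panel: list[PanelEntry] = []
    for symbol, _cls in PGC_REFERENCE_GENES:
        ref_id = PUFM_REFERENCE_ID if symbol == "pufM" else f"SYN_{symbol.upper()}.1"
        panel.append(PanelEntry(reference_id=ref_id, gene_label=symbol,
                                protein=reference_protein(symbol)))
    for subtree, prot in rhodopsin_reference_panel():
        panel.append(PanelEntry(reference_id=SUBTREE_REFERENCE_IDS[subtree],
                                gene_label=RHODOPSIN_LABEL, protein=prot))
    panel.append(PanelEntry(reference_id="SYN_BRP_BLH.1", gene_label=BRP_BLH_LABEL,
                            protein=reference_protein("brp_blh")))
    panel.append(PanelEntry(reference_id="SYN_CRTY.1", gene_label="crtY",
                            protein=reference_protein("crtY")))
    return panel


def panel_to_records(panel: list[PanelEntry]) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=f"{e.reference_id}|{e.gene_label}", seq=e.protein)
        for e in panel
    ]


def known_gene_labels() -> set[str]:
    labels = {sym for sym, _ in PGC_REFERENCE_GENES}
    labels.update(RHODOPSIN_OPERON_CRT)
    labels.add(RHODOPSIN_LABEL)
    labels.add(BRP_BLH_LABEL)
    return labels
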