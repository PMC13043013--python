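"""Readers, writers and in-memory model for MAG collections.

All external artifacts are plain text: nucleotide/protein FASTA, GFF3,
and tab-separated tables (assembly manifest, QC, coverage, taxonomy).
Coordinates are 0-based half-open everywhere inside the package;
conversion to/from the 1-based inclusive GFF convention happens only at
the GFF boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("cyanophot")

# IUPAC nucleotide codes (ambiguity included) and amino acids with X and stop.
NUCLEOTIDE_ALPHABET = set("ACGTNRYSWKMBDHV")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

#: gene-family symbols the reference panels can assign; anything else is "unknown"
CONTROLLED_VOCABULARY_EXTRA = {"unknown"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeBin:
    """One MAG: its contigs plus derived assembly statistics.

    ``mag_id`` follows the study's ``<lineage>-<strain>-<rank>`` pattern but
    is treated as an opaque string. ``gc_content`` excludes N bases from the
    denominator, matching standard assembly-statistics practice.
    """

    mag_id: str
    metagenome_id: str
    contigs: list[SequenceRecord]
    is_host: bool = False

    @property
    def genome_size(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def gc_content(self) -> float:
        g = c = at = 0
        for contig in self.contigs:
            s = contig.seq
            g += s.count("G")
            c += s.count("C")
            at += s.count("A") + s.count("T")
        denom = g + c + at
        return (g + c) / denom if denom else 0.0

    def contig(self, contig_id: str) -> SequenceRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"contig {contig_id!r} not in MAG {self.mag_id!r}")


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a contig; 0-based half-open internally."""

    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    label: str  # gene-family symbol or "unknown"
    source: str = "predicted"  # {"annotated", "predicted"}

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end}) on "
                f"{self.contig_id}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def overlaps(self, other: "GeneFeature") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class QCRecord:
    """CheckM-style completeness/contamination estimate for one MAG."""

    mag_id: str
    completeness: float  # percent, [0, 100]
    contamination: float  # percent, >= 0

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(
                f"completeness of {self.mag_id} outside [0, 100]: "
                f"{self.completeness}"
            )
        if self.contamination < 0:
            raise ValueError(
                f"contamination of {self.mag_id} negative: {self.contamination}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; for nucleotide input U is mapped to T.
    Duplicate ids and characters outside the IUPAC alphabet raise
    ``ValueError``.
    """
    if alphabet not in {"nucleotide", "protein"}:
        raise ValueError(f"alphabet must be 'nucleotide' or 'protein', got {alphabet!r}")
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise ValueError(
                    f"illegal character {ch!r} at position {pos + 1} of record "
                    f"{rec.id!r} in {path}"
                )
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description))
    if not records:
        logger.warning("fasta_empty path=%s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(
    path: str | Path,
    symbol_key: str = "gene",
    fallback_key: str = "Name",
    known_labels: set[str] | None = None,
) -> list[GeneFeature]:
    """Read GFF3 feature rows into :class:`GeneFeature` objects.

    1-based inclusive coordinates are converted to 0-based half-open. The
    gene symbol is taken from attribute ``symbol_key`` (default ``gene``),
    falling back to ``fallback_key``; symbols outside ``known_labels`` (when
    given) are mapped to ``"unknown"``.
    """
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(parts)}")
            contig_id, source, _ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            start_1, end_1 = int(start_s), int(end_s)
            if end_1 < start_1:
                raise ValueError(f"{path}:{lineno}: end < start ({end_1} < {start_1})")
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: strand required, got {strand!r}")
            attr_map: dict[str, str] = {}
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk and "=" in chunk:
                    k, v = chunk.split("=", 1)
                    attr_map[k] = v
            label = attr_map.get(symbol_key) or attr_map.get(fallback_key) or "unknown"
            if known_labels is not None and label not in known_labels:
                label = "unknown"
            features.append(
                GeneFeature(
                    contig_id=contig_id,
                    start=start_1 - 1,
                    end=end_1,
                    strand=strand,
                    label=label,
                    source="annotated" if source != "cyanophot" else "predicted",
                )
            )
    return features


def write_gff(features: Iterable[GeneFeature], path: str | Path, source: str = "cyanophot") -> None:
    """Write features as GFF3 (coordinates back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        source,
                        "gene",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"gene={f.label}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tables and collection assembly
# ---------------------------------------------------------------------------

def load_collection(manifest_path: str | Path) -> list[GenomeBin]:
    """Assemble a MAG collection from a TSV manifest.

    The manifest columns are ``mag_id``, ``metagenome_id``, ``fasta_path``
    and optionally ``is_host`` (0/1). Relative FASTA paths are resolved
    against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"mag_id", "metagenome_id", "fasta_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns: {sorted(missing)}")
    mags: list[GenomeBin] = []
    seen: set[str] = set()
    for row in table.itertuples(index=False):
        mag_id = row.mag_id
        if mag_id in seen:
            raise ValueError(f"duplicate mag_id {mag_id!r} in manifest")
        seen.add(mag_id)
        fasta = Path(row.fasta_path)
        if not fasta.is_absolute():
            fasta = manifest_path.parent / fasta
        if not fasta.exists():
            raise FileNotFoundError(f"FASTA for MAG {mag_id!r} not found: {fasta}")
        contigs = read_fasta(fasta, alphabet="nucleotide")
        is_host = bool(int(getattr(row, "is_host", "0") or "0"))
        mags.append(
            GenomeBin(
                mag_id=mag_id,
                metagenome_id=row.metagenome_id,
                contigs=contigs,
                is_host=is_host,
            )
        )
    return mags


def read_qc_table(path: str | Path) -> list[QCRecord]:
    table = pd.read_csv(path, sep="\t")
    required = {"mag_id", "completeness", "contamination"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"QC table {path} missing columns: {sorted(missing)}")
    return [
        QCRecord(
            mag_id=str(r.mag_id),
            completeness=float(r.completeness),
            contamination=float(r.contamination),
        )
        for r in table.itertuples(index=False)
    ]


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Coverage TSV with columns ``mag_id metagenome_id mapped_bases``."""
    table = pd.read_csv(path, sep="\t")
    required = {"mag_id", "metagenome_id", "mapped_bases"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"coverage table {path} missing columns: {sorted(missing)}")
    table["mapped_bases"] = table["mapped_bases"].astype(float)
    return table


def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    """Taxonomy TSV: ``mag_id`` plus a semicolon-separated six-rank lineage."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "mag_id" not in table.columns or "lineage" not in table.columns:
        raise ValueError(f"taxonomy table {path} must have columns mag_id, lineage")
    return table


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
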