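"""Abundance, commonality and community-composition exports.

Relative abundance is host-calibrated: coverage (mapped bases / genome
size) of every MAG is expressed as a percentage of the cyanobacterial
host MAG's coverage in the same metagenome, so the host is 100% by
definition and values above 100% mark associated bacteria that outgrow
their host. Commonality is simply the number of metagenomes in which a
taxon occurs. MAGs are filtered on CheckM-style completeness (>80%,
strict) and contamination (<10%, strict) before any of this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GenomeBin, QCRecord

logger = logging.getLogger("cyanophot")

COMPLETENESS_THRESHOLD = 80.0  # keep iff strictly greater
CONTAMINATION_THRESHOLD = 10.0  # keep iff strictly smaller

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
#: ranks at which presence-absence matrices are exported
MATRIX_RANKS = ("species", "genus", "family", "order", "class", "phylum")


@dataclass(frozen=True)
class CoverageRecord:
    mag_id: str
    metagenome_id: str
    mapped_bases: float
    genome_size: int
    coverage: float  # fold
    relative_abundance: float  # percent of host coverage


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def filter_mags(
    qc: Sequence[QCRecord],
    mags: Sequence[GenomeBin],
    completeness_threshold: float = COMPLETENESS_THRESHOLD,
    contamination_threshold: float = CONTAMINATION_THRESHOLD,
) -> list[GenomeBin]:
    """Keep MAGs with completeness > threshold and contamination < threshold.

    Both inequalities are strict; boundary values (exactly 80% complete or
    exactly 10% contaminated) are removed. Every MAG must have a QC row.
    """
    qc_by_id = {r.mag_id: r for r in qc}
    kept: list[GenomeBin] = []
    for mag in mags:
        rec = qc_by_id.get(mag.mag_id)
        if rec is None:
            raise ValueError(f"no QC record for MAG {mag.mag_id!r}")
        if rec.completeness > completeness_threshold and rec.contamination < contamination_threshold:
            kept.append(mag)
        else:
            logger.info(
                "qc_removed mag_id=%s completeness=%.2f contamination=%.2f",
                mag.mag_id, rec.completeness, rec.contamination,
            )
    return kept


# ---------------------------------------------------------------------------
# Abundance
# ---------------------------------------------------------------------------

def compute_abundance(
    coverage_rows: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    host_mag_id: str,
) -> list[CoverageRecord]:
    """Host-calibrated relative abundance for one metagenome's coverage rows.

    ``coverage_rows`` has columns ``mag_id, metagenome_id, mapped_bases``
    for a single metagenome; ``genome_sizes`` maps mag_id to assembly
    length. Coverage = mapped_bases / genome_size; relative abundance =
    100 x coverage / host coverage.
    """
    ids = set(coverage_rows["mag_id"])
    if host_mag_id not in ids:
        raise ValueError(f"host MAG {host_mag_id!r} absent from coverage rows")
    metagenomes = set(coverage_rows["metagenome_id"])
    if len(metagenomes) != 1:
        raise ValueError(f"coverage rows span several metagenomes: {sorted(metagenomes)}")
    cov: dict[str, float] = {}
    for row in coverage_rows.itertuples(index=False):
        size = genome_sizes.get(row.mag_id)
        if not size or size <= 0:
            raise ValueError(f"genome size missing or nonpositive for {row.mag_id!r}")
        cov[row.mag_id] = float(row.mapped_bases) / size
    host_cov = cov[host_mag_id]
    if host_cov <= 0:
        raise ValueError(f"host MAG {host_mag_id!r} has zero coverage")
    metagenome_id = next(iter(metagenomes))
    return [
        CoverageRecord(
            mag_id=mag_id,
            metagenome_id=metagenome_id,
            mapped_bases=cov[mag_id] * genome_sizes[mag_id],
            genome_size=genome_sizes[mag_id],
            coverage=cov[mag_id],
            relative_abundance=100.0 * cov[mag_id] / host_cov,
        )
        for mag_id in sorted(cov)
    ]


def abundance_table(records: Sequence[CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mag_id": r.mag_id,
                "metagenome_id": r.metagenome_id,
                "coverage": r.coverage,
                "relative_abundance": r.relative_abundance,
            }
            for r in records
        ],
        columns=["mag_id", "metagenome_id", "coverage", "relative_abundance"],
    )


# ---------------------------------------------------------------------------
# Commonality and presence-absence matrices
# ---------------------------------------------------------------------------

def _parse_lineage(lineage: str) -> dict[str, str]:
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) != len(RANKS):
        raise ValueError(
            f"malformed lineage (need {len(RANKS)} ';'-separated ranks): {lineage!r}"
        )
    return dict(zip(RANKS, parts))


def _taxon_table(
    taxonomy: pd.DataFrame, mags: Sequence[GenomeBin]
) -> pd.DataFrame:
    """Per-MAG table of metagenome and rank assignments.

    MAGs missing from the taxonomy table get a placeholder lineage
    ``unclassified_<mag_id>`` at every rank.
    """
    assigned = {str(r.mag_id): str(r.lineage) for r in taxonomy.itertuples(index=False)}
    rows = []
    for mag in mags:
        lineage = assigned.get(mag.mag_id)
        if lineage is None:
            ranks = {rank: f"unclassified_{mag.mag_id}" for rank in RANKS}
        else:
            ranks = _parse_lineage(lineage)
        rows.append({"mag_id": mag.mag_id, "metagenome_id": mag.metagenome_id, **ranks})
    return pd.DataFrame(rows, columns=["mag_id", "metagenome_id", *RANKS])


def commonality(
    taxonomy: pd.DataFrame, mags: Sequence[GenomeBin], rank: str = "species"
) -> pd.DataFrame:
    """Number of metagenomes in which each taxon occurs at the given rank.

    A taxon counts once per metagenome regardless of how many of its MAGs
    were binned there. Sorted by count descending, then taxon name.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    table = _taxon_table(taxonomy, mags)
    counts = (
        table.groupby(rank)["metagenome_id"].nunique().reset_index(name="n_metagenomes")
    )
    counts = counts.rename(columns={rank: "taxon"})
    return counts.sort_values(
        ["n_metagenomes", "taxon"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def presence_matrix(
    taxonomy: pd.DataFrame, mags: Sequence[GenomeBin], rank: str
) -> pd.DataFrame:
    """Binary taxa x metagenomes matrix at one taxonomic rank.

    All-zero taxon rows are pruned (they cannot arise from observed MAGs
    but may after external edits); row and column order are sorted for
    determinism. The matrix is exported for external ordination.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    table = _taxon_table(taxonomy, mags)
    matrix = (
        pd.crosstab(table[rank], table["metagenome_id"])
        .clip(upper=1)
        .astype(int)
    )
    matrix = matrix.loc[matrix.sum(axis=1) > 0]
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    matrix.index.name = "taxon"
    matrix.columns.name = None
    return matrix
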