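"""End-to-end orchestration: filter -> screen -> rhodopsin -> pgc -> calls -> metrics.

The stages are plain library calls stitched together; each stage writes
its TSV/JSON outputs as it completes so partial results survive a
downstream failure. The CLI is a thin wrapper over :func:`run_pipeline`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import community_metrics, io_formats, orf_homology, pgc_analysis
from . import phototrophy_calls as calls_mod
from . import references, rhodopsin_classifier
from .io_formats import GenomeBin, QCRecord
from .orf_homology import ProteinHit, ScreenThresholds

logger = logging.getLogger("cyanophot")


@dataclass
class RunConfig:
    """All paths and threshold knobs of one pipeline run."""

    manifest: str | None = None
    panel_fasta: str | None = None  # None -> packaged synthetic panel
    qc_table: str | None = None
    coverage_table: str | None = None
    taxonomy_table: str | None = None
    out_dir: str = "cyanophot_out"
    seed: int = 0
    min_identity: float = orf_homology.DEFAULT_MIN_IDENTITY
    min_query_cov: float = orf_homology.DEFAULT_MIN_QUERY_COV
    min_score: float = orf_homology.DEFAULT_MIN_SCORE
    min_orf_aa: int = orf_homology.DEFAULT_MIN_ORF_AA
    window_bp: int = rhodopsin_classifier.DEFAULT_WINDOW_BP
    pgc_completeness_floor: float = pgc_analysis.DEFAULT_COMPLETENESS_FLOOR
    pgc_max_span_bp: int = pgc_analysis.DEFAULT_MAX_SPAN_BP
    completeness_threshold: float = community_metrics.COMPLETENESS_THRESHOLD
    contamination_threshold: float = community_metrics.CONTAMINATION_THRESHOLD

    def thresholds(self) -> ScreenThresholds:
        return ScreenThresholds(
            min_identity=self.min_identity,
            min_query_cov=self.min_query_cov,
            min_score=self.min_score,
            min_orf_aa=self.min_orf_aa,
        )

    def log_knobs(self) -> None:
        for key in (
            "min_identity", "min_query_cov", "min_score", "min_orf_aa",
            "window_bp", "pgc_completeness_floor", "pgc_max_span_bp",
            "completeness_threshold", "contamination_threshold", "seed",
        ):
            logger.info("config %s=%s", key, getattr(self, key))


@dataclass
class ResultBundle:
    mags: list[GenomeBin]
    hits: list[ProteinHit]
    rhodopsin_records: list
    pgc_inventories: dict
    calls: list
    venn: dict
    abundance: pd.DataFrame | None
    commonality: pd.DataFrame | None
    out_dir: Path | None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def analyze_collection(
    mags: Sequence[GenomeBin],
    panel=None,
    qc: Sequence[QCRecord] | None = None,
    coverage: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> ResultBundle:
    """Run the full analysis on an in-memory MAG collection."""
    cfg = config or RunConfig()
    cfg.log_knobs()
    panel = panel if panel is not None else references.default_panel()
    outp = Path(out_dir) if out_dir else None
    if outp:
        outp.mkdir(parents=True, exist_ok=True)

    def _write(df: pd.DataFrame, name: str) -> None:
        if outp is not None:
            df.to_csv(outp / name, sep="\t", index=False)

    # --- filter ---------------------------------------------------------
    if qc is not None:
        try:
            mags = community_metrics.filter_mags(
                qc, mags, cfg.completeness_threshold, cfg.contamination_threshold
            )
        except Exception as e:  # pragma: no cover - passthrough
            raise StageError("filter", e) from e
    logger.info("stage=filter retained=%d", len(mags))

    # --- screen ---------------------------------------------------------
    try:
        hits: list[ProteinHit] = []
        for mag in mags:
            hits.extend(orf_homology.screen_genome(mag, panel, cfg.thresholds()))
    except Exception as e:
        raise StageError("screen", e) from e
    _write(orf_homology.hits_to_table(hits), "hits.tsv")
    logger.info("stage=screen hits=%d", len(hits))

    # --- rhodopsin ------------------------------------------------------
    try:
        records = []
        hits_by_mag: dict[str, list[ProteinHit]] = {}
        for h in hits:
            hits_by_mag.setdefault(h.mag_id, []).append(h)
        for mag in mags:
            mag_hits = hits_by_mag.get(mag.mag_id, [])
            feats = [h.to_feature() for h in mag_hits]
            records.extend(
                rhodopsin_classifier.classify_rhodopsins(
                    mag_hits, feats, window_bp=cfg.window_bp
                )
            )
    except Exception as e:
        raise StageError("rhodopsin", e) from e
    _write(rhodopsin_classifier.records_to_table(records), "rhodopsins.tsv")
    logger.info("stage=rhodopsin records=%d", len(records))

    # --- pgc ------------------------------------------------------------
    try:
        inventories = {
            mag.mag_id: pgc_analysis.inventory_pgc(
                hits_by_mag.get(mag.mag_id, []),
                mag,
                completeness_floor=cfg.pgc_completeness_floor,
                max_span_bp=cfg.pgc_max_span_bp,
            )
            for mag in mags
        }
    except Exception as e:
        raise StageError("pgc", e) from e
    _write(
        pgc_analysis.inventory_to_table(list(inventories.values())), "pgc_inventory.tsv"
    )
    logger.info(
        "stage=pgc with_pgc=%d", sum(1 for i in inventories.values() if i.has_pgc)
    )

    # --- calls ----------------------------------------------------------
    try:
        records_by_mag: dict[str, list] = {}
        for r in records:
            records_by_mag.setdefault(r.hit.mag_id, []).append(r)
        calls = [
            calls_mod.call_phototrophy(
                mag.mag_id,
                inventories.get(mag.mag_id),
                records_by_mag.get(mag.mag_id, []),
                is_host=mag.is_host,
            )
            for mag in mags
        ]
        venn = calls_mod.summarize_venn(calls)
    except Exception as e:
        raise StageError("calls", e) from e
    _write(calls_mod.calls_to_table(calls), "phototrophy_calls.tsv")
    if outp is not None:
        with open(outp / "venn_summary.json", "w") as fh:
            json.dump(venn, fh, indent=2, sort_keys=True)
    logger.info("stage=calls venn=%s", venn)

    # --- metrics --------------------------------------------------------
    abundance = None
    common = None
    if coverage is not None:
        try:
            sizes = {m.mag_id: m.genome_size for m in mags}
            hosts = {m.metagenome_id: m.mag_id for m in mags if m.is_host}
            mag_ids = set(sizes)
            parts = []
            for meta_id, rows in coverage.groupby("metagenome_id"):
                rows = rows[rows["mag_id"].isin(mag_ids)]
                host = hosts.get(str(meta_id))
                if host is None or host not in set(rows["mag_id"]):
                    logger.warning("metrics_skip metagenome=%s reason=no_host", meta_id)
                    continue
                recs = community_metrics.compute_abundance(rows, sizes, host)
                parts.append(community_metrics.abundance_table(recs))
            abundance = (
                pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
            )
            if taxonomy is not None:
                common = community_metrics.commonality(taxonomy, mags)
                if outp is not None:
                    for rank in community_metrics.MATRIX_RANKS:
                        matrix = community_metrics.presence_matrix(taxonomy, mags, rank)
                        matrix.to_csv(outp / f"presence_{rank}.tsv", sep="\t")
        except StageError:
            raise
        except Exception as e:
            raise StageError("metrics", e) from e
        _write(abundance, "abundance.tsv")
        if common is not None:
            _write(common, "commonality.tsv")
    else:
        logger.warning("stage=metrics skipped reason=no_coverage_table")

    return ResultBundle(
        mags=list(mags),
        hits=hits,
        rhodopsin_records=records,
        pgc_inventories=inventories,
        calls=calls,
        venn=venn,
        abundance=abundance,
        commonality=common,
        out_dir=outp,
    )


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Load all inputs named in the config and run the full analysis."""
    if not config.manifest:
        raise ValueError("config.manifest is required")
    mags = io_formats.load_collection(config.manifest)
    panel = None
    if config.panel_fasta:
        panel = orf_homology.load_panel(
            io_formats.read_fasta(config.panel_fasta, alphabet="protein")
        )
    qc = io_formats.read_qc_table(config.qc_table) if config.qc_table else None
    coverage = (
        io_formats.read_coverage_table(config.coverage_table)
        if config.coverage_table
        else None
    )
    taxonomy = (
        io_formats.read_taxonomy_table(config.taxonomy_table)
        if config.taxonomy_table
        else None
    )
    return analyze_collection(
        mags,
        panel=panel,
        qc=qc,
        coverage=coverage,
        taxonomy=taxonomy,
        config=config,
        out_dir=config.out_dir,
    )
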