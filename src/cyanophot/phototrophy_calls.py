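"""Per-MAG phototrophy calls and the collection-level Venn summary.

Evidence from the PGC inventory and the rhodopsin records is combined
into one mode per MAG: the cyanobacterial host is flagged externally and
always called ``cyano_oxygenic``; an associated MAG carrying both a PGC
and a proton-pumping rhodopsin (in the study's cases always a
xanthorhodopsin operon) is a dual phototroph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .pgc_analysis import PGCInventory
from .rhodopsin_classifier import RhodopsinRecord


@dataclass
class PhototrophyCall:
    mag_id: str
    has_pgc: bool
    pump_rhodopsins: int  # bona_fide_pump records
    candidate_rhodopsins: int  # candidate_pump records
    xr_operon: bool  # subtree-III record with adjacent brp/blh
    is_host: bool
    mode: str  # {cyano_oxygenic, pgc_only, rhodopsin_only, dual, none}
    evidence: dict = field(default_factory=dict)


def call_phototrophy(
    mag_id: str,
    pgc: PGCInventory | None,
    rhodopsins: Sequence[RhodopsinRecord],
    is_host: bool,
) -> PhototrophyCall:
    """Aggregate PGC and rhodopsin evidence into one call for a MAG."""
    has_pgc = bool(pgc and pgc.has_pgc)
    pumps = sum(1 for r in rhodopsins if r.call == "bona_fide_pump")
    candidates = sum(1 for r in rhodopsins if r.call == "candidate_pump")
    xr_operon = any(
        r.subtree == "III" and r.context.brp_blh_adjacent for r in rhodopsins
    )
    if is_host:
        mode = "cyano_oxygenic"
    elif has_pgc and (pumps > 0 or xr_operon):
        mode = "dual"
    elif has_pgc:
        mode = "pgc_only"
    elif pumps > 0 or xr_operon:
        mode = "rhodopsin_only"
    else:
        mode = "none"
    return PhototrophyCall(
        mag_id=mag_id,
        has_pgc=has_pgc,
        pump_rhodopsins=pumps,
        candidate_rhodopsins=candidates,
        xr_operon=xr_operon,
        is_host=is_host,
        mode=mode,
        evidence={
            "pgc_completeness": pgc.completeness if pgc else 0.0,
            "rhodopsin_calls": [r.call for r in rhodopsins],
        },
    )


def summarize_venn(calls: Sequence[PhototrophyCall]) -> dict[str, int]:
    """Collection-wide counts behind the phototrophy Venn diagram.

    ``pgc_total`` counts PGC-bearing non-host MAGs; ``rhodopsin_total``
    counts MAGs with at least one bona fide *or* candidate pump (the
    broader tally), ``rhodopsin_bona_fide`` only bona fide pumps; ``dual``
    counts MAGs called dual; ``cyano`` the hosts; ``none`` the rest.
    """
    seen: set[str] = set()
    for c in calls:
        if c.mag_id in seen:
            raise ValueError(f"duplicate mag_id in calls: {c.mag_id!r}")
        seen.add(c.mag_id)
    non_host = [c for c in calls if not c.is_host]
    summary = {
        "total_mags": len(calls),
        "cyano": sum(1 for c in calls if c.is_host),
        "pgc_total": sum(1 for c in non_host if c.has_pgc),
        "rhodopsin_total": sum(
            1
            for c in non_host
            if c.pump_rhodopsins > 0 or c.candidate_rhodopsins > 0 or c.xr_operon
        ),
        "rhodopsin_bona_fide": sum(1 for c in non_host if c.pump_rhodopsins > 0),
        "dual": sum(1 for c in non_host if c.mode == "dual"),
        "none": sum(1 for c in non_host if c.mode == "none"),
    }
    return summary


def calls_to_table(calls: Sequence[PhototrophyCall]) -> pd.DataFrame:
    rows = [
        {
            "mag_id": c.mag_id,
            "mode": c.mode,
            "has_pgc": int(c.has_pgc),
            "pump_rhodopsins": c.pump_rhodopsins,
            "candidate_rhodopsins": c.candidate_rhodopsins,
            "xr_operon": int(c.xr_operon),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id", "mode", "has_pgc", "pump_rhodopsins",
            "candidate_rhodopsins", "xr_operon",
        ],
    )
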