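"""Coordinate joins of predicted circRNAs against local circRNA database tables.

Database content is supplied by the user as TSV dumps (one per database) with
a small column-mapping configuration; matching is either exact on
(chrom, start, end) or by reciprocal overlap.  Assembly conversion is the
caller's responsibility — all inputs must share one genome assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import CircRecord, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class DbTable:
    """One database dump: a label plus (interval, attributes) records."""

    name: str
    records: list[tuple[GenomicInterval, dict[str, str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def load_db_table(
    path: str | Path,
    name: str,
    chrom_col: str = "chrom",
    start_col: str = "start",
    end_col: str = "end",
    strand_col: str | None = None,
    one_based: bool = False,
) -> DbTable:
    """Load a database TSV, mapping its coordinate columns onto intervals.

    ``one_based=True`` declares 1-based inclusive coordinates (converted on
    load); all remaining columns become annotation attributes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (chrom_col, start_col, end_col):
        if col not in df.columns:
            raise ValueError(f"database {name!r} is missing column {col!r}")
    coord_cols = {chrom_col, start_col, end_col} | ({strand_col} if strand_col else set())
    attr_cols = [c for c in df.columns if c not in coord_cols]
    table = DbTable(name)
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        start = int(d[start_col]) - (1 if one_based else 0)
        end = int(d[end_col])
        strand = d.get(strand_col, "unknown") if strand_col else "unknown"
        if strand not in ("+", "-"):
            strand = "unknown"
        interval = GenomicInterval(str(d[chrom_col]), start, end, strand)
        table.records.append((interval, {c: d[c] for c in attr_cols}))
    return table


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(intersection/len(a), intersection/len(b)); 0 when chroms differ."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.span, inter / b.span)


def annotate_circrnas(
    circs: Sequence[CircRecord],
    tables: Sequence[DbTable],
    mode: str = "exact",
    min_overlap: float = 0.9,
) -> pd.DataFrame:
    """Join circRNAs against database tables by genomic coordinates.

    Exact mode matches on (chrom, start, end); overlap mode requires
    reciprocal overlap >= ``min_overlap``.  The result has one row per
    (circRNA, database, hit) — attribute columns are prefixed with the
    database name to avoid collisions — plus an ``annotated_in`` column
    listing every database that matched the circRNA.  circRNAs with no hit
    anywhere still appear, once, with empty annotation.
    """
    if mode not in ("exact", "overlap"):
        raise ValueError("mode must be 'exact' or 'overlap'")
    exact_lookup: dict[str, dict[tuple[str, int, int], list[dict[str, str]]]] = {}
    if mode == "exact":
        for table in tables:
            lk: dict[tuple[str, int, int], list[dict[str, str]]] = {}
            for interval, attrs in table.records:
                lk.setdefault((interval.chrom, interval.start, interval.end), []).append(attrs)
            exact_lookup[table.name] = lk

    rows: list[dict] = []
    for circ in circs:
        hits: list[tuple[str, dict[str, str]]] = []
        for table in tables:
            if mode == "exact":
                key = (circ.interval.chrom, circ.interval.start, circ.interval.end)
                for attrs in exact_lookup[table.name].get(key, []):
                    hits.append((table.name, attrs))
            else:
                for interval, attrs in table.records:
                    if reciprocal_overlap(circ.interval, interval) >= min_overlap:
                        hits.append((table.name, attrs))
        annotated_in = ",".join(sorted({name for name, _ in hits}))
        if not hits:
            rows.append({"circ_id": circ.id, "db": "", "annotated_in": ""})
        for name, attrs in hits:
            row = {"circ_id": circ.id, "db": name, "annotated_in": annotated_in}
            row.update({f"{name}.{k}": v for k, v in attrs.items()})
            rows.append(row)
    return pd.DataFrame(rows)
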