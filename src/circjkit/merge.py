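"""Merge per-sample circRNA predictions and intersect predictions across tools.

The replicate filter follows the two-threshold rule used to reduce spurious
back-splice calls: a circRNA is kept only if, in at least one experimental
condition, strictly more than ``min_reads`` BS-supporting reads are seen in at
least ``min_reps`` replicates AND the mean count over that condition's
replicates is strictly greater than ``min_avg``.  Requiring the predicate in
*every* condition instead (``require_all_conditions=True``) would discard
condition-specific circRNAs, so any-condition is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CircRecord, CountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeParams:
    """Thresholds of the replicate filter (defaults: min_reads=2, min_reps=2, min_avg=10)."""

    min_reads: int = 2
    min_reps: int = 2
    min_avg: float = 10.0

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.min_avg < 0:
            raise ValueError("min_reads and min_avg must be >= 0")
        if self.min_reps < 1:
            raise ValueError("min_reps must be >= 1")


def _records_to_series(records: Sequence[CircRecord], sample: str) -> pd.Series:
    counts: dict[str, int] = {}
    for rec in records:
        if rec.id in counts:
            raise ValueError(f"duplicate circRNA {rec.id} in sample {sample!r}")
        counts[rec.id] = rec.bs_reads
    return pd.Series(counts, dtype=int, name=sample)


def retained(row: Mapping[str, int], covariates: Mapping[str, str], params: MergeParams,
             require_all_conditions: bool = False) -> bool:
    """Evaluate the retention predicate for one circRNA's per-sample counts."""
    conditions: dict[str, list[int]] = {}
    for sample, condition in covariates.items():
        conditions.setdefault(condition, []).append(int(row.get(sample, 0)))
    verdicts = []
    for counts in conditions.values():
        arr = np.asarray(counts)
        ok = (arr > params.min_reads).sum() >= params.min_reps and arr.mean() > params.min_avg
        verdicts.append(ok)
    return all(verdicts) if require_all_conditions else any(verdicts)


def merge_predictions(
    per_sample: Mapping[str, Sequence[CircRecord]],
    covariates: Mapping[str, str],
    params: MergeParams = MergeParams(),
    require_all_conditions: bool = False,
) -> CountTable:
    """Join per-sample predictions into one filtered BS count table.

    Samples absent a circRNA contribute a count of 0.  Output rows are sorted
    by canonical id; columns follow the order of ``per_sample``.
    """
    missing = [s for s in per_sample if s not in covariates]
    if missing:
        raise ValueError(f"samples missing from covariates: {missing}")
    columns = [_records_to_series(recs, sample) for sample, recs in per_sample.items()]
    if not columns:
        return CountTable(pd.DataFrame(dtype=int), dict(covariates))
    table = pd.concat(columns, axis=1).fillna(0).astype(int).sort_index()
    table.index.name = "circ_id"
    relevant_cov = {s: covariates[s] for s in table.columns}
    keep = [
        retained(table.loc[cid], relevant_cov, params, require_all_conditions)
        for cid in table.index
    ]
    return CountTable(table.loc[keep], dict(covariates))


def overlap_tool_predictions(
    per_tool: Mapping[str, Sequence[CircRecord]],
    min_tools: int,
    reference_tool: str | None = None,
    tolerance: int = 0,
) -> list[CircRecord]:
    """Keep circRNAs predicted by at least ``min_tools`` tools.

    Matching is exact on (chrom, start, end), strand ignored; ``tolerance``
    (bp) allows off-by-``tolerance`` drift on both coordinates for dialects
    that disagree by a base.  The surviving record's count comes from
    ``reference_tool`` when given (and present), else the maximum across
    tools.
    """
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    if min_tools > len(per_tool):
        logger.warning(
            "min_tools=%d exceeds the %d supplied tools; result is empty", min_tools, len(per_tool)
        )
        return []
    # key -> tool -> record (each tool's list deduplicated by coordinates)
    by_key: dict[tuple[str, int, int], dict[str, CircRecord]] = {}
    for tool, records in per_tool.items():
        for rec in records:
            key = (rec.interval.chrom, rec.interval.start, rec.interval.end)
            by_key.setdefault(key, {})[tool] = rec

    def supporters(key: tuple[str, int, int]) -> dict[str, CircRecord]:
        if tolerance == 0:
            return by_key[key]
        chrom, start, end = key
        found: dict[str, CircRecord] = {}
        for (c2, s2, e2), tools in by_key.items():
            if c2 == chrom and abs(s2 - start) <= tolerance and abs(e2 - end) <= tolerance:
                for tool, rec in tools.items():
                    found.setdefault(tool, rec)
        return found

    out: list[CircRecord] = []
    for key in sorted(by_key):
        tools = supporters(key)
        if len(tools) < min_tools:
            continue
        if reference_tool is not None and reference_tool in tools:
            chosen = tools[reference_tool]
        else:
            chosen = max(tools.values(), key=lambda r: r.bs_reads)
        rec = by_key[key].get(chosen.tool, chosen)
        out.append(
            CircRecord(rec.interval, chosen.bs_reads, sample=rec.sample, tool=rec.tool)
        )
    if tolerance > 0:
        # tolerance matching can surface the same consensus set from several
        # nearby keys; keep the first occurrence of each coordinate key
        seen: set[tuple[str, int, int]] = set()
        unique = []
        for rec in out:
            key = (rec.interval.chrom, rec.interval.start, rec.interval.end)
            if key not in seen:
                seen.add(key)
                unique.append(rec)
        out = unique
    return out


def merge_count_tables(
    tables: Sequence[CountTable],
    covariates: Mapping[str, str] | None = None,
) -> CountTable:
    """Outer-join count tables on circ ids; missing cells become 0."""
    seen: set[str] = set()
    for table in tables:
        clash = seen & set(table.samples)
        if clash:
            raise ValueError(f"sample labels appear in more than one table: {sorted(clash)}")
        seen |= set(table.samples)
    frames = [t.counts for t in tables if t.shape[1] > 0]
    if not frames:
        return CountTable(pd.DataFrame(dtype=int), dict(covariates or {}))
    joined = pd.concat(frames, axis=1).fillna(0).astype(int).sort_index()
    joined.index.name = "circ_id"
    cov = dict(covariates or {})
    if not cov:
        for table in tables:
            cov.update(table.covariates)
    return CountTable(joined, cov)
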