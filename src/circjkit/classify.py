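"""Five-class back-splice-site classification against exon annotations.

Each circRNA carries two back-splice (BS) sites: the 5' site at its genomic
start and the 3' site at its genomic end.  Against one transcript:

* both sites coincide exactly with exon boundaries (5' site == an exon start,
  3' site == an exon end) -> ``monoexonic`` or ``multiexonic`` depending on
  how many of the transcript's exons the circRNA spans;
* otherwise, a site lying inside an exon (but failing the boundary pair
  test) marks the call ``putative_exon``; a site inside an intron marks it
  ``intronic`` (``putative_exon`` takes precedence when the two sites
  disagree); sites outside the transcript span contribute nothing;
* a circRNA overlapped by no transcript at all is ``intergenic``.

Classification is strand-agnostic by default (antisense circRNAs are real);
pass ``same_strand=True`` to restrict matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import CircRecord, ExonRecord

logger = logging.getLogger(__name__)

MONOEXONIC = "monoexonic"
MULTIEXONIC = "multiexonic"
PUTATIVE_EXON = "putative_exon"
INTRONIC = "intronic"
INTERGENIC = "intergenic"

CATEGORIES = (MONOEXONIC, MULTIEXONIC, PUTATIVE_EXON, INTRONIC, INTERGENIC)

# priority used when aggregating transcript-level calls per gene
_PRIORITY = {MONOEXONIC: 4, MULTIEXONIC: 3, PUTATIVE_EXON: 2, INTRONIC: 1, INTERGENIC: 0}


@dataclass(frozen=True)
class Classification:
    """One classification call for a (circRNA, transcript-or-gene) pair."""

    circ_id: str
    level: str  # "transcript" | "gene"
    subject_id: str
    category: str
    exons_involved: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == MONOEXONIC and len(self.exons_involved) != 1:
            raise ValueError("monoexonic requires exactly one involved exon")
        if self.category == MULTIEXONIC and len(self.exons_involved) < 2:
            raise ValueError("multiexonic requires >= 2 involved exons")
        if self.category in (PUTATIVE_EXON, INTRONIC, INTERGENIC) and self.exons_involved:
            raise ValueError(f"{self.category} carries no involved exons")


@dataclass
class _Transcript:
    transcript_id: str
    gene_id: str
    exons: list[ExonRecord]

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def start(self) -> int:
        return min(e.interval.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.interval.end for e in self.exons)


def group_transcripts(exons: Iterable[ExonRecord]) -> list[_Transcript]:
    by_tx: dict[str, list[ExonRecord]] = {}
    for exon in exons:
        by_tx.setdefault(exon.transcript_id, []).append(exon)
    transcripts = []
    for tx_id, tx_exons in by_tx.items():
        chroms = {e.interval.chrom for e in tx_exons}
        if len(chroms) > 1:
            raise ValueError(f"transcript {tx_id} spans multiple chromosomes: {sorted(chroms)}")
        transcripts.append(_Transcript(tx_id, tx_exons[0].gene_id, sorted(tx_exons, key=lambda e: e.interval.start)))
    return transcripts


def classify_against_transcript(
    circ: CircRecord,
    exons: Sequence[ExonRecord],
) -> Classification | None:
    """Classify one circRNA against the exons of one transcript.

    Returns ``None`` when the circRNA does not overlap the transcript span or
    when neither BS site falls inside the span (such circRNAs are candidates
    for the global intergenic call).
    """
    tx_ids = {e.transcript_id for e in exons}
    if len(tx_ids) != 1:
        raise ValueError(f"exons from mixed transcripts: {sorted(tx_ids)}")
    tx = group_transcripts(exons)[0]
    if circ.interval.chrom != tx.chrom:
        raise ValueError("circRNA and transcript are on different chromosomes")
    if circ.interval.end <= tx.start or circ.interval.start >= tx.end:
        return None

    site5, site3 = circ.interval.start, circ.interval.end
    starts = {e.interval.start for e in tx.exons}
    ends = {e.interval.end for e in tx.exons}
    if site5 in starts and site3 in ends:
        involved = tuple(
            sorted(
                e.exon_rank
                for e in tx.exons
                if e.interval.start >= site5 and e.interval.end <= site3
            )
        )
        category = MONOEXONIC if len(involved) == 1 else MULTIEXONIC
        return Classification(circ.id, "transcript", tx.transcript_id, category, involved)

    # The boundary pair failed.  A site sitting exactly at its required
    # boundary (5' site at an exon start / 3' site at an exon end) is not
    # "intra-exonic" and contributes no region; the other site decides.
    regions = []
    if site5 not in starts:
        regions.append(_site_region(site5, tx))
    if site3 not in ends:
        regions.append(_site_region(site3 - 1, tx))
    if "exon" in regions:
        return Classification(circ.id, "transcript", tx.transcript_id, PUTATIVE_EXON)
    if "intron" in regions:
        return Classification(circ.id, "transcript", tx.transcript_id, INTRONIC)
    return None


def _site_region(pos: int, tx: _Transcript) -> str:
    if pos < tx.start or pos >= tx.end:
        return "outside"
    for exon in tx.exons:
        if exon.interval.start <= pos < exon.interval.end:
            return "exon"
    return "intron"


def classify_all(
    circs: Sequence[CircRecord],
    exons: Sequence[ExonRecord],
    same_strand: bool = False,
) -> list[Classification]:
    """Transcript-level classification of every circRNA.

    Every circRNA receives at least one call: one per overlapping transcript,
    or a single ``intergenic`` call with subject ``"none"`` when no transcript
    overlaps it (including circRNAs on chromosomes absent from the
    annotation).
    """
    transcripts = group_transcripts(exons)
    trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        trees.setdefault(tx.chrom, IntervalTree()).addi(tx.start, tx.end, tx)

    out: list[Classification] = []
    for circ in circs:
        tree = trees.get(circ.interval.chrom)
        if tree is None:
            logger.warning("chromosome %s absent from annotation; %s called intergenic",
                           circ.interval.chrom, circ.id)
            out.append(Classification(circ.id, "transcript", "none", INTERGENIC))
            continue
        calls: list[Classification] = []
        for hit in sorted(tree.overlap(circ.interval.start, circ.interval.end),
                          key=lambda h: h.data.transcript_id):
            tx: _Transcript = hit.data
            if same_strand and circ.interval.strand in ("+", "-") and tx.strand != circ.interval.strand:
                continue
            call = classify_against_transcript(circ, tx.exons)
            if call is not None:
                calls.append(call)
        if calls:
            out.extend(calls)
        else:
            out.append(Classification(circ.id, "transcript", "none", INTERGENIC))
    return out


def aggregate_gene_level(
    transcript_classifications: Sequence[Classification],
    gene_of_transcript: dict[str, str] | None = None,
    exons: Sequence[ExonRecord] | None = None,
) -> list[Classification]:
    """Collapse transcript-level calls to one call per (circRNA, gene).

    The best category across a gene's transcripts wins, under the priority
    monoexonic > multiexonic > putative_exon > intronic; ties keep the first
    transcript's exon ranks.  A circRNA attributable to several genes keeps
    one row per gene, which is why gene-level rows can outnumber circRNAs.
    """
    if gene_of_transcript is None:
        gene_of_transcript = {}
        for exon in exons or []:
            gene_of_transcript[exon.transcript_id] = exon.gene_id
    best: dict[tuple[str, str], Classification] = {}
    order: list[tuple[str, str]] = []
    for call in transcript_classifications:
        if call.level != "transcript":
            raise ValueError("aggregate_gene_level expects transcript-level input")
        gene = gene_of_transcript.get(call.subject_id, call.subject_id)
        key = (call.circ_id, gene)
        current = best.get(key)
        if current is None:
            order.append(key)
            best[key] = Classification(call.circ_id, "gene", gene, call.category, call.exons_involved)
        elif _PRIORITY[call.category] > _PRIORITY[current.category]:
            best[key] = Classification(call.circ_id, "gene", gene, call.category, call.exons_involved)
    return [best[key] for key in order]


def classifications_to_rows(calls: Sequence[Classification]) -> list[dict]:
    """Flatten calls for tabular output (exon ranks comma-joined)."""
    return [
        {
            "circ_id": c.circ_id,
            "level": c.level,
            "subject_id": c.subject_id,
            "category": c.category,
            "exons_involved": ",".join(map(str, c.exons_involved)),
        }
        for c in calls
    ]
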