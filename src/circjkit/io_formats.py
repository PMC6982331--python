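"""Readers, writers and core record types.

All coordinates are held internally as 0-based half-open intervals
``[start, end)``.  Formats that use 1-based inclusive coordinates (CIRI2
tables, GTF) are converted at the parse boundary, and the canonical display
id of a circRNA uses 1-based inclusive coordinates again
(``chrom_{start+1}_{end}``), so that ids look like ``chr14_58718837_58724716``.

Parsers never raise on a malformed data row: row-level problems are collected
as :class:`RowError` objects (pass an ``errors`` list to receive them) so that
``len(records) + len(errors)`` always equals the number of data rows.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", "unknown")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (non-ACGT kept as N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """File-level problem: unknown dialect, bad configuration, broken header."""


@dataclass(frozen=True)
class RowError:
    """One rejected input row."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in the internal 0-based half-open convention."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def display_id(self) -> str:
        """Canonical 1-based inclusive id, e.g. ``chr1_101_200``."""
        return f"{self.chrom}_{self.start + 1}_{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_from_display(circ_id: str) -> GenomicInterval:
    """Invert :attr:`GenomicInterval.display_id` (strand is not encoded)."""
    chrom, start, end = circ_id.rsplit("_", 2)
    return GenomicInterval(chrom, int(start) - 1, int(end))


@dataclass
class CircRecord:
    """One predicted circRNA with its provenance."""

    interval: GenomicInterval
    bs_reads: int = 0
    sample: str = ""
    tool: str = ""

    def __post_init__(self) -> None:
        if self.bs_reads < 0:
            raise ValueError("bs_reads must be >= 0")

    @property
    def id(self) -> str:
        return self.interval.display_id


@dataclass
class ExonRecord:
    """One exon of one transcript; exon_rank 1 is the transcript's first exon."""

    interval: GenomicInterval
    transcript_id: str
    gene_id: str
    gene_name: str = ""
    exon_rank: int = 1

    def __post_init__(self) -> None:
        if self.exon_rank < 1:
            raise ValueError("exon_rank must be >= 1")


class CountTable:
    """circRNA x sample matrix of BS-supporting read counts with covariates.

    Thin wrapper over a pandas DataFrame (index: canonical circ ids, columns:
    sample labels) plus a sample -> condition map.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        covariates: Mapping[str, str] | None = None,
    ) -> None:
        if counts.index.has_duplicates:
            raise ValueError("duplicated circ ids in count table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicated sample labels in count table")
        if (counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        self.counts = counts
        self.covariates = dict(covariates or {})

    @property
    def circ_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def condition_of(self, sample: str) -> str:
        return self.covariates[sample]

    def sorted(self) -> "CountTable":
        return CountTable(self.counts.sort_index(), self.covariates)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and list(self.counts.index) == list(other.counts.index)
            and list(self.counts.columns) == list(other.counts.columns)
            and (self.counts.values == other.counts.values).all()
            and self.covariates == other.covariates
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountTable({self.shape[0]} circRNAs x {self.shape[1]} samples)"


# ---------------------------------------------------------------------------
# circRNA prediction dialects
# ---------------------------------------------------------------------------

KNOWN_TOOLS = ("ciri2", "starchip", "bed")


def parse_predictions(
    path: str | Path,
    tool: str,
    sample: str,
    errors: list[RowError] | None = None,
) -> list[CircRecord]:
    """Parse one tool's per-sample circRNA prediction file.

    Supported dialects:

    ``ciri2``
        Tab-separated with a header row; columns ``chr``, ``circRNA_start``,
        ``circRNA_end``, ``#junction_reads`` and optionally ``strand``.
        Coordinates are 1-based inclusive.
    ``starchip``
        Tab-separated, no header; first column a junction id formatted
        ``chrom:start-end:strand`` (1-based inclusive), second column the
        BS-supporting read count.
    ``bed``
        BED6 (``chrom start end name score strand``); already 0-based
        half-open; the score column carries the read count.  Other tools'
        outputs can be funnelled through this dialect.
    """
    if tool not in KNOWN_TOOLS:
        raise FormatError(f"unknown prediction tool {tool!r}; expected one of {KNOWN_TOOLS}")
    if errors is None:
        errors = []
    text = _read_text(path)
    if tool == "ciri2":
        return _parse_ciri2(text, sample, errors)
    if tool == "starchip":
        return _parse_starchip(text, sample, errors)
    return _parse_bed(text, sample, errors)


def _read_text(path: str | Path) -> str:
    raw = Path(path).read_bytes()
    if raw[:2] == b"\x1f\x8b":  # gzip magic, regardless of extension
        raw = gzip.decompress(raw)
    return raw.decode()


def _parse_ciri2(text: str, sample: str, errors: list[RowError]) -> list[CircRecord]:
    lines = text.splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    try:
        col = {name: header.index(name) for name in ("chr", "circRNA_start", "circRNA_end")}
        col["reads"] = header.index("#junction_reads")
    except ValueError as exc:
        raise FormatError(f"CIRI2 header missing required column: {exc}") from exc
    strand_col = header.index("strand") if "strand" in header else None
    records: list[CircRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            chrom = fields[col["chr"]]
            start1 = int(fields[col["circRNA_start"]])
            end1 = int(fields[col["circRNA_end"]])
            reads = int(fields[col["reads"]])
            strand = fields[strand_col] if strand_col is not None else "unknown"
            interval = GenomicInterval(chrom, start1 - 1, end1, _norm_strand(strand))
            records.append(CircRecord(interval, reads, sample=sample, tool="ciri2"))
        except (IndexError, ValueError) as exc:
            errors.append(RowError(lineno, f"malformed CIRI2 row: {exc}"))
    return records


def _parse_starchip(text: str, sample: str, errors: list[RowError]) -> list[CircRecord]:
    records: list[CircRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            junction = fields[0]
            chrom, coords, strand = junction.split(":")
            start1, end1 = coords.split("-")
            reads = int(float(fields[1]))
            interval = GenomicInterval(chrom, int(start1) - 1, int(end1), _norm_strand(strand))
            records.append(CircRecord(interval, reads, sample=sample, tool="starchip"))
        except (IndexError, ValueError) as exc:
            errors.append(RowError(lineno, f"malformed STARChip row: {exc}"))
    return records


def _parse_bed(text: str, sample: str, errors: list[RowError]) -> list[CircRecord]:
    records: list[CircRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split()
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            reads = int(fields[4]) if len(fields) > 4 and fields[4] != "." else 0
            strand = fields[5] if len(fields) > 5 else "unknown"
            interval = GenomicInterval(chrom, start, end, _norm_strand(strand))
            records.append(CircRecord(interval, reads, sample=sample, tool="bed"))
        except (IndexError, ValueError) as exc:
            errors.append(RowError(lineno, f"malformed BED row: {exc}"))
    return records


def _norm_strand(strand: str) -> str:
    if strand in ("+", "-"):
        return strand
    logger.warning("strand %r treated as unknown (defaults to '+' downstream)", strand)
    return "unknown"


def write_predictions(records: Sequence[CircRecord], path: str | Path) -> None:
    """Write circRNA records as a BED6-style TSV (internal coordinates)."""
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end)):
            strand = rec.interval.strand if rec.interval.strand != "unknown" else "."
            fh.write(
                f"{rec.interval.chrom}\t{rec.interval.start}\t{rec.interval.end}"
                f"\t{rec.id}\t{rec.bs_reads}\t{strand}\n"
            )


def read_predictions_tsv(path: str | Path, sample: str = "", errors: list[RowError] | None = None) -> list[CircRecord]:
    """Read the BED6-style TSV written by :func:`write_predictions`."""
    return parse_predictions(path, "bed", sample, errors)


# ---------------------------------------------------------------------------
# Exon annotation
# ---------------------------------------------------------------------------

_EXON_TSV_COLUMNS = ["chrom", "start", "end", "strand", "transcript_id", "gene_id", "gene_name", "exon_rank"]


def read_exon_annotation(
    path: str | Path,
    format: str = "gtf",
    errors: list[RowError] | None = None,
) -> list[ExonRecord]:
    """Read exon records from a GTF file or a flat exon TSV.

    GTF coordinates (1-based inclusive) are converted to the internal
    convention.  ``exon_rank`` is taken from the GTF ``exon_number`` attribute
    or the TSV ``exon_rank`` column when present, and otherwise computed by
    traversing each transcript's exons in transcript orientation (ascending
    start on '+', descending on '-').
    """
    if errors is None:
        errors = []
    if format == "gtf":
        exons, needs_rank = _read_gtf_exons(path, errors)
    elif format == "tsv":
        exons, needs_rank = _read_exon_tsv(path, errors)
    else:
        raise FormatError(f"unknown annotation format {format!r}")
    _fill_missing_ranks(exons, needs_rank)
    exons.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return exons


def _read_gtf_exons(
    path: str | Path, errors: list[RowError]
) -> tuple[list[ExonRecord], set[str]]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: list[ExonRecord] = []
    needs_rank: set[str] = set()
    for n, feat in enumerate(db.features_of_type("exon"), start=1):
        try:
            transcript_id = feat.attributes["transcript_id"][0]
        except KeyError:
            errors.append(RowError(n, "exon feature missing transcript_id"))
            continue
        gene_id = feat.attributes.get("gene_id", [""])[0]
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        rank_attr = feat.attributes.get("exon_number", [None])[0]
        start0, end0 = feat.start - 1, feat.end  # GTF is 1-based inclusive
        if start0 >= end0 or start0 < 0:
            errors.append(RowError(n, f"invalid exon coordinates {feat.start}-{feat.end}"))
            continue
        exons.append(
            ExonRecord(
                GenomicInterval(feat.seqid, start0, end0, _norm_strand(feat.strand)),
                transcript_id=transcript_id,
                gene_id=gene_id,
                gene_name=gene_name,
                exon_rank=int(rank_attr) if rank_attr is not None else 1,
            )
        )
        if rank_attr is None:
            needs_rank.add(transcript_id)
    return exons, needs_rank


def _read_exon_tsv(
    path: str | Path, errors: list[RowError]
) -> tuple[list[ExonRecord], set[str]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EXON_TSV_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"exon TSV missing columns: {sorted(missing)}")
    exons: list[ExonRecord] = []
    needs_rank: set[str] = set()
    for n, row in enumerate(df.itertuples(index=False), start=2):
        try:
            if not row.transcript_id or pd.isna(row.transcript_id):
                raise ValueError("missing transcript_id")
            has_rank = "exon_rank" in df.columns and not pd.isna(row.exon_rank)
            rank = int(row.exon_rank) if has_rank else 1
            if not has_rank:
                needs_rank.add(str(row.transcript_id))
            exons.append(
                ExonRecord(
                    GenomicInterval(str(row.chrom), int(row.start), int(row.end), _norm_strand(str(row.strand))),
                    transcript_id=str(row.transcript_id),
                    gene_id=str(row.gene_id),
                    gene_name=str(getattr(row, "gene_name", "") or ""),
                    exon_rank=rank,
                )
            )
        except ValueError as exc:
            errors.append(RowError(n, f"malformed exon row: {exc}"))
    return exons, needs_rank


def _fill_missing_ranks(exons: list[ExonRecord], needs_rank: set[str]) -> None:
    """Compute exon_rank by transcript-orientation order where the file had none."""
    by_tx: dict[str, list[ExonRecord]] = {}
    for exon in exons:
        if exon.transcript_id in needs_rank:
            by_tx.setdefault(exon.transcript_id, []).append(exon)
    for tx_exons in by_tx.values():
        reverse = tx_exons[0].interval.strand == "-"
        ordered = sorted(tx_exons, key=lambda e: e.interval.start, reverse=reverse)
        for rank, exon in enumerate(ordered, start=1):
            exon.exon_rank = rank


def write_exon_tsv(exons: Sequence[ExonRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": e.interval.chrom,
            "start": e.interval.start,
            "end": e.interval.end,
            "strand": e.interval.strand,
            "transcript_id": e.transcript_id,
            "gene_id": e.gene_id,
            "gene_name": e.gene_name,
            "exon_rank": e.exon_rank,
        }
        for e in exons
    ]
    pd.DataFrame(rows, columns=_EXON_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def write_count_table(
    table: CountTable,
    path: str | Path,
    covariates_path: str | Path | None = None,
) -> None:
    """Write a count table (and optionally its covariates) as TSV.

    Rows are written in the table's id order; write ``table.sorted()`` for the
    canonical byte-stable layout.  Counts that are integral are written as
    integers.
    """
    df = table.counts.copy()
    if (df.values == df.values.astype(int)).all():
        df = df.astype(int)
    df.index.name = "circ_id"
    df.to_csv(path, sep="\t")
    if covariates_path is not None:
        cov = pd.DataFrame(
            {"sample": table.samples, "condition": [table.covariates.get(s, "") for s in table.samples]}
        )
        cov.to_csv(covariates_path, sep="\t", index=False)


def read_count_table(
    path: str | Path,
    covariates_path: str | Path | None = None,
) -> CountTable:
    """Read a TSV count table written by :func:`write_count_table`."""
    df = pd.read_csv(path, sep="\t", index_col="circ_id", dtype=str)
    df.index = df.index.astype(str)
    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    if not (counts.values == counts.values.astype(int)).all():
        raise FormatError(f"non-integer count in {path}")
    counts = counts.astype(int)
    if counts.index.has_duplicates:
        raise FormatError(f"duplicated circ id in {path}")
    covariates: dict[str, str] = {}
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, sep="\t", dtype=str)
        covariates = dict(zip(cov["sample"], cov["condition"]))
    return CountTable(counts, covariates)


# ---------------------------------------------------------------------------
# Sequences: genome FASTA and FASTQ reads
# ---------------------------------------------------------------------------


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA fully into memory as chrom -> sequence.

    For large genomes prefer ``pyfaidx.Fasta``; every function that takes a
    genome accepts either, via :func:`fetch_sequence`.
    """
    from Bio import SeqIO

    raw = Path(path).read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    handle = io.StringIO(raw.decode())
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Slice ``genome[chrom][start:end]`` from a dict or a pyfaidx.Fasta."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom][start:end]
    return str(seq).upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as an uncompressed two-line-record FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def iter_fastq(
    path: str | Path,
    errors: list[RowError] | None = None,
) -> Iterator[tuple[str, str]]:
    """Iterate (read id, sequence) over a FASTQ file, plain or gzipped.

    Gzip is detected from magic bytes.  Structurally broken records (missing
    header/separator, sequence/quality length mismatch) are skipped and
    reported through ``errors`` rather than aborting the stream, so a single
    corrupt record does not lose a whole lane.
    """
    if errors is None:
        errors = []
    raw = Path(path).read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    lines = raw.decode().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        chunk = lines[i : i + 4]
        if len(chunk) < 4:
            errors.append(RowError(i + 1, "truncated FASTQ record"))
            break
        header, seq, sep, qual = chunk
        if not header.startswith("@") or not sep.startswith("+") or len(seq) != len(qual):
            errors.append(RowError(i + 1, "malformed FASTQ record"))
            i += 4
            continue
        yield header[1:].split()[0], seq.upper()
        i += 4


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTQ with constant 'I' qualities."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
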