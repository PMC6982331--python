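"""Seed-deterministic synthetic fixtures: genome, annotation, circRNAs, reads.

The generator emulates the shape of a bulk total-RNA-Seq circRNA experiment
at desk scale: an i.i.d.-base genome, non-overlapping multi-exon transcripts,
a truth set of circRNAs planted per class (exon-boundary circRNAs for
monoexonic/multiexonic, offset-into-exon for putative_exon, intron-interior
for intronic, between-transcript for intergenic), and 75 bp reads — planted
junction-spanning reads drawn across each circRNA's back-splice point plus
linear background reads.

Background reads are rejection-sampled so that none shares a 30 bp exact
block with any planted junction sequence, which makes zero-false-positive
assertions on the quantifier exact rather than probabilistic.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bsjunction import reconstruct_bs_sequence
from .classify import INTERGENIC, INTRONIC, MONOEXONIC, MULTIEXONIC, PUTATIVE_EXON
from .io_formats import CircRecord, ExonRecord, GenomicInterval, revcomp, write_fasta, write_fastq

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_CLASS_MIX = {
    MONOEXONIC: 0.3,
    MULTIEXONIC: 0.3,
    PUTATIVE_EXON: 0.2,
    INTRONIC: 0.1,
    INTERGENIC: 0.1,
}


@dataclass
class SimConfig:
    """Shape of the synthetic experiment (defaults emulate 75 bp bulk RNA-Seq)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 50_000
    n_transcripts: int = 16
    exons_per_transcript: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (100, 300)
    intergenic_gap_range: tuple[int, int] = (200, 600)
    n_circs: int = 12
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    reads_per_circ: int = 10
    n_background_reads: int = 1000
    read_length: int = 75
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length, self.n_transcripts) < 1:
            raise ValueError("genome shape parameters must be positive")
        if self.n_circs < 0 or self.reads_per_circ < 0 or self.n_background_reads < 0:
            raise ValueError("counts must be >= 0")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions must sum to 1 (got {total})")
        if self.read_length > self.chrom_length:
            raise ValueError("read_length exceeds chrom_length")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _allocate(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n circRNAs to categories."""
    cats = sorted(mix)
    raw = {c: n * mix[c] for c in cats}
    counts = {c: int(raw[c]) for c in cats}
    leftover = n - sum(counts.values())
    for c in sorted(cats, key=lambda c: raw[c] - counts[c], reverse=True)[:leftover]:
        counts[c] += 1
    return counts


def simulate_genome_annotation(
    config: SimConfig,
) -> tuple[dict[str, str], list[ExonRecord], list[tuple[CircRecord, str]]]:
    """Generate (genome, exon annotation, circRNA truth set).

    Transcripts are tiled left to right with intergenic gaps; circRNAs are
    planted so that each truth label is recoverable by construction
    (boundary-exact coordinates for exonic classes, >= 1 bp offsets for
    putative_exon, >= 2 bp margins for intronic/intergenic).  All planted
    spans are >= 80 bp so that default-flank junction reconstruction and
    75 bp junction reads are well defined.
    """
    rng = np.random.default_rng(config.seed)
    genome = {f"chr{i + 1}": _random_sequence(rng, config.chrom_length) for i in range(config.n_chroms)}

    exons: list[ExonRecord] = []
    transcripts: list[dict] = []  # chrom, strand, exons (list of (start, end)), span
    gaps: list[tuple[str, int, int]] = []
    tx_i = 0
    for chrom in genome:
        pos = 0
        while tx_i < config.n_transcripts:
            gap = int(rng.integers(*config.intergenic_gap_range))
            n_exons = int(rng.integers(config.exons_per_transcript[0], config.exons_per_transcript[1] + 1))
            exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
            intron_lens = rng.integers(*config.intron_length_range, size=max(n_exons - 1, 0))
            tx_len = int(exon_lens.sum() + intron_lens.sum())
            if pos + gap + tx_len + 2 > config.chrom_length:
                break
            gaps.append((chrom, pos, pos + gap))
            start = pos + gap
            strand = "+" if rng.random() < 0.5 else "-"
            coords = []
            p = start
            for idx in range(n_exons):
                coords.append((p, p + int(exon_lens[idx])))
                p += int(exon_lens[idx])
                if idx < n_exons - 1:
                    p += int(intron_lens[idx])
            transcripts.append({"chrom": chrom, "strand": strand, "exons": coords, "id": tx_i})
            ranks = range(1, n_exons + 1) if strand == "+" else range(n_exons, 0, -1)
            for (s, e), rank in zip(coords, ranks):
                exons.append(
                    ExonRecord(
                        GenomicInterval(chrom, s, e, strand),
                        transcript_id=f"tx_{tx_i}",
                        gene_id=f"gene_{tx_i}",
                        gene_name=f"GENE{tx_i}",
                        exon_rank=rank,
                    )
                )
            pos = p
            tx_i += 1
        gaps.append((chrom, pos, config.chrom_length))
    if tx_i < config.n_transcripts:
        raise ValueError(
            f"genome too small: placed {tx_i}/{config.n_transcripts} transcripts; "
            "increase chrom_length or n_chroms"
        )

    counts = _allocate(config.n_circs, config.class_mix)
    truth: list[tuple[CircRecord, str]] = []
    used: set[str] = set()

    def plant(interval: GenomicInterval, category: str) -> bool:
        circ = CircRecord(interval, bs_reads=0, tool="synthetic")
        if circ.id in used:
            return False
        used.add(circ.id)
        truth.append((circ, category))
        return True

    min_span = 80  # keeps 35 bp flanks and 75 bp junction reads well defined
    order = rng.permutation(len(transcripts))
    for category, n_cat in counts.items():
        planted = 0
        attempts = 0
        while planted < n_cat:
            attempts += 1
            if attempts > 200 * max(n_cat, 1):
                raise ValueError(f"could not plant {n_cat} {category} circRNAs; genome too crowded")
            if category == INTERGENIC:
                chrom, gs, ge = gaps[int(rng.integers(len(gaps)))]
                if ge - gs < min_span + 6:
                    continue
                span = int(rng.integers(min_span, min(ge - gs - 4, 300)))
                start = int(rng.integers(gs + 2, ge - span - 2 + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                if plant(GenomicInterval(chrom, start, start + span, strand), category):
                    planted += 1
                continue
            tx = transcripts[int(order[int(rng.integers(len(order)))])]
            chrom, strand, coords = tx["chrom"], tx["strand"], tx["exons"]
            if category == MONOEXONIC:
                s, e = coords[int(rng.integers(len(coords)))]
                if e - s < min_span:
                    continue
                ok = plant(GenomicInterval(chrom, s, e, strand), category)
            elif category == MULTIEXONIC:
                if len(coords) < 2:
                    continue
                i = int(rng.integers(0, len(coords) - 1))
                j = int(rng.integers(i + 1, len(coords)))
                ok = plant(GenomicInterval(chrom, coords[i][0], coords[j][1], strand), category)
            elif category == PUTATIVE_EXON:
                s, e = coords[int(rng.integers(len(coords)))]
                if e - s < min_span + 5:
                    continue
                offset = int(rng.integers(1, e - s - min_span + 1))
                ok = plant(GenomicInterval(chrom, s + offset, e, strand), category)
            elif category == INTRONIC:
                if len(coords) < 2:
                    continue
                i = int(rng.integers(0, len(coords) - 1))
                istart, iend = coords[i][1], coords[i + 1][0]
                if iend - istart < min_span + 6:
                    continue
                ok = plant(GenomicInterval(chrom, istart + 2, iend - 2, strand), category)
            else:
                raise ValueError(f"unknown category in class_mix: {category}")
            if ok:
                planted += 1

    exons.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    truth.sort(key=lambda t: t[0].id)
    return genome, exons, truth


def _add_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.where(rng.random(arr.size) < error_rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_reads(
    genome: dict[str, str],
    truth: list[tuple[CircRecord, str]],
    config: SimConfig,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Generate (reads, planted per-circRNA junction-read counts).

    For every truth circRNA, ``reads_per_circ`` junction-spanning reads are
    drawn from the circularized sequence: a read with ``j`` bases upstream of
    the junction point reads ``genome[end-j:end] + genome[start:...]``, with
    ``j`` uniform over the read interior leaving >= 5 bp on each side; minus
    strand circRNAs yield the reverse complement.  Background reads are
    linear genome windows screened to share no 30 bp block with any planted
    junction sequence.  Substitution errors are applied at ``error_rate``.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.read_length
    reads: list[tuple[str, str]] = []
    planted: dict[str, int] = {}

    block = 30
    junction_blocks: set[str] = set()
    for circ, _ in truth:
        bsj = reconstruct_bs_sequence(circ, genome, flank=35)
        for oriented in (bsj.sequence, revcomp(bsj.sequence)):
            for i in range(len(oriented) - block + 1):
                junction_blocks.add(oriented[i : i + block])

    for circ, _ in truth:
        iv = circ.interval
        if iv.span < L:
            logger.warning("%s span %d < read length %d; no junction reads planted", circ.id, iv.span, L)
            planted[circ.id] = 0
            continue
        chrom_seq = genome[iv.chrom]
        n = 0
        for _ in range(config.reads_per_circ):
            j = int(rng.integers(5, L - 5 + 1))  # bases upstream of the junction
            seq = chrom_seq[iv.end - j : iv.end] + chrom_seq[iv.start : iv.start + (L - j)]
            if iv.strand == "-":
                seq = revcomp(seq)
            seq = _add_errors(rng, seq, config.error_rate)
            reads.append((f"circ|{circ.id}|{n}", seq))
            n += 1
        planted[circ.id] = n

    chroms = list(genome)
    accepted = 0
    attempts = 0
    while accepted < config.n_background_reads:
        attempts += 1
        if attempts > 50 * max(config.n_background_reads, 1) + 1000:
            raise RuntimeError("background read rejection sampling did not converge")
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, len(genome[chrom]) - L + 1))
        seq = genome[chrom][start : start + L]
        if any(seq[i : i + block] in junction_blocks for i in range(L - block + 1)):
            continue
        if rng.random() < 0.5:
            seq = revcomp(seq)
        seq = _add_errors(rng, seq, config.error_rate)
        reads.append((f"bg|{accepted}", seq))
        accepted += 1
    return reads, planted


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------


def write_gtf(exons: list[ExonRecord], path: str | Path) -> None:
    """Write exon records as a minimal GTF (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for e in exons:
            attrs = (
                f'gene_id "{e.gene_id}"; transcript_id "{e.transcript_id}"; '
                f'gene_name "{e.gene_name}"; exon_number "{e.exon_rank}";'
            )
            fh.write(
                f"{e.interval.chrom}\tcircjkit\texon\t{e.interval.start + 1}\t{e.interval.end}"
                f"\t.\t{e.interval.strand}\t.\t{attrs}\n"
            )


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a full fixture set (genome.fa, annotation.gtf, truth.tsv, reads.fq.gz)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, exons, truth = simulate_genome_annotation(config)
    reads, planted = simulate_reads(genome, truth, config)
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.gtf",
        "truth": out / "truth.tsv",
        "reads": out / "reads.fq.gz",
    }
    write_fasta(genome.items(), paths["genome"])
    write_gtf(exons, paths["annotation"])
    with open(paths["truth"], "w") as fh:
        fh.write("circ_id\tchrom\tstart\tend\tstrand\tcategory\tplanted_reads\n")
        for circ, category in truth:
            iv = circ.interval
            fh.write(
                f"{circ.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{category}"
                f"\t{planted.get(circ.id, 0)}\n"
            )
    write_fastq(reads, paths["reads"])
    return paths
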