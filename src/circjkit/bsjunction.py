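"""Back-splice junction (BSJ) sequence reconstruction.

Circularization joins the 3' end of a circRNA back to its 5' start, so the
junction context does not exist anywhere in the linear genome.  It is
reconstructed by concatenating the last ``flank`` genomic bases of the
circRNA interval with its first ``flank`` bases: with the default 35 bp
flank this yields the 70 bp junction sequence with the junction point at
offset 35.  Flanks are truncated to the circRNA span, so short circRNAs give
shorter sequences instead of wrapping around the junction twice.  For minus
strand circRNAs the plus-strand construction is reverse complemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io_formats import CircRecord, chrom_length, fetch_sequence, revcomp, write_fasta

DEFAULT_FLANK = 35


@dataclass(frozen=True)
class BSJunctionSeq:
    """A reconstructed junction sequence.

    ``sequence[:junction_offset]`` derives from the circRNA 3' end and
    ``sequence[junction_offset:]`` from its 5' start (in plus-strand genomic
    terms); ``flank`` is the requested flank size.
    """

    circ_id: str
    sequence: str
    junction_offset: int
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if not (0 < self.junction_offset < len(self.sequence)) and len(self.sequence) > 0:
            raise ValueError("junction_offset must lie strictly inside the sequence")
        if len(self.sequence) > 2 * self.flank:
            raise ValueError("sequence longer than two flanks")

    def __len__(self) -> int:
        return len(self.sequence)


def _clean(seq: str) -> str:
    return "".join(b if b in "ACGT" else "N" for b in seq.upper())


def reconstruct_bs_sequence(circ: CircRecord, genome, flank: int = DEFAULT_FLANK) -> BSJunctionSeq:
    """Reconstruct the BSJ sequence of one circRNA from the genome.

    ``genome`` is a chrom -> sequence mapping (dict or ``pyfaidx.Fasta``).
    A circRNA of span >= ``flank`` yields a sequence of ``2 * flank`` bases
    with the junction in the middle; shorter spans truncate both flanks to
    the span.  Strand ``-`` reverse-complements the plus-strand result;
    strand ``unknown`` is treated as ``+``.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    iv = circ.interval
    if iv.chrom not in genome:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    if iv.end > chrom_length(genome, iv.chrom):
        raise ValueError(f"{circ.id} extends past the end of {iv.chrom}")
    f = min(flank, iv.span)
    left = fetch_sequence(genome, iv.chrom, iv.end - f, iv.end)
    right = fetch_sequence(genome, iv.chrom, iv.start, iv.start + f)
    seq = _clean(left + right)
    if iv.strand == "-":
        seq = revcomp(seq)
    return BSJunctionSeq(circ.id, seq, junction_offset=f, flank=flank)


def reconstruct_all(circs: Sequence[CircRecord], genome, flank: int = DEFAULT_FLANK) -> list[BSJunctionSeq]:
    return [reconstruct_bs_sequence(c, genome, flank) for c in circs]


def write_bsj_fasta(seqs: Sequence[BSJunctionSeq], path: str | Path) -> None:
    """Write BSJ sequences as FASTA, sorted by id (byte-deterministic)."""
    ids = [s.circ_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate BSJ ids")
    bad = [i for i in ids if any(ch.isspace() for ch in i)]
    if bad:
        raise ValueError(f"BSJ ids may not contain whitespace: {bad}")
    write_fasta(((s.circ_id, s.sequence) for s in sorted(seqs, key=lambda s: s.circ_id)), path)


def read_bsj_fasta(path: str | Path, flank: int = DEFAULT_FLANK) -> list[BSJunctionSeq]:
    """Read a BSJ FASTA back; the junction is assumed at the sequence midpoint.

    Junction sequences produced with symmetric flanks always have an even
    length with the junction in the middle, so the midpoint convention
    round-trips :func:`write_bsj_fasta` output exactly.
    """
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        out.append(BSJunctionSeq(rec.id, seq, junction_offset=len(seq) // 2, flank=flank))
    return out
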