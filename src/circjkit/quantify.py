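"""Alignment-free counting of back-splice-junction (BSJ) supporting reads.

Counting is a two-step procedure over a set of reconstructed BSJ sequences:

1. **k-mer prefilter** — every k-mer of every BSJ sequence (and of its
   reverse complement, so the filter is orientation-blind) is inserted into a
   fixed-capacity hash table with per-bucket collision lists.  A read passes
   when at least ``min_shared_kmers`` of its k-mer positions hit the table.
   Membership answers are exact: collisions only grow bucket lists, they
   never produce false positives or negatives, so the capacity trades memory
   against speed only.
2. **Smith–Waterman confirmation** — each passing read is locally aligned
   (affine gaps) against the BSJ sequences in both orientations.  A read
   supports a circRNA when the best alignment has at least ``min_matches``
   matched bases and, by default, crosses the junction point — a match lying
   wholly inside one flank is equally consistent with the linear transcript
   and is not back-splicing evidence.

Default parameters (k=21, 17 shared k-mers, 30 matched bases, table capacity
1,000,003) are tuned for 75 bp reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .bsjunction import BSJunctionSeq
from .io_formats import CountTable, RowError, iter_fastq, revcomp

__all__ = [
    "QuantParams",
    "KmerIndex",
    "AlignmentResult",
    "build_kmer_index",
    "prefilter_read",
    "align_confirm",
    "count_bs_reads",
    "smith_waterman",
]


@dataclass(frozen=True)
class QuantParams:
    """Parameters of the two-step BSJ read counter.

    ``min_matches`` is interpreted according to ``match_mode``: the number of
    matched bases in the best local alignment (``"bases"``, default) or the
    longest contiguous exact stretch within it (``"contiguous"``).
    """

    k: int = 21
    min_shared_kmers: int = 17
    min_matches: int = 30
    table_capacity: int = 1_000_003
    collision_dim: int | None = None
    threads: int = 1
    require_junction_span: bool = True
    match_mode: str = "bases"
    ties: str = "fractional"  # or "all"
    sw_match: int = 2
    sw_mismatch: int = -2
    sw_gap_open: int = 3  # cost of the first base of a gap
    sw_gap_extend: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 31):
            raise ValueError("k must be in [1, 31]")
        if self.min_shared_kmers < 1 or self.min_matches < 1:
            raise ValueError("min_shared_kmers and min_matches must be >= 1")
        if self.table_capacity < 1:
            raise ValueError("table_capacity must be >= 1")
        if self.match_mode not in ("bases", "contiguous"):
            raise ValueError("match_mode must be 'bases' or 'contiguous'")
        if self.ties not in ("fractional", "all"):
            raise ValueError("ties must be 'fractional' or 'all'")


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_kmers(seq: str, k: int) -> list[int | None]:
    """2-bit encodings of all k-mers of ``seq``; None where a k-mer holds a non-ACGT base."""
    n = len(seq)
    if n < k:
        return []
    codes = [_ENC.get(b, -1) for b in seq]
    out: list[int | None] = []
    mask = (1 << (2 * k)) - 1
    val = 0
    invalid = 0  # bases remaining until the window is clean again
    for i, c in enumerate(codes):
        if c < 0:
            invalid = k
            val = (val << 2) & mask
        else:
            val = ((val << 2) | c) & mask
            if invalid:
                invalid -= 1
        if i >= k - 1:
            out.append(None if invalid else val)
    return out


class KmerIndex:
    """Fixed-capacity hash table answering exact k-mer membership.

    Buckets are addressed by ``encoded_kmer % capacity`` and hold collision
    lists of ``(encoded_kmer, source BSJ ids)``; lookups compare the full
    encoding, so membership is exact at any capacity.  ``collision_dim``
    optionally caps the collision-list length (overflow raises), mirroring a
    fixed-size collision array.
    """

    def __init__(self, k: int, capacity: int = 1_000_003, collision_dim: int | None = None) -> None:
        if capacity < 1:
            raise ValueError("hash table capacity must be >= 1")
        self.k = k
        self.capacity = capacity
        self.collision_dim = collision_dim
        self._buckets: dict[int, list[tuple[int, list[str]]]] = {}
        self.n_kmers = 0

    def insert(self, encoded: int, source_id: str) -> None:
        bucket = self._buckets.setdefault(encoded % self.capacity, [])
        for key, ids in bucket:
            if key == encoded:
                if source_id not in ids:
                    ids.append(source_id)
                return
        if self.collision_dim is not None and len(bucket) >= self.collision_dim:
            raise OverflowError(
                f"collision list full (dim={self.collision_dim}) in bucket {encoded % self.capacity}"
            )
        bucket.append((encoded, [source_id]))
        self.n_kmers += 1

    def add_sequence(self, seq: str, source_id: str) -> None:
        """Insert every k-mer of ``seq`` and of its reverse complement."""
        for oriented in (seq, revcomp(seq)):
            for enc in _encode_kmers(oriented.upper(), self.k):
                if enc is not None:
                    self.insert(enc, source_id)

    def lookup(self, encoded: int) -> list[str] | None:
        for key, ids in self._buckets.get(encoded % self.capacity, ()):
            if key == encoded:
                return ids
        return None

    def contains(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer")
        encs = _encode_kmers(kmer.upper(), self.k)
        return bool(encs) and encs[0] is not None and self.lookup(encs[0]) is not None


def build_kmer_index(
    bsj_seqs: Sequence[BSJunctionSeq],
    params: QuantParams = QuantParams(),
    errors: list[RowError] | None = None,
) -> KmerIndex:
    """Index all k-mers (both orientations) of the BSJ sequence set.

    BSJ sequences shorter than ``k`` are skipped and reported via ``errors``.
    """
    if errors is None:
        errors = []
    index = KmerIndex(params.k, params.table_capacity, params.collision_dim)
    for n, bsj in enumerate(bsj_seqs, start=1):
        if len(bsj.sequence) < params.k:
            errors.append(RowError(n, f"BSJ {bsj.circ_id} shorter than k={params.k}"))
            continue
        index.add_sequence(bsj.sequence, bsj.circ_id)
    return index


def prefilter_read(read: str, index: KmerIndex, params: QuantParams = QuantParams()) -> tuple[bool, int]:
    """Count read k-mer positions found in the index.

    Returns ``(passes, shared)`` with ``passes`` true when ``shared`` reaches
    ``min_shared_kmers``.  Because the index holds both orientations of every
    BSJ k-mer, the count is identical for a read and its reverse complement.
    """
    shared = 0
    for enc in _encode_kmers(read.upper(), params.k):
        if enc is not None and index.lookup(enc) is not None:
            shared += 1
    return shared >= params.min_shared_kmers, shared


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment (affine gaps) with match-counting traceback
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sw_fill(a: np.ndarray, b: np.ndarray, match: int, mismatch: int, open_: int, ext: int):
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**9, dtype=np.int32)  # gap consuming a (vertical)
    F = np.full((n + 1, m + 1), -10**9, dtype=np.int32)  # gap consuming b (horizontal)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 opened from H, 0 extended
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - open_
            e_ext = E[i - 1, j] - ext
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i, j - 1] - open_
            f_ext = F[i, j - 1] - ext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, ptrH, ptrE, ptrF, best, bi, bj


_SW_CODES = np.full(128, 4, dtype=np.int8)
for _b, _c in _ENC.items():
    _SW_CODES[ord(_b)] = _c
_SW_CODES[ord("N")] = 4


def _encode_for_sw(seq: str, parity: int) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = _SW_CODES[arr]
    # every non-ACGT base gets a unique negative code (odd for one sequence,
    # even for the other) so ambiguous bases never count as matches
    bad = np.where(out == 4)[0]
    out = out.astype(np.int32)
    out[bad] = -(2 * bad.astype(np.int32) + 4 + parity)
    return out


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a read against one BSJ sequence."""

    score: int
    n_matches: int
    longest_run: int
    read_span: tuple[int, int]
    ref_span: tuple[int, int]
    crosses_junction: bool = False
    reverse_complemented: bool = False


def smith_waterman(
    read: str,
    ref: str,
    match: int = 2,
    mismatch: int = -2,
    gap_open: int = 3,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Best-scoring local alignment; a gap of length L costs open + (L-1)*extend."""
    if not read:
        raise ValueError("empty read")
    if not ref:
        raise ValueError("empty reference")
    a = _encode_for_sw(read, 0)
    b = _encode_for_sw(ref, 1)
    H, ptrH, ptrE, ptrF, best, bi, bj = _sw_fill(a, b, match, mismatch, gap_open, gap_extend)
    if best <= 0:
        return AlignmentResult(0, 0, 0, (0, 0), (0, 0))
    i, j = bi, bj
    n_matches = 0
    run = 0
    longest = 0
    state = 0  # 0: in H, 2: in E, 3: in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                if a[i - 1] == b[j - 1]:
                    n_matches += 1
                    run += 1
                    longest = max(longest, run)
                else:
                    run = 0
                i -= 1
                j -= 1
            else:
                state = p
                run = 0
        elif state == 2:
            if ptrE[i, j] == 1:
                state = 0
            i -= 1
        else:
            if ptrF[i, j] == 1:
                state = 0
            j -= 1
    return AlignmentResult(int(best), n_matches, longest, (i, bi), (j, bj))


def align_confirm(
    read: str,
    bsj: BSJunctionSeq,
    params: QuantParams = QuantParams(),
    orientation: str = "forward",
) -> AlignmentResult:
    """Smith–Waterman the read against one BSJ and flag junction crossing.

    The alignment crosses the junction when its reference span contains both
    the last base of the left flank (``junction_offset - 1``) and the first
    base of the right flank (``junction_offset``).
    """
    seq = revcomp(read) if orientation == "reverse" else read
    res = smith_waterman(
        seq, bsj.sequence, params.sw_match, params.sw_mismatch, params.sw_gap_open, params.sw_gap_extend
    )
    jo = bsj.junction_offset
    crosses = res.ref_span[0] <= jo - 1 and res.ref_span[1] >= jo + 1
    return replace(res, crosses_junction=crosses, reverse_complemented=orientation == "reverse")


def _match_stat(res: AlignmentResult, params: QuantParams) -> int:
    return res.n_matches if params.match_mode == "bases" else res.longest_run


def _rank_key(res: AlignmentResult, params: QuantParams) -> tuple[int, int]:
    # Rank by alignment score first: with affine gaps this cheap, the optimal
    # local alignment of two *unrelated* sequences still accumulates many
    # scattered matched bases, so the raw match count does not discriminate
    # the true junction from lookalikes — the score does.
    return res.score, _match_stat(res, params)


def best_alignment(read: str, bsj: BSJunctionSeq, params: QuantParams) -> AlignmentResult:
    """Best orientation of the read against one BSJ (forward preferred on ties)."""
    fwd = align_confirm(read, bsj, params, "forward")
    rev = align_confirm(read, bsj, params, "reverse")
    return fwd if _rank_key(fwd, params) >= _rank_key(rev, params) else rev


def confirms(res: AlignmentResult, params: QuantParams) -> bool:
    """The confirmation predicate on one best-orientation alignment."""
    if _match_stat(res, params) < params.min_matches:
        return False
    if params.require_junction_span and not res.crosses_junction:
        return False
    return True


def assign_read(
    read: str, bsj_seqs: Sequence[BSJunctionSeq], params: QuantParams
) -> list[str]:
    """BSJ ids credited for one (prefilter-passing) read.

    The read is first *assigned* to its best-aligning BSJ(s) — highest score,
    ties on score broken by matched bases, exact ties shared — and only then
    checked against the confirmation predicate.  Assign-then-confirm keeps
    counts monotone in the thresholds: raising ``min_matches`` can only drop
    a read, never re-route it to a different circRNA.
    """
    results = [(bsj.circ_id, best_alignment(read, bsj, params)) for bsj in bsj_seqs]
    best_key = max(_rank_key(r, params) for _, r in results)
    if best_key <= (0, 0):
        return []
    tied = [(cid, r) for cid, r in results if _rank_key(r, params) == best_key]
    return [cid for cid, r in tied if confirms(r, params)]


def _count_chunk(
    reads: Sequence[tuple[str, str]],
    bsj_seqs: Sequence[BSJunctionSeq],
    index: KmerIndex,
    params: QuantParams,
) -> dict[str, float]:
    counts: dict[str, float] = {}
    for _, seq in reads:
        passes, _ = prefilter_read(seq, index, params)
        if not passes:
            continue
        credited = assign_read(seq, bsj_seqs, params)
        if not credited:
            continue
        weight = 1.0 if params.ties == "all" else 1.0 / len(credited)
        for cid in credited:
            counts[cid] = counts.get(cid, 0.0) + weight
    return counts


def count_bs_reads(
    reads: Iterable[tuple[str, str]] | str | Path,
    bsj_seqs: Sequence[BSJunctionSeq],
    params: QuantParams = QuantParams(),
    sample: str = "sample",
    errors: list[RowError] | None = None,
) -> CountTable:
    """Count BS-supporting reads per circRNA over one sample's reads.

    ``reads`` may be an iterable of ``(read_id, sequence)`` pairs or a FASTQ
    path (plain or gzipped).  A read is counted for a circRNA when it passes
    the k-mer prefilter and its best-orientation alignment to that circRNA's
    BSJ satisfies the confirmation predicate; a read satisfying several
    circRNAs is assigned to the best one (exact ties split fractionally by
    default).  With ``params.threads > 1`` reads are processed in chunks in a
    thread pool; chunk results are merged in input order, so counts do not
    depend on the thread count.
    """
    ids = [b.circ_id for b in bsj_seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate BSJ ids")
    if errors is None:
        errors = []
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads, errors)
    index = build_kmer_index(bsj_seqs, params, errors)
    read_list = list(reads)

    if params.threads > 1 and len(read_list) > 1:
        from concurrent.futures import ThreadPoolExecutor

        n_chunks = min(params.threads * 4, len(read_list))
        chunks = [read_list[i::n_chunks] for i in range(n_chunks)]
        with ThreadPoolExecutor(max_workers=params.threads) as pool:
            partials = list(pool.map(lambda ch: _count_chunk(ch, bsj_seqs, index, params), chunks))
    else:
        partials = [_count_chunk(read_list, bsj_seqs, index, params)]

    totals: dict[str, float] = {cid: 0.0 for cid in ids}
    for part in partials:
        for cid, val in part.items():
            totals[cid] += val
    values = np.array([totals[cid] for cid in sorted(ids)])
    if np.allclose(values, np.round(values)):
        values = values.astype(int)
    df = pd.DataFrame({sample: values}, index=sorted(ids))
    df.index.name = "circ_id"
    return CountTable(df)
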