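"""k-mer prefilter, Smith–Waterman confirmation and two-step read counting."""

import numpy as np
import pytest

from circjkit.bsjunction import BSJunctionSeq, reconstruct_all
from circjkit.io_formats import revcomp
from circjkit.quantify import (
    KmerIndex,
    QuantParams,
    align_confirm,
    build_kmer_index,
    count_bs_reads,
    prefilter_read,
    smith_waterman,
)
from conftest import random_dna


def bsj(seq, circ_id="c1"):
    return BSJunctionSeq(circ_id, seq, junction_offset=len(seq) // 2, flank=len(seq) // 2)


@pytest.fixture()
def bsj70(rng):
    return bsj(random_dna(rng, 70))


class TestKmerIndex:
    def test_70mer_has_50_forward_kmers_all_queryable(self, bsj70):
        params = QuantParams()
        index = build_kmer_index([bsj70], params)
        seq = bsj70.sequence
        kmers = {seq[i : i + 21] for i in range(50)}
        assert len(seq) - 21 + 1 == 50
        assert all(index.contains(k) for k in kmers)
        assert all(index.contains(revcomp(k)) for k in kmers)

    def test_absent_kmer_is_negative(self, bsj70):
        index = build_kmer_index([bsj70], QuantParams())
        probe = "A" * 21
        if probe in bsj70.sequence:  # vanishingly unlikely at this seed
            probe = "C" * 21
        assert not index.contains(probe)

    def test_membership_exact_under_total_collision(self, rng):
        """Capacity 1 funnels every k-mer into one bucket; answers are unchanged."""
        seqs = [bsj(random_dna(rng, 70), f"c{i}") for i in range(5)]
        big = build_kmer_index(seqs, QuantParams(table_capacity=1_000_003))
        tiny = build_kmer_index(seqs, QuantParams(table_capacity=1))
        truth = set()
        for s in seqs:
            for oriented in (s.sequence, revcomp(s.sequence)):
                truth.update(oriented[i : i + 21] for i in range(len(oriented) - 20))
        for _ in range(200):
            probe = random_dna(rng, 21)
            expected = probe in truth
            assert big.contains(probe) is expected
            assert tiny.contains(probe) is expected
        for probe in list(truth)[:100]:
            assert tiny.contains(probe) and big.contains(probe)

    def test_kmers_with_ambiguous_bases_are_skipped(self):
        index = KmerIndex(k=5)
        index.add_sequence("ACGTNACGTA", "x")
        assert not index.contains("CGTNA")
        assert index.contains("ACGTA")

    def test_collision_dim_overflow_and_capacity_validation(self, rng):
        with pytest.raises(ValueError):
            KmerIndex(k=21, capacity=0)
        small = KmerIndex(k=21, capacity=1, collision_dim=3)
        with pytest.raises(OverflowError):
            small.add_sequence(random_dna(rng, 70), "c1")

    def test_short_bsj_reported_not_fatal(self):
        errors = []
        index = build_kmer_index([bsj("ACGT" * 2, "tiny")], QuantParams(), errors)
        assert index.n_kmers == 0 and len(errors) == 1


class TestPrefilter:
    def test_read_equal_to_bsj_shares_50(self, bsj70):
        index = build_kmer_index([bsj70], QuantParams())
        passes, shared = prefilter_read(bsj70.sequence, index, QuantParams())
        assert passes and shared == 50

    def test_contiguous_37bp_block_gives_exactly_17(self, rng, bsj70):
        index = build_kmer_index([bsj70], QuantParams())
        block = bsj70.sequence[10:47]  # 37 bp
        while True:  # random context that adds no extra shared k-mers
            read = random_dna(rng, 20) + block + random_dna(rng, 18)
            _, shared = prefilter_read(read, index, QuantParams())
            if shared == 37 - 21 + 1:
                break
        assert shared == 17
        passes, _ = prefilter_read(read, index, QuantParams())
        assert passes  # exactly at the default threshold

    def test_unrelated_read_shares_nothing(self, rng, bsj70):
        index = build_kmer_index([bsj70], QuantParams())
        passes, shared = prefilter_read(random_dna(rng, 75), index, QuantParams())
        assert shared == 0 and not passes

    def test_read_shorter_than_k_fails_cleanly(self, bsj70):
        index = build_kmer_index([bsj70], QuantParams())
        assert prefilter_read("ACGT", index, QuantParams()) == (False, 0)

    def test_orientation_blind(self, rng, bsj70):
        index = build_kmer_index([bsj70], QuantParams())
        read = bsj70.sequence[5:65]
        _, fwd = prefilter_read(read, index, QuantParams())
        _, rev = prefilter_read(revcomp(read), index, QuantParams())
        assert fwd == rev > 0


class TestSmithWaterman:
    def test_self_alignment(self, bsj70):
        res = align_confirm(bsj70.sequence, bsj70, QuantParams())
        assert res.n_matches == 70 and res.score == 140
        assert res.ref_span == (0, 70) and res.crosses_junction

    def test_left_half_does_not_cross_junction(self, bsj70):
        res = align_confirm(bsj70.sequence[:35], bsj70, QuantParams())
        assert res.n_matches == 35 and res.ref_span == (0, 35)
        assert not res.crosses_junction

    def test_two_substitutions_give_68_matches(self, bsj70):
        seq = list(bsj70.sequence)
        for pos in (10, 40):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        res = align_confirm("".join(seq), bsj70, QuantParams())
        assert res.n_matches == 68

    def test_empty_read_is_an_error(self, bsj70):
        with pytest.raises(ValueError):
            smith_waterman("", bsj70.sequence)

    @staticmethod
    def _slow_affine_sw_score(a, b, match=2, mis=-2, open_=3, ext=1):
        """Plain-Python full-DP oracle for the optimal local alignment score."""
        NEG = -(10**9)
        n, m = len(a), len(b)
        H = [[0] * (m + 1) for _ in range(n + 1)]
        E = [[NEG] * (m + 1) for _ in range(n + 1)]
        F = [[NEG] * (m + 1) for _ in range(n + 1)]
        best = 0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                E[i][j] = max(H[i - 1][j] - open_, E[i - 1][j] - ext)
                F[i][j] = max(H[i][j - 1] - open_, F[i][j - 1] - ext)
                s = match if a[i - 1] == b[j - 1] else mis
                H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
                best = max(best, H[i][j])
        return best

    def test_score_matches_independent_dp_oracle(self, rng):
        import warnings

        from skbio import DNA
        from skbio.alignment import local_pairwise_align

        sub = {a: {b: (2 if a == b else -2) for b in "ACGT"} for a in "ACGT"}
        for _ in range(15):
            read = random_dna(rng, 60)
            ref = random_dna(rng, 70)
            # embed a shared, mutated block half the time
            if rng.random() < 0.5:
                block = ref[20:55]
                read = read[:10] + block + read[45:]
            ours = smith_waterman(read, ref)
            assert ours.score == self._slow_affine_sw_score(read, ref)
            # cross-check against scikit-bio, whose heuristic-free DP gives a
            # feasible (sometimes suboptimal) local alignment: a lower bound
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, skbio_score, _ = local_pairwise_align(
                    DNA(read), DNA(ref), gap_open_penalty=3, gap_extend_penalty=1,
                    substitution_matrix=sub,
                )
            assert ours.score >= skbio_score

    def test_gap_cost_convention(self):
        # one deleted base: 19 matches (+38) minus one opened gap (-3)
        ref = "ACGTACGTGGGGACGTACGT"
        read = "ACGTACGTGGGACGTACGT"
        res = smith_waterman(read, ref)
        assert res.score == 35 and res.n_matches == 19

    def test_n_bases_never_match(self):
        res = smith_waterman("ACGTNNNNACGT", "ACGTNNNNACGT")
        assert res.n_matches <= 8


def brute_force_counts(reads, bsj_seqs, params):
    """Full-predicate oracle: no hash table, no prefilter shortcut."""
    kmers = set()
    for b in bsj_seqs:
        for oriented in (b.sequence, revcomp(b.sequence)):
            kmers.update(
                oriented[i : i + params.k]
                for i in range(len(oriented) - params.k + 1)
                if set(oriented[i : i + params.k]) <= set("ACGT")
            )
    from circjkit.quantify import _match_stat, best_alignment

    counts = {b.circ_id: 0.0 for b in bsj_seqs}
    for _, seq in reads:
        shared = sum(
            1
            for i in range(max(len(seq) - params.k + 1, 0))
            if seq[i : i + params.k] in kmers
        )
        if shared < params.min_shared_kmers:
            continue
        results = [(b.circ_id, best_alignment(seq, b, params)) for b in bsj_seqs]
        keyed = [(cid, (r.score, _match_stat(r, params)), r) for cid, r in results]
        best = max(k for _, k, _ in keyed)
        if best <= (0, 0):
            continue
        credited = []
        for cid, k, r in keyed:
            if k != best:
                continue
            if _match_stat(r, params) < params.min_matches:
                continue
            if params.require_junction_span and not r.crosses_junction:
                continue
            credited.append(cid)
        for cid in credited:
            counts[cid] += 1.0 if params.ties == "all" else 1.0 / len(credited)
    return counts


class TestCounting:
    def _instance(self, small_fixture, n_reads=200, n_bsjs=12):
        genome, _, truth, reads, planted = small_fixture
        bsjs = reconstruct_all([c for c, _ in truth][:n_bsjs], genome)
        return reads[:n_reads], bsjs, planted

    def test_two_step_equals_brute_force_oracle(self, small_fixture):
        reads, bsjs, _ = self._instance(small_fixture)
        for params in (QuantParams(), QuantParams(table_capacity=1), QuantParams(require_junction_span=False)):
            table = count_bs_reads(reads, bsjs, params, "S1")
            oracle = brute_force_counts(reads, bsjs, params)
            for cid in oracle:
                assert float(table.counts.loc[cid, "S1"]) == pytest.approx(oracle[cid])

    def test_threshold_monotonicity(self, small_fixture):
        reads, bsjs, _ = self._instance(small_fixture, n_reads=150)
        base = count_bs_reads(reads, bsjs, QuantParams(), "S1").counts["S1"]
        for params in (QuantParams(min_shared_kmers=25), QuantParams(min_matches=45)):
            tighter = count_bs_reads(reads, bsjs, params, "S1").counts["S1"]
            assert (tighter <= base).all()

    def test_orientation_symmetry(self, small_fixture):
        reads, bsjs, _ = self._instance(small_fixture, n_reads=150)
        flipped = [(rid, revcomp(seq)) for rid, seq in reads]
        a = count_bs_reads(reads, bsjs, QuantParams(), "S1")
        b = count_bs_reads(flipped, bsjs, QuantParams(), "S1")
        assert (a.counts["S1"] == b.counts["S1"]).all()

    def test_thread_invariance(self, small_fixture):
        reads, bsjs, _ = self._instance(small_fixture, n_reads=150)
        a = count_bs_reads(reads, bsjs, QuantParams(threads=1), "S1")
        b = count_bs_reads(reads, bsjs, QuantParams(threads=8), "S1")
        assert (a.counts["S1"] == b.counts["S1"]).all()

    def test_planted_counts_recovered_exactly_at_zero_error(self, small_fixture):
        genome, _, truth, reads, planted = small_fixture
        bsjs = reconstruct_all([c for c, _ in truth], genome)
        table = count_bs_reads(reads, bsjs, QuantParams(), "S1")
        for c, _ in truth:
            assert int(table.counts.loc[c.id, "S1"]) == planted[c.id]

    def test_linear_boundary_reads_never_counted_with_junction_span(self, small_fixture):
        """Reads from the linear genome around circRNA boundaries are not BS evidence."""
        genome, _, truth, _, _ = small_fixture
        c = truth[0][0]
        chrom = genome[c.interval.chrom]
        reads = []
        for anchor in (c.interval.start, c.interval.end):
            for off in range(-40, 1, 5):
                s = anchor + off
                if 0 <= s and s + 75 <= len(chrom):
                    reads.append((f"lin{anchor}_{off}", chrom[s : s + 75]))
        bsjs = reconstruct_all([c], genome)
        table = count_bs_reads(reads, bsjs, QuantParams(), "S1")
        assert int(table.counts.loc[c.id, "S1"]) == 0

    def test_empty_fastq_gives_zero_column(self, small_fixture, tmp_path):
        genome, _, truth, _, _ = small_fixture
        bsjs = reconstruct_all([c for c, _ in truth][:3], genome)
        path = tmp_path / "empty.fq"
        path.write_text("")
        table = count_bs_reads(path, bsjs, QuantParams(), "S1")
        assert table.shape == (3, 1) and (table.counts["S1"] == 0).all()

    def test_duplicate_bsj_ids_rejected(self, bsj70):
        with pytest.raises(ValueError):
            count_bs_reads([], [bsj70, bsj70], QuantParams(), "S1")

    def test_tie_between_identical_bsjs_is_fractional(self, rng):
        seq = random_dna(rng, 70)
        twins = [bsj(seq, "c1"), bsj(seq, "c2")]
        table = count_bs_reads([("r1", seq)], twins, QuantParams(), "S1")
        assert float(table.counts.loc["c1", "S1"]) == pytest.approx(0.5)
        both = count_bs_reads([("r1", seq)], twins, QuantParams(ties="all"), "S1")
        assert int(both.counts.loc["c1", "S1"]) == 1
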