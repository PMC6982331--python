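# Methods

This note records the models and procedures implemented in `circjkit`, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
establish about real data.

## Coordinates and identifiers

All intervals are 0-based half-open internally. CIRI2 tables and GTF
(1-based inclusive) are converted at the parse boundary; BED input is passed
through. The canonical circRNA identifier is `chrom_start_end` in 1-based
inclusive display coordinates (e.g. `chr14_58718837_58724716`), so
identifiers match the coordinate-keyed naming used across circRNA databases
while arithmetic stays in one convention. The CIRI2 end coordinate is
treated as 1-based inclusive, per that tool's documented output dialect.
Records with strand `unknown` (e.g. BED without a strand column) behave as
`+` wherever a strand is required, with a logged warning.

Parsers collect malformed rows as record-level errors with line numbers
instead of aborting or silently dropping: the number of parsed records plus
reported row errors always equals the number of data rows. FASTQ reading is
deliberately tolerant for the same reason — a single corrupt record is
skipped and reported rather than voiding a whole lane — which is why the
FASTQ reader is a small in-house routine rather than a strict library
parser.

## Replicate filter (merge)

Candidates are the union of all predicted circRNAs; a sample without a
prediction for a circRNA contributes a count of 0. Retention requires, in
**at least one** condition: strictly more than `min_reads` BS-supporting
reads in at least `min_reps` replicates, and a condition mean strictly
greater than `min_avg`. Defaults are `min_reads=2`, `min_reps=2`,
`min_avg=10`. Both inequalities are strict.

Any-condition (rather than every-condition) retention is the default because
condition-specific circRNAs are a primary object of study — differential
expression between conditions presupposes circRNAs that fail the filter in
one condition. A strict-all mode (`require_all_conditions=True`) is
provided.

Cross-tool intersection matches on exact (chrom, start, end) with strand
ignored, since callers disagree systematically on strand inference; a
`tolerance` in bp (default 0) absorbs off-by-one dialect drift. The
consensus record carries the count of a designated reference tool when
given, else the maximum across tools (the field has no convention here; the
parameter makes the choice explicit).

## Five-class classification

Per transcript: let `s` and `e` be the circRNA's genomic start and end. If
`s` equals some exon start **and** `e` equals some exon end of the
transcript, the call is monoexonic/multiexonic, with the involved exons
being those fully contained in [s, e). Otherwise each site contributes a
region: a site exactly at its required boundary (5' site at an exon start,
3' site at an exon end) contributes nothing; a site inside an exon marks the
call `putative_exon`; a site inside an intron marks it `intronic`;
`putative_exon` takes precedence when the two sites disagree (an
intra-exonic site is positive evidence of exon involvement, and the class
list itself is unordered — this precedence is a declared choice). Sites
outside the transcript span contribute nothing; a circRNA with no call from
any overlapping transcript is `intergenic` (subject `"none"`).

Boundary matching is exact (tolerance 0): predictions carry single-base
precision and a slack would silently blur monoexonic/putative distinctions.
Matching considers transcripts of both strands by default, because
antisense circRNAs are a recognized class; `same_strand=True` restricts it.

Gene-level aggregation keeps, per (circRNA, gene), the best category across
that gene's transcripts under the priority monoexonic > multiexonic >
putative_exon > intronic. A circRNA whose matching exons are shared by
several genes keeps one row per gene — gene-level rows can therefore exceed
the number of circRNAs, which is expected, not double counting.

Note one boundary effect: when a monoexonic circRNA sits on a transcript's
first or last exon, shifting the outer site 1 bp outward leaves the
transcript span entirely, and with no other evidence the call resolves to
intergenic rather than putative/intronic. Interior boundaries always demote
to putative_exon or intronic. In every case a 1 bp perturbation destroys
the exonic call, which is the property that matters.

## BSJ reconstruction

For circRNA [s, e) on the plus strand with flank `f = min(35, e - s)`:
`sequence = genome[e-f : e] ++ genome[s : s+f]`, junction offset `f`. Minus
strand reverse-complements the result. Flanks are genomic windows inside the
circRNA interval — for a multiexonic circRNA whose terminal exon is shorter
than 35 bp the flank includes intronic bases; reconstructing from the
spliced sequence is out of scope. Spans below the flank truncate rather
than wrap: wrap-around would duplicate junction-adjacent bases and create
spurious k-mer matches. Bases are uppercased; non-ACGT characters become N
and never match anything downstream.

## Two-step quantification

**Parameters** (defaults in parentheses): k-mer length `k` (21), minimum
shared k-mers (17), minimum matched bases (30), hash-table capacity
(1,000,003 buckets), optional collision-list capacity (unbounded), threads
(1), junction-span requirement (on), SW scoring (+2 match, −2 mismatch, gap
open 3, extend 1; a gap of length L costs 3 + (L−1)). The k-mer and
match thresholds are tuned for 75 bp reads: a fully contained read shares
55 k-mers; 17 shared k-mers corresponds to an exact 37 bp block
(37 − 21 + 1).

**Index.** k-mers are 2-bit encoded; a k-mer containing a non-ACGT base is
skipped. Buckets are addressed by `code % capacity` and hold collision
lists of (full code, source ids), so membership is exact at any capacity —
capacity trades memory against scan time only, which the property tests pin
down by forcing capacity 1. Both orientations of every BSJ are indexed,
making the prefilter orientation-blind by construction (a read and its
reverse complement share identical counts).

**Confirmation.** The Smith–Waterman implementation is an affine-gap local
aligner with a match-counting traceback (numba-jitted DP; verified against
an independent plain-Python DP and cross-checked against scikit-bio). "30
perfect matches" is interpreted as matched bases in the best local
alignment (`match_mode="bases"`); a `"contiguous"` mode measuring the
longest exact run is provided, as both readings of "perfect matches" are
defensible. The alignment must cross the junction (reference span covering
offsets 34 and 35) by default: a 30-base match wholly inside one 35 bp
flank is equally consistent with the linear transcript and is not
back-splicing evidence. `require_junction_span=False` restores the
permissive reading.

**Assignment.** Each read is tested in both orientations against every BSJ
and *assigned* to its best-scoring BSJ (score first, then matched bases);
only then is the confirmation predicate applied. Two details here were
settled empirically during design:

* ranking by matched bases (rather than score) misassigns reads — under
  these gap costs the optimal local alignment of a read against an
  *unrelated* 70-mer routinely contains 35–48 scattered matched bases along
  a gappy, low-scoring path, so the match count does not separate the true
  junction from lookalikes, while the score does;
* assigning *after* thresholding lets a raised `min_matches` re-route a
  read to a different circRNA and so break count monotonicity in the
  thresholds; assign-then-confirm can only drop a read.

Exact ties are split fractionally (1/t to each of t tied BSJs) by default,
`ties="all"` credits each. Paired-end mates are counted as independent
reads. Quality strings are ignored. Thread counts never change results:
reads are chunked, chunks processed in a pool, partial counts merged in
fixed order.

## Synthetic fixtures

The generator emulates the shape of a bulk total-RNA 75 bp experiment at
desk scale: i.i.d.-base chromosomes (default 2 × 50 kb), non-overlapping
transcripts (16 transcripts of 3–6 exons, exons and introns 100–300 bp,
intergenic gaps 200–600 bp), and 12 planted circRNAs with class mix 30%
monoexonic, 30% multiexonic, 20% putative exon, 10% intronic, 10%
intergenic — exonic classes dominating, as observed in real classifications.
All planted spans are ≥ 80 bp so that 35 bp flanks and 75 bp junction reads
are well defined. Junction reads are drawn from the circularized sequence
with the junction uniform in the read interior (≥ 5 bp on each side);
background reads are linear windows rejection-sampled to share no 30 bp
block with any planted junction sequence, making zero-false-positive
assertions exact rather than probabilistic. Default depth is 10 junction
reads per circRNA over ~1000 background reads, substitution error 0 (1% for
the noisy-recovery measurements), qualities constant. Everything is
reproducible from the seed.

What the fixture does **not** model: realistic base composition, repeats and
homologous gene families (which would stress read assignment), coverage and
GC bias, indel sequencing errors, paired-end insert geometry, and
expression-level variation. Passing tests therefore establish algorithmic
correctness of the declared predicates, not performance on real libraries.

## Measured behaviour at 1% substitution error

With error-free reads, recovered counts equal planted counts exactly (the
acceptance script recomputes this at every run). At a 1% per-base
substitution rate the recovery of planted 75 bp junction reads at default
parameters measures ~83–88% across seeds, not higher, and the loss is
entirely at the prefilter: a read whose junction sits near a read end
overlaps its BSJ by as little as 40 bp, giving only 20 candidate k-mer
positions, and a single substitution in the interior of that window kills up
to 21 of them — below the 17-shared-k-mer threshold. Reads with central
junctions (≥ 58 bp overlap) tolerate any single error. This is an intrinsic
consequence of the k = 21 / threshold 17 operating point applied to
junction-offset-uniform reads, not an implementation artifact; the
confirmation step rejects none of the prefilter survivors at this error
rate. Lowering `min_shared_kmers` raises sensitivity at the cost of more
alignment work (the declared thresholds are kept as defaults).

## Problem sizes

Test and acceptance runs use the desk-scale defaults above (12–20 circRNAs,
hundreds of reads, ≤ 50×6 merge tables, brute-force oracles at ≤ 200 reads ×
≤ 20 junction sequences), sizes at which the exhaustive oracles are exact
and the whole suite runs in seconds.
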