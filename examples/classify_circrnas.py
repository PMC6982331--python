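"""Classify circRNAs against a transcript's exon structure.

A three-exon transcript and four circRNAs — one per placement — show the
five-class scheme: exact boundary pairs are monoexonic/multiexonic, a site
inside an exon is putative_exon, a circRNA inside an intron is intronic, and
no overlapping transcript at all means intergenic.
"""

from circjkit import CircRecord, ExonRecord, GenomicInterval, classify_all

exons = [
    ExonRecord(GenomicInterval("chr1", 100, 200, "+"), "tx1", "geneA", "GENEA", 1),
    ExonRecord(GenomicInterval("chr1", 300, 380, "+"), "tx1", "geneA", "GENEA", 2),
    ExonRecord(GenomicInterval("chr1", 450, 500, "+"), "tx1", "geneA", "GENEA", 3),
]

circs = [
    CircRecord(GenomicInterval("chr1", 300, 380)),   # = exon 2 exactly
    CircRecord(GenomicInterval("chr1", 100, 500)),   # exon 1 start .. exon 3 end
    CircRecord(GenomicInterval("chr1", 310, 380)),   # 5' site inside exon 2
    CircRecord(GenomicInterval("chr1", 210, 290)),   # wholly inside intron 1
    CircRecord(GenomicInterval("chr1", 700, 800)),   # beyond the transcript
]

for call in classify_all(circs, exons):
    ranks = ",".join(map(str, call.exons_involved)) or "-"
    print(f"{call.circ_id:18s} {call.category:14s} transcript={call.subject_id} exons={ranks}")
# Expected: monoexonic (exon 2), multiexonic (exons 1-3), putative_exon,
# intronic, intergenic.
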