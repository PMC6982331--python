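"""Join predicted circRNAs against local circRNA database dumps.

Two tiny database tables are joined by exact coordinates; the output has one
row per (circRNA, database, hit) and every circRNA appears even without a
hit, with an annotated_in summary of the databases that matched it.
"""

from circjkit import CircRecord, DbTable, GenomicInterval, annotate_circrnas

circbase = DbTable("circbase", [
    (GenomicInterval("chr1", 100, 400), {"circbase_id": "hsa_circ_0000001", "study": "demo"}),
])
tscd = DbTable("tscd", [
    (GenomicInterval("chr1", 100, 400), {"tissue": "colon"}),
    (GenomicInterval("chr2", 50, 900), {"tissue": "brain"}),
])

circs = [
    CircRecord(GenomicInterval("chr1", 100, 400)),  # in both databases
    CircRecord(GenomicInterval("chr3", 10, 80)),    # in neither
]

result = annotate_circrnas(circs, [circbase, tscd], mode="exact")
print(result.fillna("").to_string(index=False))
# chr1_101_400 yields two hit rows (circbase + tscd attributes, prefixed per
# database); chr3_11_80 yields one row with an empty annotated_in.
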