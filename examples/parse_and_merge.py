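"""Parse per-sample circRNA predictions and apply the replicate filter.

Builds three replicate CIRI2-style prediction files in memory, merges them
into one BS-supporting-read count table, and filters with the default
thresholds (count > 2 in >= 2 replicates, condition mean > 10).
"""

import tempfile
from pathlib import Path

from circjkit import MergeParams, merge_predictions, parse_predictions

HEADER = "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\tstrand\n"
ROWS = {
    # sample -> list of (chrom, start_1based, end_1based, bs_reads, strand)
    "r1": [("chr1", 101, 400, 12, "+"), ("chr1", 901, 1300, 4, "-")],
    "r2": [("chr1", 101, 400, 15, "+"), ("chr1", 901, 1300, 3, "-")],
    "r3": [("chr1", 101, 400, 9, "+")],
}

per_sample = {}
with tempfile.TemporaryDirectory() as tmp:
    for sample, rows in ROWS.items():
        path = Path(tmp) / f"{sample}.ciri2"
        body = "".join(f"{c}:{s}|{e}\t{c}\t{s}\t{e}\t{n}\t{st}\n" for c, s, e, n, st in rows)
        path.write_text(HEADER + body)
        per_sample[sample] = parse_predictions(path, "ciri2", sample)

covariates = {"r1": "tumor", "r2": "tumor", "r3": "tumor"}
table = merge_predictions(per_sample, covariates, MergeParams(min_reads=2, min_reps=2, min_avg=10))

print("count table after filtering:")
print(table.counts)
# chr1_101_400 survives: counts (12, 15, 9), two replicates above 2, mean 12 > 10.
# chr1_901_1300 is removed: mean (4 + 3 + 0) / 3 = 2.3 is far below 10.
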