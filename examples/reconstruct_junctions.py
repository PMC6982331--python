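"""Reconstruct a back-splice junction sequence from a toy genome.

The junction of a circRNA joins its genomic 3' end back to its 5' start, so
the reconstructed sequence is last-35-bases ++ first-35-bases of the circRNA
interval: 70 bp with the junction at offset 35. This sequence exists in the
circular transcript but nowhere in the linear genome.
"""

import numpy as np

from circjkit import CircRecord, GenomicInterval, reconstruct_bs_sequence

rng = np.random.default_rng(0)
genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))}

circ = CircRecord(GenomicInterval("chr1", 20, 180, "+"))
bsj = reconstruct_bs_sequence(circ, genome, flank=35)

left, right = bsj.sequence[: bsj.junction_offset], bsj.sequence[bsj.junction_offset :]
print(f"circRNA {circ.id} (span {circ.interval.span} bp)")
print(f"BSJ length {len(bsj.sequence)} bp, junction at offset {bsj.junction_offset}")
print(f"  3' flank (genome[145:180]): {left}")
print(f"  5' flank (genome[20:55]):   {right}")
print("present in linear genome:", bsj.sequence in genome["chr1"])  # False
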