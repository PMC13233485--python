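"""The binary measurement matrix and its index-table representation.

Builds a small learnable measurement matrix, binarizes it by per-row
top-k selection, streams an image through the index-matching encoder
FSM, and verifies the streamed result equals the dense product B.x while
costing m*Sample + n cycles instead of m*n.
"""

import numpy as np

from cssnn import MeasurementMatrix, build_index_table, cs_encode, stream_cs_encode

rng = np.random.default_rng(0)
mm = MeasurementMatrix.random(m=6, n=20, sample=3, seed=0)
B = mm.binary()
print(f"measurement matrix: m={mm.m}, n={mm.n}, Sample={mm.sample}, "
      f"CR={mm.cr:.2f}, sparsity={mm.sparsity:.3f}")
print("ones per row:", B.sum(axis=1), "(always exactly Sample)")

x = rng.integers(0, 256, mm.n)  # an 8-bit pixel stream
table = build_index_table(B)
print(f"index table: {len(table)} entries, last sampled pixel "
      f"{table.last_sampled_pixel} of {mm.n}")

mp, counters = stream_cs_encode(table, x)
dense = cs_encode(B, x)
print("streamed measurements:", mp)
print("dense product B.x:    ", dense, "->", "bit-exact" if (mp == dense).all() else "MISMATCH")
print(f"cycles {counters.cycles} (= m*Sample + n = {mm.m * mm.sample + mm.n}), "
      f"matrix reads {counters.matrix_reads} (vs {mm.m * mm.n} dense)")
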