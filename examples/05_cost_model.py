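"""Analytic resource models: the dense-vs-indexed encoder comparison,
model sizes, and predicted memory traffic.

At the deployment operating point (m=256, n=784, Sample=6, 14-bit table
entries) the index-matching encoder stores 21,504 bits against the
200,704-bit dense bitmap (9.33x), reads 1,536 entries (130.67x fewer),
and finishes in 2,320 cycles (86.51x fewer).
"""

from cssnn import (
    build_cost_report,
    compare_encoder_methods,
    index_bits,
    model_size,
    model_size_cs,
    predicted_rw_counts,
)

cmp = compare_encoder_methods(m=256, n=784, sample=6, bits=14)
print("dense vs index-matching encoder (m=256, n=784, Sample=6, bits=14):")
for key in ("storage", "read", "cycle"):
    print(f"  {key:8s}: dense {cmp[f'dense_{key}s' if key != 'storage' else 'dense_storage_bits']:>8,} "
          f"indexed {cmp[f'indexed_{key}s' if key != 'storage' else 'indexed_storage_bits']:>7,} "
          f"ratio {cmp[f'{key}_ratio']:7.2f}x")

print("\nindex widths by input length:",
      {n: index_bits(n) for n in (784, 2312, 32768)})
print(f"CS encoder size (784, CR=256/784, Sample=6): "
      f"{model_size_cs(784, 256 / 784, 6) * 1024:.3f} KB")
print(f"dense SNN layers 256-64-10 at 8 bits: "
      f"{model_size([(256, 64), (64, 10)], 8) * 1024:.3f} KB")

rw = predicted_rw_counts(256, 784, 6, firing_rate=0.3, layers=[(256, 64), (64, 10)])
print("\npredicted traffic at 30% firing:", {
    "matrix_reads": rw["measurement_matrix_reads"],
    "weight_reads": round(rw["total_weight_reads"]),
    "neuron_rw": round(rw["total_neuron_rw"]),
})

report = build_cost_report("784-cs256-fc64-fc10", sample=6)
print(f"\ntotal analytic OPs for 784-cs256-fc64-fc10: {report.total_ops:,} "
      f"({report.encoder_ops:,} encoder adds + {report.snn_ops:,} SNN)")
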