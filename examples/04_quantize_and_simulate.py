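"""Deploy path: fixed-point quantization and the processor simulator.

Trains a small CSSNN, quantizes it to 8-bit weights / 9-bit membrane
potentials, and runs one image through the spike-driven processor
dataflow (index-matching encoder stream + sequential neuron sweep). The
simulator's class decision is bit-exact against the dense fixed-point
reference, and its counters report the memory traffic the spike-driven
flow actually incurs.
"""

import numpy as np

from cssnn import (
    CSSNN,
    QuantSpec,
    SyntheticSpec,
    TrainConfig,
    build_index_table,
    fit,
    gen_sparse_frames,
    quantize_model,
    simulate_inference,
    train_test_split,
)
from cssnn.quantization import predict_quantized

X, y = gen_sparse_frames(SyntheticSpec(seed=3))
Xtr, ytr, Xte, yte = train_test_split(X, y, test_fraction=0.25, seed=3)
model = CSSNN.build("784-cs78-fc64-fc10", sample=20, T=10, seed=3)
fit(model, Xtr, ytr, TrainConfig(epochs=30, lr_decay=0.9, T=10, seed=3))

spec = QuantSpec(weight_bits=8, mp_bits=9)
q = quantize_model(model, spec)
print(f"quantized: threshold code {q.th_code}, MP range [{q.mp_min}, {q.mp_max}], "
      f"weight storage compression {spec.weight_ratio}x, MP {spec.mp_ratio}x")

acc_q = float(np.mean(predict_quantized(q, Xte) == yte))
print(f"fixed-point test accuracy {acc_q:.3f}")

table = build_index_table(q.encoder_B)
i = 0
pred, ctr = simulate_inference(q, Xte[i], table=table)
print(f"\nimage {i}: true class {yte[i]}, processor predicts {pred}")
print("processor counters:", ctr.as_dict())
# cycles per timestep = n pixel loads + m*Sample saves; weight reads scale
# with the measured spike activity, not with the dense layer sizes.
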