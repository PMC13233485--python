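# cssnn — compressed-sensing spiking neural networks

`cssnn` implements an end-to-end pipeline for classifying sparse signals
with a spiking neural network that *senses compressively*: instead of
feeding all n input values to the classifier, a binary {0,1} measurement
matrix Φ ∈ {0,1}^{m×n} (m ≪ n) acquires m linear measurements
x̂ = Φx, and a small leaky integrate-and-fire (LIF) network classifies
directly in the measurement domain — compressed learning, no signal
reconstruction. The matrix is not fixed: real-valued weights W ∈ [−1,1]
are co-trained with the classifier, and Φ is re-derived each forward
pass by keeping, in every row, the `Sample` largest weights
(`w_ij^b = 1 iff w_ij ∈ large(W_i, Sample)`). Each measurement therefore
samples a *fixed budget* of `Sample` pixels: a structured, hardware-
realizable sampling operator with sparsity `Sample/n`, non-negative
accumulation, and no multiplies.

The package is aimed at people studying lightweight SNNs for edge
inference: it covers the training side (surrogate-gradient
backpropagation through time), the deployment side (post-training
fixed-point quantization, 8-bit weights / 9-bit membrane potentials),
and a behavioral model of a spike-driven neuromorphic processor whose
encoder stores only the delta-encoded coordinates of the matrix's ones
(index matching) and whose synaptic work scales with measured spike
activity. The processor simulator is a bit-exact twin of the reference
fixed-point forward pass and reports exact cycle and memory-traffic
counters.

## Model in brief

* LIF dynamics per timestep: `v' = v·e^{−Δt/τ} + Σ_i W_i s_i`; spike and
  hard reset to `v_reset` when `v' ≥ v_th` (defaults `v_th=1`,
  `v_reset=0`, `τ=2`). A `1−Δt/τ` leak variant and a leak-free mode are
  selectable.
* Encoder: the compressed measurement vector is applied as a
  time-invariant input current to the first LIF layer, every timestep.
* Training: cross-entropy (or MSE) on time-averaged output firing
  rates; the spike derivative is replaced by the arctangent surrogate
  `g(x) = α/(2(1+((π/2)αx)²))` with α = 2; gradients flow through
  the binarization to the real weights by a straight-through estimator
  (strict masking available); AdamW with per-epoch learning-rate decay;
  encoder weights clipped to [−1,1] after every step.
* Cost accounting: one MAC = 2 OPs; the binary encoder contributes
  `m·Sample` additions; spike-driven SNN layers contribute
  `2·n_in·n_out·firing_rate` per timestep.

## Worked example

`examples/03_train_cssnn.py` generates a synthetic sparse-frame task
(784 inputs, 10 classes, class-specific sparse pixel support), trains a
`784-cs78-fc64-fc10` CSSNN (CR ≈ 0.1, Sample = 20) for 30 epochs, and
compares it with the compressed-learning baseline that uses a frozen
Gaussian random matrix (GRM) in front of the identical SNN:

```
CSSNN   test accuracy 1.000, total OPs/inference 102,543
GRM CL  test accuracy 0.945, total OPs/inference 1,227,637
OPs reduction: 91.6%
```

The learned binary encoder matches or beats the baseline's accuracy while the
measured operation count drops by more than 80% — the dense GRM
projection (2·m·n multiply-accumulates per timestep) dominates the
baseline's cost, whereas the sparse binary encoder performs only
m·Sample = 1,560 additions. (Exact accuracies vary a little with the
seed; the baseline is the more fragile of the two.)

`examples/04_quantize_and_simulate.py` continues to deployment:
quantization to 8-bit weights / 9-bit MPs (storage compression 4.0× and
3.55×), then one image through the processor dataflow:

```
image 0: true class 3, processor predicts 3
processor counters: {'cycles': 23440, 'matrix_reads': 15600,
 'weight_reads': 42158, 'neuron_reads': 17120, 'neuron_writes': 17120}
```

Per timestep the encoder costs `n + m·Sample` cycles (784 pixel loads +
1,560 table-entry saves → 23,440 over T = 10), and weight reads count
only the columns of neurons that actually fired.

`examples/05_cost_model.py` prints the analytic dense-vs-indexed
encoder comparison at the m=256, n=784, Sample=6, 14-bit operating
point: storage 200,704 → 21,504 bits (9.33×), reads 200,704 → 1,536
(130.67×), cycles 200,704 → 2,320 (86.51×).

A thin CLI wraps the same functions: `cssnn synth`, `cssnn train`,
`cssnn quantize`, `cssnn simulate`, `cssnn cost` (see `--help`).

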