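# Methods

## Model and assumptions

The system is a compressed-learning classifier: an m×n binary {0,1}
measurement matrix Φ acquires x̂ = Φx from a non-negative input
x ∈ [0,1]^n, and a layered LIF spiking network classifies x̂ directly.
No reconstruction is attempted or supported. The binary matrix models a
physical sampling operator — a 1 means "this pixel is read by this
measurement" — so measurements are sums of sampled pixel values:
non-negative, multiply-free, bias-free. Each row holds exactly `Sample`
ones (a fixed per-measurement sensing budget); matrix sparsity is
`Sample/n` and the compression rate is `CR = m/n`.

**LIF discretization.** Per step: `v' = v·decay + I`, spike iff
`v' ≥ v_th`, hard reset to `v_reset`, no refractory period. The default
leak is the exponential form `decay = exp(−Δt/τ)` (≈ 0.6065 at τ = 2,
Δt = 1); a linearized `1 − Δt/τ` variant is provided because several SNN
training frameworks discretize that way, and a leak-free mode
(`decay = 1`) gives the pure integrate-and-fire limit used by the
first-spike-time sanity checks. Defaults: `v_th = 1.0`, `v_reset = 0.0`,
`τ = 2.0`.

**Temporal structure.** Frame inputs are time-invariant: the encoder
projection is computed once per inference and re-applied as the input
current of the first LIF layer at every timestep. Event inputs supply a
per-timestep current instead. Within a timestep spikes propagate through
all layers with zero inter-layer latency (input → encoder layer → hidden
→ output), and membrane state persists across timesteps. Classification
is by output spike-count voting with ties broken toward the lowest class
index (deterministic and testable).

## Training

Backpropagation unrolls the T timesteps. The spike non-linearity is
replaced in the backward pass by the arctangent surrogate
`g(x) = α / (2(1 + ((π/2)αx)²))`, α = 2.0, which is exactly the
derivative of the smooth spike `σ(x) = arctan((π/2)αx)/π + ½`. The
backward pass includes the reset path (the product rule through
`v_post = v(1−s) + v_reset·s`), so running the forward with σ instead of
the Heaviside step makes the computed gradients the *exact* gradients of
that smoothed network — the property the finite-difference tests verify.
Temporal credit assignment happens inside the spiking layers only; the
encoder is a time-invariant projection with no recurrent state, so its
gradient is the spatial path summed over timesteps.

**Binarization gradient.** The top-k selection is not differentiable.
Default is a straight-through estimator: the gradient w.r.t. the binary
mask is applied to the full real weight matrix, so currently de-selected
weights can grow back into the top-k. A strict-mask mode (gradient only
on selected entries) is selectable. The mask is re-derived from the real
weights on every forward pass, and the real weights are clipped to
[−1,1] after every optimizer step (implicit regularization; also keeps
the fixed-point weight grid meaningful). Top-k ties break toward the
lowest column index via a stable sort.

**Loss and protocol.** The loss is cross-entropy on time-averaged output
firing rates (MSE-on-rates selectable); both are standard for
surrogate-gradient SNN training and the choice is not critical on the
tasks here. Optimizer: AdamW (β = 0.9/0.999, weight decay 0.01), initial
LR 1e-3, multiplicative per-epoch decay λ. Reference settings are
64 epochs, batch 18, λ = 0.1, T = 100 for frame data and T = 10 for
event data. Note λ = 0.1 per epoch extinguishes the LR within ~3 epochs;
the package's desk-scale protocol for the synthetic studies is
**30 epochs, λ = 0.9, batch 18, T = 10** (T = 10 is also the deployment
timestep count), which converges cleanly on the synthetic tasks in a few
CPU-seconds per model. Runs are deterministic given the config seed.

**Baseline.** The compressed-learning control replaces the learned
binary encoder by a frozen Gaussian random matrix with i.i.d. N(0,1)
entries scaled by 1/√n. The scaling keeps encoder membrane currents
commensurate with the unit threshold for [0,1]-normalized inputs; the
raw N(0,1) generator is exposed separately. Only the SNN layers train in
this mode.

## Quantization

Post-training, symmetric, per-tensor, round-half-away-from-zero.
`quantize_tensor` defaults to a max-abs scale (largest magnitude maps to
the extreme code; elementwise error ≤ scale/2). The *deployed* model
instead anchors a single grid to the threshold:
`s = v_th / 2^(mp_bits−2)`, so the threshold sits at integer code
`2^(mp_bits−2)` (128 for 9-bit MPs) with 2× headroom before saturation,
and weights quantize onto the same grid (the [−1,1] clip means 8-bit
codes cover the weight range at step 1/128). Sharing one grid lets the
simulator accumulate integer weight codes directly into integer MPs.
MPs saturate (clamp) at the signed `mp_bits` range rather than wrapping
— comparator semantics. The leak multiplies the integer MP by the real
decay factor and rounds half-away, identically in the dense reference
and the simulator. Storage ratios are reported floored to two decimals
(32/8 → 4.0×, 32/9 → 3.55×), a convention that never overstates
compression; the dense-vs-indexed comparison table rounds instead.

At 32/32 bits the grid step is ~1e-9 and the quantized path reproduces
the float decisions; at the 8/9-bit deployment point the synthetic-task
accuracy drop is within a few points (asserted at ≤ 5).

## Processor model

**Index matching.** The binary matrix is stored as the coordinates of
its ones sorted along the pixel axis: per entry, the gap to the
previously sampled pixel (`diff_pixel`, baseline 0) and the measurement
row (`addr_neuron`); same-pixel entries are adjacent in ascending row
order. Streaming encode: one cycle per arriving pixel, and whenever the
gap counter equals the next entry's gap, the pixel value is accumulated
into the addressed neuron (one cycle, one matrix read, one neuron
read+write per entry), repeating for every row sampling that pixel.
Total: `m·Sample + n` cycles, `m·Sample` matrix reads, result bit-exact
against B·x. The encoder's output is available once the last sampled
pixel has arrived; the cycle model still counts all n loads.

**Spike-driven SNN flow.** Each timestep: the measurements are
re-streamed into the encoder MPs; then every layer is swept in order
(encoder, hidden, output; ascending neuron address). A neuron at or
above threshold spikes, resets to zero, and pushes its outgoing weight
column into the post-layer accumulators (weight reads = post-layer size
per firing neuron); a silent neuron leaks. Output spikes accumulate into
vote counters. Because the sweep order matches the reference forward's
layer order and the arithmetic is the same saturated integer pipeline,
the simulator reproduces the reference spike rasters and class decisions
exactly — the central hardware-correctness property, asserted over
random networks and trained models. Whether hardware would re-stream
pixels or replay stored measurements each timestep is an open
implementation detail; re-application of the same measurements is
modeled. Pipeline timing finer than the 1-cycle-per-event model, SRAM
banking, and the byte-level host protocol are out of scope.

Closed-form traffic: encoder matrix reads and neuron read/writes are
both `m·Sample`; an SNN layer (n_in, n_out) reads
`n_in·n_out·firing_rate` weights and does `n_in·n_out·firing_rate +
n_out` neuron read/writes, with the firing rate taken as the
whole-inference average.

## Cost accounting

One MAC = 2 OPs. Dense FC layer: `2·n_in·n_out`. Binary encoder:
`m·Sample` additions (no multiplies). Dense model size:
`Σ (n_in·n_out + biases)·bits / (8·1024²)` MB. CS-encoder size: only
the indices of the ones are stored — `m·Sample` indices of
`round(log2 n)` bits (10/11/15 bits for n = 784/2312/32768). The
nearest-integer width follows the reported per-dataset widths; a strict
ceiling would give 12 bits for n = 2312. The dense-vs-indexed comparison
additionally takes an explicit per-entry bit width (14 at the reference
operating point), since a packed table entry holds gap + address rather
than a raw index.

**Empirical OPs** (the CSSNN-vs-GRM comparison) are measured, not
assumed: per timestep, the encoder contributes `m·Sample` adds (sparse
binary) or `2·m·n` (dense GRM) — the processor re-enters its encoder
state every timestep, so encoder work is counted per timestep for both —
and each SNN layer contributes `2·n_in·n_out·r` with r the firing rate
of its pre-layer measured on the evaluation set. Both models use
identical accounting, so the reported percentage reduction does not
depend on the MAC convention for the shared SNN term.

## Synthetic data

`gen_sparse_frames` emulates the structure that makes frame images
compressible: each class owns a fixed support of `k_active` pixels
(defaults: n = 784, 10 classes, k_active = 150 ≈ 19% active — the
active-pixel density of handwritten-digit frames — of which 80 pixels
are shared across all classes and 70 are class-exclusive), per-sample
amplitudes U(0.5, 1.0) on the support, additive N(0, 0.1²) noise,
clipped to [0,1]. 80 samples per class, split 75/25 into disjoint
train/test sets. `gen_event_frames` emulates event-camera tensors:
T × 2 × H × W binary frames, class-specific spatial support firing
Bernoulli(event_rate) per step on the ON channel, the OFF channel firing
only where ON is silent (anti-correlated polarities); flattening order
is (channel, row, col), row-major — the index table depends on this
convention. Both generators are pure functions of (spec, seed).

What this does and does not show: the synthetic tasks are linearly
separable by support, so absolute accuracies (~1.0) say nothing about
accuracy on real image sets; they exist to exercise the full pipeline —
co-optimization, quantization, dataflow equivalence, and the relative
OPs comparison, which depends on architecture and measured firing rates
rather than task difficulty. Published-scale accuracy figures require
the real datasets and the full 64-epoch protocol and are deliberately
not asserted. The IDX reader provides the optional real-data path;
pixel normalization to [0,1] (8-bit values / 255) happens in the
encoder, keeping the reader format-faithful.

## Numerical and design notes

* Per-measurement ("row") sampling budget: the binarization operates on
  rows of W, one row per measurement neuron; descriptions of the same
  constraint as column-wise in other notations refer to the identical
  per-measurement budget.
* All-zero vote vectors classify as class 0 by the tie rule; all-zero
  tensors quantize to scale 0 and decode to exact zeros.
* Fractional measurement counts (n·CR not integer) are rounded to the
  nearest integer with a warning in the size model; the desk
  architecture uses m = 78 for CR ≈ 0.1.
* The simulator refuses float models: the dataflow equivalence claim is
  defined on fixed-point arithmetic only.
* Known limitations: no convolutional layers (FC topologies only), no
  per-channel quantization, no quantization-aware training, no axonal
  delays or stochastic neurons; the GRM baseline scaling is a package
  choice, and absolute read/write totals depend on accounting details
  (counted and logged, but only the closed-form quantities are
  asserted).
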