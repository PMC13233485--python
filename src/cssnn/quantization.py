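"""Post-training fixed-point quantization of weights and membrane potentials.

Weights go from 32-bit float to ``weight_bits`` (default 8) signed
fixed-point, membrane potentials (MPs) to ``mp_bits`` (default 9) with
saturation at the representable range — the comparator/accumulator
semantics of the processor. Storage compression ratios are the bit-width
ratios: 32/8 = 4x for weights, 32/9 ≈ 3.55x for MP state.

For the deployed model the fixed-point grid is anchored to the firing
threshold rather than to per-tensor max-abs: one shared scale
``s = v_th / 2^(mp_bits-2)`` puts the threshold at code ``2^(mp_bits-2)``
with 2x headroom above it, and because weights and MPs share the grid the
event-driven simulator can accumulate integer weight codes straight into
integer MP codes — the property that makes the dense reference path and
the processor dataflow bit-exact twins. :func:`quantize_tensor` itself
defaults to the usual symmetric max-abs scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import CSSNN

__all__ = [
    "QuantSpec",
    "quantize_tensor",
    "dequantize",
    "round_half_away",
    "QuantizedCSSNN",
    "quantize_model",
    "quantized_forward",
    "predict_quantized",
    "quantized_inference",
]


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (bit-exact across platforms)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass(frozen=True)
class QuantSpec:
    """Fixed-point widths: signed ``weight_bits`` weights, ``mp_bits`` MPs,
    against a ``float_bits`` floating-point reference."""

    weight_bits: int = 8
    mp_bits: int = 9
    float_bits: int = 32

    def __post_init__(self) -> None:
        for name in ("weight_bits", "mp_bits"):
            bits = getattr(self, name)
            if not 2 <= bits <= 32:
                raise ValueError(f"{name} must be in [2, 32], got {bits}")
        if self.float_bits < max(self.weight_bits, self.mp_bits):
            raise ValueError("quantized widths cannot exceed the float reference")

    @property
    def weight_ratio(self) -> float:
        """Weight-storage compression, floored to two decimals (4.0 at 8 bits)."""
        return math.floor(self.float_bits / self.weight_bits * 100) / 100

    @property
    def mp_ratio(self) -> float:
        """MP-storage compression, floored to two decimals (3.55 at 9 bits)."""
        return math.floor(self.float_bits / self.mp_bits * 100) / 100


def quantize_tensor(
    values: np.ndarray, bits: int, scale: float | None = None
) -> tuple[np.ndarray, float]:
    """Symmetric per-tensor quantization to signed integer codes.

    Codes lie in [−2^(bits−1), 2^(bits−1)−1]. If ``scale`` is omitted it
    is chosen from the max-abs value so the largest-magnitude element maps
    to an extreme code; the elementwise dequantization error is then at
    most ``scale/2`` (before saturation). An all-zero tensor gets scale 0
    and decodes to exact zeros.
    """
    values = np.asarray(values, dtype=float)
    if bits < 2:
        raise ValueError("bits must be >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    lo, hi = -(2 ** (bits - 1)), 2 ** (bits - 1) - 1
    if scale is None:
        max_abs = float(np.max(np.abs(values))) if values.size else 0.0
        if max_abs == 0.0:
            return np.zeros(values.shape, dtype=np.int64), 0.0
        scale = max_abs / hi
    codes = np.clip(round_half_away(values / scale), lo, hi).astype(np.int64)
    return codes, float(scale)


def dequantize(codes: np.ndarray, scale: float) -> np.ndarray:
    return np.asarray(codes, dtype=float) * scale


@dataclass
class QuantizedCSSNN:
    """Integer CSSNN ready for the fixed-point simulator.

    ``weight_codes`` share the single threshold-anchored ``scale``;
    ``encoder_B`` is the frozen binary mask; MPs saturate at
    [``mp_min``, ``mp_max``] codes. ``decay`` stays a real multiplier
    whose product is rounded half-away on every leak step.
    """

    encoder_B: np.ndarray
    weight_codes: list[np.ndarray]
    scale: float
    th_code: int
    mp_min: int
    mp_max: int
    decay: float
    T: int
    spec: QuantSpec = field(default_factory=QuantSpec)
    arch: str = ""

    @property
    def layer_sizes(self) -> list[int]:
        return [self.encoder_B.shape[0]] + [w.shape[0] for w in self.weight_codes]

    def input_codes(self, X: np.ndarray) -> np.ndarray:
        """Quantize normalized pixels in [0, 1] onto the shared MP grid."""
        return round_half_away(np.asarray(X, dtype=float) / self.scale).astype(np.int64)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"qw{i}": w for i, w in enumerate(self.weight_codes)}
        arrays["enc_B"] = self.encoder_B
        np.savez(str(prefix) + ".npz", **arrays)
        meta = {
            "scale": self.scale,
            "th_code": self.th_code,
            "mp_min": self.mp_min,
            "mp_max": self.mp_max,
            "decay": self.decay,
            "T": self.T,
            "arch": self.arch,
            "weight_bits": self.spec.weight_bits,
            "mp_bits": self.spec.mp_bits,
            "float_bits": self.spec.float_bits,
            "n_weights": len(self.weight_codes),
        }
        Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "QuantizedCSSNN":
        prefix = str(prefix)
        meta = json.loads(Path(prefix + ".json").read_text())
        data = np.load(prefix + ".npz")
        return cls(
            encoder_B=data["enc_B"],
            weight_codes=[data[f"qw{i}"] for i in range(meta["n_weights"])],
            scale=meta["scale"],
            th_code=meta["th_code"],
            mp_min=meta["mp_min"],
            mp_max=meta["mp_max"],
            decay=meta["decay"],
            T=meta["T"],
            spec=QuantSpec(meta["weight_bits"], meta["mp_bits"], meta["float_bits"]),
            arch=meta["arch"],
        )


def quantize_model(model: CSSNN, spec: QuantSpec | None = None) -> QuantizedCSSNN:
    """Freeze the binary mask and quantize all synaptic weights.

    The grid step is ``v_th / 2^(mp_bits−2)``; weight codes are clipped to
    the signed ``weight_bits`` range, MPs will saturate at the signed
    ``mp_bits`` range during inference.
    """
    spec = spec or QuantSpec()
    v_th = model.lif.v_th
    scale = v_th / 2 ** (spec.mp_bits - 2)
    codes = [quantize_tensor(w, spec.weight_bits, scale=scale)[0] for w in model.weights]
    return QuantizedCSSNN(
        encoder_B=model.encoder.projection_matrix().astype(np.int64),
        weight_codes=codes,
        scale=scale,
        th_code=2 ** (spec.mp_bits - 2),
        mp_min=-(2 ** (spec.mp_bits - 1)),
        mp_max=2 ** (spec.mp_bits - 1) - 1,
        decay=model.lif.decay,
        T=model.T,
        spec=spec,
        arch=model.arch,
    )


def quantized_forward(
    q: QuantizedCSSNN, X: np.ndarray, T: int | None = None
) -> list[np.ndarray]:
    """Dense integer reference forward pass.

    Stored MPs carry the leak pre-applied (reset neurons hold 0, others
    the saturated, rounded leaked value), so one step is
    ``v = stored + current; spike if sat(v) >= th``. Returns per-layer
    spike tensors (T, batch, size). This is the oracle the event-driven
    processor simulator must match bit for bit.
    """
    T = T or q.T
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    I = q.input_codes(X) @ q.encoder_B.T  # (batch, m) integer currents
    batch = X.shape[0]
    sizes = q.layer_sizes
    spikes = [np.zeros((T, batch, n), dtype=np.int8) for n in sizes]
    stored = [np.zeros((batch, n), dtype=np.int64) for n in sizes]
    for t in range(T):
        for layer, n in enumerate(sizes):
            if layer == 0:
                c = I
            else:
                c = spikes[layer - 1][t].astype(np.int64) @ q.weight_codes[layer - 1].T
            v = np.clip(stored[layer] + c, q.mp_min, q.mp_max)
            s = v >= q.th_code
            leaked = np.clip(
                round_half_away(q.decay * v).astype(np.int64), q.mp_min, q.mp_max
            )
            stored[layer] = np.where(s, 0, leaked)
            spikes[layer][t] = s.astype(np.int8)
    return spikes


def predict_quantized(q: QuantizedCSSNN, X: np.ndarray, T: int | None = None) -> np.ndarray:
    out = quantized_forward(q, X, T)[-1]
    return np.argmax(out.sum(axis=0), axis=1)


def quantized_inference(
    model: CSSNN,
    spec: QuantSpec,
    X: np.ndarray,
    y: np.ndarray,
    T: int | None = None,
) -> dict:
    """Quantize a trained model and report accuracy and storage effects.

    Returns the fixed-point accuracy, its delta against the float path on
    the same data, and the weight/MP storage compression ratios.
    """
    y = np.asarray(y)
    q = quantize_model(model, spec)
    preds = predict_quantized(q, X, T)
    acc_q = float(np.mean(preds == y))
    acc_f = float(np.mean(model.predict(np.asarray(X, dtype=float), T=T) == y))
    n_params = sum(w.size for w in model.weights)
    return {
        "accuracy_quantized": acc_q,
        "accuracy_float": acc_f,
        "accuracy_delta": acc_q - acc_f,
        "weight_compression": spec.weight_ratio,
        "mp_compression": spec.mp_ratio,
        "weight_bits": spec.weight_bits,
        "mp_bits": spec.mp_bits,
        "snn_weight_storage_bits": n_params * spec.weight_bits,
        "model": q,
    }
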