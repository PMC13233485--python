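"""Closed-form operation counts, model sizes, and resource comparisons.

Conventions: one multiply-accumulate (MAC) counts as two operations, so a
dense fully connected layer (n_in, n_out) costs 2·n_in·n_out OPs. The
binary CS encoder performs no multiplies — one addition per stored one,
m·Sample in total. Model sizes convert parameter bits to MB by
bits / (8·1024²). The index-matching representation stores one index per
one instead of an m×n bitmap; its per-index width follows the reported
convention of the nearest integer of log2(L_in) (784 → 10, 2312 → 11,
32768 → 15 bits).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ops_fc",
    "ops_cs",
    "index_bits",
    "model_size",
    "model_size_cs",
    "compare_encoder_methods",
    "empirical_ops",
    "ops_reduction_vs_grm",
    "CostReport",
    "build_cost_report",
]

_MB = 8 * 1024 * 1024  # bits per megabyte


def ops_fc(layers: list[tuple[int, int]]) -> int:
    """Total OPs of dense FC layers: Σ 2·n_in·n_out (MAC = 2 ops)."""
    total = 0
    for n_in, n_out in layers:
        if n_in <= 0 or n_out <= 0:
            raise ValueError("layer sizes must be positive")
        total += 2 * n_in * n_out
    return total


def ops_cs(m: int, sample: int) -> int:
    """Sparse binary encoder OPs: one add per stored one, m·Sample total."""
    return m * sample


def index_bits(L_in: int) -> int:
    """Per-index bit width for the compressed matrix representation."""
    if L_in < 2:
        raise ValueError("input length must be >= 2")
    return int(round(math.log2(L_in)))


def model_size(layers: list[tuple[int, int]], bits: int, biases: bool = True) -> float:
    """Dense model size in MB: Σ (n_in·n_out + b)·bits / (8·1024²).

    Each FC layer carries ``n_out`` bias parameters unless ``biases`` is
    disabled.
    """
    if bits <= 0:
        raise ValueError("bits must be positive")
    total_bits = 0
    for n_in, n_out in layers:
        b = n_out if biases else 0
        total_bits += (n_in * n_out + b) * bits
    return total_bits / _MB


def model_size_cs(
    L_in: int, CR: float, sample: int, bits: int | None = None
) -> float:
    """CS-encoder size in MB: (L_in·CR·Sample) stored indices × index width.

    Only the coordinates of the ones are stored (the matrix is binary and
    bias-free). A non-integer measurement count L_in·CR is rounded to the
    nearest integer with a warning.
    """
    if not 0 < CR < 1:
        raise ValueError("CR must be in (0, 1)")
    m = L_in * CR
    if abs(m - round(m)) > 1e-9:
        warnings.warn(
            f"L_in*CR = {m} is not an integer measurement count; rounding to {round(m)}",
            stacklevel=2,
        )
    m = round(m)
    bits = bits if bits is not None else index_bits(L_in)
    return m * sample * bits / _MB


def compare_encoder_methods(m: int, n: int, sample: int, bits: int) -> dict:
    """Dense binary-FC multiplication versus index-matching resource model.

    Dense: an m×n 1-bit bitmap, one read and one cycle per element.
    Indexed: m·Sample entries of ``bits`` bits, one read per entry, and
    m·Sample + n cycles (one per streamed pixel plus one per entry).
    Ratios are dense/indexed, rounded to two decimals.
    """
    if min(m, n, sample, bits) <= 0:
        raise ValueError("all parameters must be positive")
    dense_storage = m * n * 1
    idx_storage = m * sample * bits
    dense_reads = m * n
    idx_reads = m * sample
    dense_cycles = m * n
    idx_cycles = m * sample + n
    return {
        "dense_storage_bits": dense_storage,
        "indexed_storage_bits": idx_storage,
        "storage_ratio": round(dense_storage / idx_storage, 2),
        "dense_reads": dense_reads,
        "indexed_reads": idx_reads,
        "read_ratio": round(dense_reads / idx_reads, 2),
        "dense_cycles": dense_cycles,
        "indexed_cycles": idx_cycles,
        "cycle_ratio": round(dense_cycles / idx_cycles, 2),
    }


def empirical_ops(model, X: np.ndarray, T: int | None = None) -> dict:
    """Measured per-inference OPs of a model on a dataset.

    The encoder contributes every timestep (the processor re-accumulates
    the measurements each step): m·Sample adds for the sparse binary
    encoder, 2·m·n for the dense GRM baseline. Each SNN layer contributes
    2·n_in·n_out per timestep weighted by the measured firing rate of its
    pre-layer — the spike-driven cost in the MAC=2 convention.
    """
    from .encoder import MeasurementMatrix

    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("empty dataset")
    T = T or model.T
    rates = model.firing_rates(X, T=T)
    enc = model.encoder
    if isinstance(enc, MeasurementMatrix):
        encoder_per_step = ops_cs(enc.m, enc.sample)
    else:
        encoder_per_step = 2 * enc.m * enc.n
    sizes = model.layer_sizes
    snn_per_step = sum(
        2 * sizes[i] * sizes[i + 1] * rates[i] for i in range(len(sizes) - 1)
    )
    total = T * (encoder_per_step + snn_per_step)
    return {
        "encoder_ops": T * encoder_per_step,
        "snn_ops": T * snn_per_step,
        "total_ops": total,
        "firing_rates": rates,
        "T": T,
    }


def ops_reduction_vs_grm(model_sparse, model_grm, X: np.ndarray, T: int | None = None) -> float:
    """Percentage OPs reduction of the sparse-binary CSSNN over the GRM
    compressed-learning baseline, measured on the same data."""
    if model_sparse.layer_sizes != model_grm.layer_sizes:
        raise ValueError("models must share the SNN topology")
    ops_s = empirical_ops(model_sparse, X, T)["total_ops"]
    ops_g = empirical_ops(model_grm, X, T)["total_ops"]
    return 100.0 * (1.0 - ops_s / ops_g)


@dataclass
class CostReport:
    """Flat summary of analytic costs for one architecture."""

    arch: str
    m: int
    n: int
    sample: int
    encoder_ops: int
    snn_ops: int
    total_ops: int
    model_size_mb: float
    model_size_cs_mb: float
    comparison: dict
    rw: dict

    def as_dict(self) -> dict:
        flat = {
            "arch": self.arch,
            "m": self.m,
            "n": self.n,
            "sample": self.sample,
            "encoder_ops": self.encoder_ops,
            "snn_ops": self.snn_ops,
            "total_ops": self.total_ops,
            "model_size_mb": self.model_size_mb,
            "model_size_cs_mb": self.model_size_cs_mb,
        }
        flat.update({f"cmp_{k}": v for k, v in self.comparison.items()})
        flat.update(
            {
                f"rw_{k}": v
                for k, v in self.rw.items()
                if not isinstance(v, list)
            }
        )
        return flat


def build_cost_report(
    arch: str,
    sample: int,
    bits_entry: int = 14,
    weight_bits: int = 8,
    firing_rate: float = 0.3,
) -> CostReport:
    """Assemble the full analytic cost picture for an architecture string."""
    from .index_matching import predicted_rw_counts
    from .model import parse_arch

    n, m, fcs = parse_arch(arch)
    sizes = [m] + fcs
    fc_pairs = list(zip(sizes[:-1], sizes[1:]))
    enc_ops = ops_cs(m, sample)
    snn_ops = ops_fc(fc_pairs)
    return CostReport(
        arch=arch,
        m=m,
        n=n,
        sample=sample,
        encoder_ops=enc_ops,
        snn_ops=snn_ops,
        total_ops=enc_ops + snn_ops,
        model_size_mb=model_size(fc_pairs, weight_bits),
        model_size_cs_mb=model_size_cs(n, m / n, sample),
        comparison=compare_encoder_methods(m, n, sample, bits_entry),
        rw=predicted_rw_counts(m, n, sample, firing_rate, fc_pairs),
    )
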