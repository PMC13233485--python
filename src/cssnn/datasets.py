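"""Synthetic datasets and standard-format readers.

Two generators emulate the two input regimes the classifier is designed
for, so the full pipeline runs without downloads:

* :func:`gen_sparse_frames` — dense frames with class-dependent sparse
  support, the structure frame-image digits present to a compressive
  sampler: each class lights up a fixed random subset of pixels (partially
  shared across classes), with per-sample amplitude jitter and additive
  Gaussian noise, normalized to [0, 1].
* :func:`gen_event_frames` — event-camera-style binary frames, T
  timesteps × 2 polarity channels × H × W, where a class-specific spatial
  pattern fires Bernoulli(event_rate) per step on the ON channel and the
  OFF channel fires anti-correlated on the same support.

Both are pure functions of (spec, seed). The IDX reader handles the
big-endian container frame-image digit sets are distributed in, for the
optional real-data path; pixel normalization is left to the encoder so
the reader stays format-faithful.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticSpec",
    "class_supports",
    "gen_sparse_frames",
    "gen_event_frames",
    "read_idx",
    "train_test_split",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults describe the standard study conditions: 784 inputs, 10
    classes, ~19% active pixels per class (the active-pixel density of
    handwritten-digit frames), moderate pixel noise. ``overlap`` pixels of
    each class's support come from a pool shared by all classes; the rest
    are class-exclusive, which is what makes classes separable.
    """

    n_features: int = 784
    n_classes: int = 10
    samples_per_class: int = 80
    k_active: int = 150
    amplitude: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 0.1
    overlap: int = 80
    T: int = 10
    event_rate: float = 0.3
    height: int = 0  # event mode only; 2*height*width must equal n_features
    width: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_active > self.n_features:
            raise ValueError("k_active cannot exceed n_features")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.event_rate <= 1:
            raise ValueError("event_rate must be in [0, 1]")
        if not 0 <= self.overlap <= self.k_active:
            raise ValueError("overlap must be in [0, k_active]")
        exclusive = self.overlap + self.n_classes * (self.k_active - self.overlap)
        if exclusive > self.n_features:
            raise ValueError(
                f"infeasible config: {self.n_classes} classes x {self.k_active} active "
                f"pixels with overlap {self.overlap} need {exclusive} > "
                f"{self.n_features} features"
            )


def class_supports(spec: SyntheticSpec, grid: int | None = None) -> np.ndarray:
    """Active-pixel index sets per class, (n_classes, k_active).

    ``grid`` overrides the index space size (used by the event generator,
    which draws supports on the H×W grid rather than the flat input).
    """
    space = grid if grid is not None else spec.n_features
    rng = np.random.default_rng(spec.seed)
    pool = rng.permutation(space)
    shared = pool[: spec.overlap]
    k_excl = spec.k_active - spec.overlap
    supports = np.empty((spec.n_classes, spec.k_active), dtype=np.int64)
    for c in range(spec.n_classes):
        excl = pool[spec.overlap + c * k_excl : spec.overlap + (c + 1) * k_excl]
        supports[c] = np.concatenate([shared, excl])
    return supports


def gen_sparse_frames(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Dense frames with class-dependent sparse support.

    Returns ``(X, y)`` with X in [0, 1], shape (N, n_features), samples
    interleaved across classes so any prefix is class-balanced.
    """
    rng = np.random.default_rng(spec.seed + 1)
    supports = class_supports(spec)
    N = spec.n_classes * spec.samples_per_class
    X = np.zeros((N, spec.n_features))
    y = np.tile(np.arange(spec.n_classes), spec.samples_per_class)
    a_lo, a_hi = spec.amplitude
    for i in range(N):
        amps = rng.uniform(a_lo, a_hi, size=spec.k_active)
        X[i, supports[y[i]]] = amps
    if spec.noise_sd > 0:
        X += rng.normal(0.0, spec.noise_sd, size=X.shape)
    return np.clip(X, 0.0, 1.0), y


def gen_event_frames(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Event-style binary frames, (N, T, n_features) with n = 2·H·W.

    Flattening order is (channel, row, col), row-major, 0-based: index
    = channel·H·W + row·W + col. On its spatial support a class's ON
    channel fires Bernoulli(event_rate) each timestep; the OFF channel
    fires only where ON stayed silent (anti-correlated polarities).
    """
    H, W = spec.height, spec.width
    if H <= 0 or W <= 0 or 2 * H * W != spec.n_features:
        raise ValueError(
            f"event mode needs 2*height*width == n_features "
            f"(got 2*{H}*{W} vs {spec.n_features})"
        )
    rng = np.random.default_rng(spec.seed + 2)
    supports = class_supports(spec, grid=H * W)
    N = spec.n_classes * spec.samples_per_class
    y = np.tile(np.arange(spec.n_classes), spec.samples_per_class)
    X = np.zeros((N, spec.T, spec.n_features), dtype=np.int8)
    hw = H * W
    for i in range(N):
        sup = supports[y[i]]
        on = rng.random((spec.T, spec.k_active)) < spec.event_rate
        off = (~on) & (rng.random((spec.T, spec.k_active)) < spec.event_rate)
        X[i][:, sup] = on  # ON channel occupies indices [0, H*W)
        X[i][:, hw + sup] = off  # OFF channel at [H*W, 2*H*W)
    return X, y


def train_test_split(
    X: np.ndarray, y: np.ndarray, test_fraction: float = 0.25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint shuffled split: (X_train, y_train, X_test, y_test)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_test = int(len(X) * test_fraction)
    test, train = order[:n_test], order[n_test:]
    return X[train], y[train], X[test], y[test]


_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: ">i2",
    0x0C: ">i4",
    0x0D: ">f4",
    0x0E: ">f8",
}


def read_idx(path: str | Path) -> np.ndarray:
    """Read a big-endian IDX container (the MNIST distribution format).

    Pixel values are returned unscaled (8-bit images stay 0..255);
    image tensors keep their (N, rows, cols) shape — flatten row-major
    for the 784-long input vectors.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise ValueError(f"{path}: truncated IDX file (no magic)")
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0 or dtype_code not in _IDX_DTYPES:
        raise ValueError(f"{path}: bad IDX magic {raw[:4]!r}")
    header_len = 4 + 4 * ndim
    if len(raw) < header_len:
        raise ValueError(f"{path}: truncated IDX header")
    dims = struct.unpack(f">{ndim}I", raw[4:header_len])
    dtype = np.dtype(_IDX_DTYPES[dtype_code])
    expected = int(np.prod(dims)) * dtype.itemsize
    body = raw[header_len:]
    if len(body) != expected:
        raise ValueError(
            f"{path}: header promises {dims} ({expected} bytes) but body has "
            f"{len(body)} bytes"
        )
    return np.frombuffer(body, dtype=dtype).reshape(dims)
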