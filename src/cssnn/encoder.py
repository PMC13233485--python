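"""Learnable compressed-sensing encoder with a binary measurement matrix.

Compression is modeled as x̂ = Φx with Φ a binary {0,1} matrix of shape
(m, n), m ≪ n. Each of the m rows is one measurement and carries a fixed
sensing budget: exactly ``Sample`` ones, placed at that row's ``Sample``
largest real-valued weights. The real weights W ∈ [−1, 1] are what gets
trained; the binary mask is re-derived from W on every forward pass.

A 1 means "this pixel is physically sampled by this measurement", so the
encoder accumulates non-negative pixel values only — no sign handling,
no multiplies, no bias. The classical compressed-learning baseline uses a
fixed dense Gaussian random matrix (GRM) instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "binarize_rows",
    "cs_encode",
    "clip_weights",
    "gaussian_baseline",
    "MeasurementMatrix",
    "FixedGaussianEncoder",
]


def binarize_rows(W: np.ndarray, sample: int) -> np.ndarray:
    """Per-row top-k binarization.

    Each row of the result has exactly ``sample`` ones, at the columns
    holding that row's ``sample`` largest weights. Ties are broken toward
    the lowest column index (stable sort), so the mask is deterministic
    across platforms. ``W`` is not modified.
    """
    W = np.asarray(W)
    if W.ndim != 2:
        raise ValueError("W must be 2-D")
    m, n = W.shape
    if not 0 < sample <= n:
        raise ValueError(f"Sample must be in (0, {n}], got {sample}")
    # stable argsort of -W puts equal weights in ascending column order
    order = np.argsort(-W, axis=1, kind="stable")[:, :sample]
    B = np.zeros((m, n), dtype=np.int8)
    np.put_along_axis(B, order, 1, axis=1)
    return B


def cs_encode(B: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Compress a non-negative signal: x̂ = B·x (length m).

    With B binary this is a per-row sum of the sampled entries, so the
    result is non-negative whenever the input is.
    """
    B = np.asarray(B)
    x = np.asarray(x)
    if x.ndim != 1 or x.shape[0] != B.shape[1]:
        raise ValueError(f"signal length {x.shape} != matrix width {B.shape[1]}")
    if np.any(x < 0):
        raise ValueError("input signal must be non-negative (pixel data)")
    return B @ x


def clip_weights(W: np.ndarray) -> np.ndarray:
    """Elementwise clip to [−1, 1] (idempotent)."""
    return np.clip(W, -1.0, 1.0)


def gaussian_baseline(m: int, n: int, seed: int) -> np.ndarray:
    """Fixed i.i.d. standard-normal measurement matrix, reproducible from seed."""
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    return np.random.default_rng(seed).standard_normal((m, n))


@dataclass
class MeasurementMatrix:
    """Trainable binary measurement matrix.

    Holds the real weights ``W`` (clipped to [−1, 1] by the optimizer) and
    derives the binary mask on demand, so the mask always reflects the
    current weights.
    """

    W: np.ndarray
    sample: int

    trainable = True

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D")
        m, n = self.W.shape
        if not 0 < self.sample <= n:
            raise ValueError(f"Sample must be in (0, {n}], got {self.sample}")
        if not 0 < m < n:
            raise ValueError(f"need 0 < m < n for compression, got m={m}, n={n}")

    @classmethod
    def random(cls, m: int, n: int, sample: int, seed: int = 0) -> "MeasurementMatrix":
        rng = np.random.default_rng(seed)
        return cls(W=rng.uniform(-0.5, 0.5, size=(m, n)), sample=sample)

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]

    @property
    def cr(self) -> float:
        """Compression rate m/n."""
        return self.m / self.n

    @property
    def sparsity(self) -> float:
        """Matrix sparsity Sample/n."""
        return self.sample / self.n

    def binary(self) -> np.ndarray:
        """Fresh binary mask derived from the current weights."""
        return binarize_rows(self.W, self.sample)

    def projection_matrix(self) -> np.ndarray:
        return self.binary().astype(float)

    def clip(self) -> None:
        self.W = clip_weights(self.W)

    def save(self, prefix: str | Path) -> None:
        """Write weights as plain text plus a JSON sidecar (m, n, Sample, CR)."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".txt"), self.W)
        meta = {"m": self.m, "n": self.n, "sample": self.sample, "cr": self.cr}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "MeasurementMatrix":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        W = np.loadtxt(prefix.with_suffix(".txt")).reshape(meta["m"], meta["n"])
        return cls(W=W, sample=meta["sample"])


@dataclass
class FixedGaussianEncoder:
    """Compressed-learning baseline encoder: a frozen dense GRM.

    Entries are i.i.d. N(0, 1) scaled by 1/sqrt(n) so that measurement
    magnitudes — and hence encoder membrane potentials — stay commensurate
    with a unit firing threshold for inputs normalized to [0, 1].
    """

    Phi: np.ndarray

    trainable = False

    @classmethod
    def random(cls, m: int, n: int, seed: int = 0) -> "FixedGaussianEncoder":
        return cls(Phi=gaussian_baseline(m, n, seed) / np.sqrt(n))

    @property
    def m(self) -> int:
        return self.Phi.shape[0]

    @property
    def n(self) -> int:
        return self.Phi.shape[1]

    @property
    def cr(self) -> float:
        return self.m / self.n

    def projection_matrix(self) -> np.ndarray:
        return self.Phi
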