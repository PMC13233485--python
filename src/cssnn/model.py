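"""The CSSNN model container: encoder + spiking classifier.

An architecture string follows the ``"784-cs256-fc64-fc10"`` convention:
input length, compressed-sensing encoder width (one LIF layer that
receives the compressed measurements as constant input current), then
fully connected LIF layers ending in one output neuron per class.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoder import FixedGaussianEncoder, MeasurementMatrix
from .lif import LIFParams, SpikeRaster, SpikingNet, classify_by_votes, network_forward

__all__ = ["parse_arch", "CSSNN", "forward_batch", "BatchForward"]

_ARCH_RE = re.compile(r"^(\d+)-cs(\d+)((?:-fc\d+)+)$")


def parse_arch(arch: str) -> tuple[int, int, list[int]]:
    """Split an architecture string into (n_input, m_measurements, fc sizes)."""
    match = _ARCH_RE.match(arch.replace(",", "").strip())
    if match is None:
        raise ValueError(
            f"cannot parse architecture {arch!r}; expected e.g. '784-cs256-fc64-fc10'"
        )
    n = int(match.group(1))
    m = int(match.group(2))
    fcs = [int(tok) for tok in match.group(3).split("-fc")[1:]]
    return n, m, fcs


@dataclass
class CSSNN:
    """Compressed-sensing spiking neural network.

    ``encoder`` is either a trainable :class:`MeasurementMatrix` (the CSSNN
    proper) or a frozen :class:`FixedGaussianEncoder` (the compressed-
    learning baseline). ``weights[i]`` connects spiking layer ``i`` to
    layer ``i+1``; layer 0 is the encoder LIF population of size m.
    """

    encoder: MeasurementMatrix | FixedGaussianEncoder
    weights: list[np.ndarray]
    lif: LIFParams = field(default_factory=LIFParams)
    T: int = 10
    arch: str = ""

    @classmethod
    def build(
        cls,
        arch: str,
        sample: int | None = None,
        encoder_kind: str = "cs",
        T: int = 10,
        lif: LIFParams | None = None,
        seed: int = 0,
    ) -> "CSSNN":
        """Construct a randomly initialized model from an architecture string.

        ``sample`` (ones per measurement row) is required for the ``"cs"``
        encoder and ignored for the ``"grm"`` baseline.
        """
        n, m, fcs = parse_arch(arch)
        rng = np.random.default_rng(seed)
        if encoder_kind == "cs":
            if sample is None:
                raise ValueError("the cs encoder needs a Sample value")
            enc: MeasurementMatrix | FixedGaussianEncoder = MeasurementMatrix(
                W=rng.uniform(-0.5, 0.5, size=(m, n)), sample=sample
            )
        elif encoder_kind == "grm":
            enc = FixedGaussianEncoder(
                Phi=rng.standard_normal((m, n)) / np.sqrt(n)
            )
        else:
            raise ValueError(f"unknown encoder kind {encoder_kind!r}")
        sizes = [m] + fcs
        weights = [
            rng.uniform(-1.0, 1.0, size=(sizes[i + 1], sizes[i]))
            / np.sqrt(sizes[i])
            for i in range(len(sizes) - 1)
        ]
        return cls(
            encoder=enc,
            weights=weights,
            lif=lif or LIFParams(),
            T=T,
            arch=arch,
        )

    @property
    def layer_sizes(self) -> list[int]:
        return [self.encoder.m] + [w.shape[0] for w in self.weights]

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[0]

    def encoder_current(self, X: np.ndarray) -> np.ndarray:
        """Project inputs to measurement currents.

        ``X`` is (batch, n) for static frames (one time-invariant current
        per sample) or (batch, T, n) for event streams (per-step currents).
        """
        M = self.encoder.projection_matrix()
        return np.asarray(X, dtype=float) @ M.T

    def to_spiking_net(self) -> SpikingNet:
        return SpikingNet(sizes=self.layer_sizes, weights=self.weights, params=self.lif)

    def forward_sample(self, x: np.ndarray, T: int | None = None) -> list[SpikeRaster]:
        """Reference single-sample forward via the layered LIF simulation."""
        T = T or self.T
        current = self.encoder_current(np.asarray(x)[None, ...])[0]
        return network_forward(self.to_spiking_net(), current, T)

    def predict_sample(self, x: np.ndarray, T: int | None = None) -> int:
        return classify_by_votes(self.forward_sample(x, T)[-1])

    def predict(self, X: np.ndarray, T: int | None = None) -> np.ndarray:
        """Batched class predictions by output spike-count voting."""
        out = forward_batch(self, X, T).spikes[-1]  # (T, batch, classes)
        return np.argmax(out.sum(axis=0), axis=1)

    def firing_rates(self, X: np.ndarray, T: int | None = None) -> list[float]:
        """Mean per-layer firing rates over a batch."""
        sim = forward_batch(self, X, T)
        return [float(s.mean()) for s in sim.spikes]

    # -- checkpoint IO (npz payload + JSON metadata) --------------------

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        if isinstance(self.encoder, MeasurementMatrix):
            arrays["enc_W"] = self.encoder.W
        else:
            arrays["enc_Phi"] = self.encoder.Phi
        np.savez(str(prefix) + ".npz", **arrays)
        meta = {
            "arch": self.arch,
            "T": self.T,
            "encoder": "cs" if isinstance(self.encoder, MeasurementMatrix) else "grm",
            "sample": getattr(self.encoder, "sample", None),
            "lif": {
                "v_th": self.lif.v_th,
                "v_reset": self.lif.v_reset,
                "tau": self.lif.tau,
                "dt": self.lif.dt,
                "leak": self.lif.leak,
            },
            "n_weights": len(self.weights),
        }
        Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "CSSNN":
        prefix = str(prefix)
        meta = json.loads(Path(prefix + ".json").read_text())
        data = np.load(prefix + ".npz")
        weights = [data[f"w{i}"] for i in range(meta["n_weights"])]
        if meta["encoder"] == "cs":
            enc: MeasurementMatrix | FixedGaussianEncoder = MeasurementMatrix(
                W=data["enc_W"], sample=meta["sample"]
            )
        else:
            enc = FixedGaussianEncoder(Phi=data["enc_Phi"])
        return cls(
            encoder=enc,
            weights=weights,
            lif=LIFParams(**meta["lif"]),
            T=meta["T"],
            arch=meta["arch"],
        )


@dataclass
class BatchForward:
    """Caches from a batched spiking forward pass.

    ``spikes[l]`` and ``v_pre[l]`` are (T, batch, size_l); ``current`` is
    the encoder input current, (batch, m) or (T, batch, m).
    """

    spikes: list[np.ndarray]
    v_pre: list[np.ndarray]
    current: np.ndarray

    @property
    def output_rates(self) -> np.ndarray:
        """Per-class mean firing rate of the output layer, (batch, classes)."""
        return self.spikes[-1].mean(axis=0)


def forward_batch(
    model: CSSNN,
    X: np.ndarray,
    T: int | None = None,
    spike_fn=None,
) -> BatchForward:
    """Vectorized spiking forward over a batch.

    ``spike_fn`` maps the MP offset from threshold to the spike output;
    ``None`` gives the hard Heaviside step. Passing a smooth surrogate
    makes the whole forward differentiable, which the gradient
    verification tests exploit.
    """
    T = T or model.T
    X = np.asarray(X, dtype=float)
    per_step = X.ndim == 3
    I = model.encoder_current(X)  # (B, m) or (B, T, m)
    if per_step:
        if X.shape[1] != T:
            raise ValueError(f"event input has {X.shape[1]} steps, expected T={T}")
        I = np.swapaxes(I, 0, 1)  # (T, B, m)
    batch = X.shape[0]
    sizes = model.layer_sizes
    decay = model.lif.decay
    v_th, v_reset = model.lif.v_th, model.lif.v_reset

    spikes = [np.zeros((T, batch, n)) for n in sizes]
    v_pre = [np.zeros((T, batch, n)) for n in sizes]
    v_post = [np.zeros((batch, n)) for n in sizes]
    for t in range(T):
        for layer in range(len(sizes)):
            if layer == 0:
                c = I[t] if per_step else I
            else:
                c = spikes[layer - 1][t] @ model.weights[layer - 1].T
            v = v_post[layer] * decay + c
            if spike_fn is None:
                s = (v >= v_th).astype(float)
            else:
                s = spike_fn(v - v_th)
            v_pre[layer][t] = v
            spikes[layer][t] = s
            v_post[layer] = v + (v_reset - v) * s
    return BatchForward(spikes=spikes, v_pre=v_pre, current=I)
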