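"""Discrete-time leaky integrate-and-fire (LIF) dynamics.

The neuron state is a membrane potential (MP) ``v`` that leaks
multiplicatively each simulation step, integrates synaptic current, and
emits a binary spike when it crosses the firing threshold, after which it
is hard-reset to ``v_reset``::

    v' = v * decay + I(t)
    s  = 1  if v' >= v_th  else 0
    v  <- v_reset if s else v'

``decay`` is ``exp(-dt/tau)`` for the exponential leak (the model form as
written), ``1 - dt/tau`` for the linearized variant common in SNN training
frameworks, or exactly 1 for the leak-free integrate-and-fire limit.

These primitives are shared by the training engine, the floating-point
inference path and the fixed-point processor simulator, which all reduce
to the same recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFParams",
    "LayerState",
    "SpikeRaster",
    "SpikingNet",
    "lif_step",
    "layer_forward",
    "network_forward",
    "classify_by_votes",
    "firing_rate",
]

_LEAK_MODES = ("exp", "linear", "none")


@dataclass(frozen=True)
class LIFParams:
    """Neuron constants shared by every neuron of a layer.

    Parameters
    ----------
    v_th:
        Firing threshold (dimensionless; MPs are expressed relative to it).
    v_reset:
        Potential assigned to a neuron immediately after it spikes.
    tau:
        Leak time constant, in units of ``dt``.
    dt:
        Simulation step length.
    leak:
        ``"exp"`` for multiplicative decay ``exp(-dt/tau)``, ``"linear"``
        for the ``1 - dt/tau`` variant, ``"none"`` for no leak (decay 1).
    """

    v_th: float = 1.0
    v_reset: float = 0.0
    tau: float = 2.0
    dt: float = 1.0
    leak: str = "exp"

    def __post_init__(self) -> None:
        if not self.v_th > self.v_reset:
            raise ValueError(f"v_th ({self.v_th}) must exceed v_reset ({self.v_reset})")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.leak not in _LEAK_MODES:
            raise ValueError(f"leak must be one of {_LEAK_MODES}, got {self.leak!r}")
        if self.leak == "linear" and not self.dt / self.tau < 1:
            raise ValueError("linear leak requires dt/tau < 1")

    @property
    def decay(self) -> float:
        """Per-step multiplicative MP decay factor."""
        if self.leak == "exp":
            return math.exp(-self.dt / self.tau)
        if self.leak == "linear":
            return 1.0 - self.dt / self.tau
        return 1.0


@dataclass
class LayerState:
    """Membrane potentials and last-step spikes of one layer."""

    v: np.ndarray
    spikes: np.ndarray

    @classmethod
    def zeros(cls, size: int) -> "LayerState":
        return cls(v=np.zeros(size), spikes=np.zeros(size, dtype=np.int8))


@dataclass
class SpikeRaster:
    """Binary spike tensor shaped (timesteps, neurons)."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s)
        if self.s.ndim != 2:
            raise ValueError("raster must be 2-D (timesteps x neurons)")

    @property
    def counts(self) -> np.ndarray:
        """Total spikes per neuron over all timesteps."""
        return self.s.sum(axis=0)


def lif_step(
    state: LayerState, input_current: np.ndarray, params: LIFParams
) -> tuple[np.ndarray, LayerState]:
    """Advance one layer by one timestep.

    Returns the binary spike vector and the new state. A neuron that
    spiked has its potential set to ``v_reset`` exactly.
    """
    input_current = np.asarray(input_current, dtype=float)
    if input_current.shape != state.v.shape:
        raise ValueError(
            f"current shape {input_current.shape} != state shape {state.v.shape}"
        )
    v = state.v * params.decay + input_current
    spikes = (v >= params.v_th).astype(np.int8)
    v_new = np.where(spikes == 1, params.v_reset, v)
    return spikes, LayerState(v=v_new, spikes=spikes)


def layer_forward(
    weights: np.ndarray,
    pre_spikes: np.ndarray,
    state: LayerState,
    params: LIFParams,
    spike_driven: bool = False,
) -> tuple[np.ndarray, LayerState]:
    """One step of a fully connected spiking layer.

    ``weights`` is (n_post, n_pre). With ``spike_driven=True`` the synaptic
    current is accumulated by iterating only over firing pre-neurons — the
    processor dataflow — which is numerically identical to the dense
    matrix-vector product because spikes are exactly 0 or 1.
    """
    weights = np.asarray(weights, dtype=float)
    pre_spikes = np.asarray(pre_spikes)
    if weights.ndim != 2 or weights.shape[1] != pre_spikes.shape[0]:
        raise ValueError(
            f"weights {weights.shape} incompatible with pre-spikes {pre_spikes.shape}"
        )
    if spike_driven:
        current = np.zeros(weights.shape[0])
        for i in np.nonzero(pre_spikes)[0]:
            current += weights[:, i]
    else:
        current = weights @ pre_spikes.astype(float)
    return lif_step(state, current, params)


def network_forward(
    net: "SpikingNet",
    encoder_current: np.ndarray,
    T: int,
) -> list[SpikeRaster]:
    """Simulate a layered spiking network for ``T`` timesteps.

    ``encoder_current`` is the synaptic current into the first LIF layer:
    either a fixed vector re-applied every timestep (static frame input,
    the projection being time-invariant) or a (T, size) sequence for
    event-style inputs. Within a timestep, spikes propagate through all
    layers with zero inter-layer latency; states persist across timesteps.

    Returns one :class:`SpikeRaster` per layer.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not net.sizes:
        raise ValueError("empty network")
    encoder_current = np.asarray(encoder_current, dtype=float)
    per_step = encoder_current.ndim == 2
    if per_step and encoder_current.shape != (T, net.sizes[0]):
        raise ValueError(
            f"per-step current shape {encoder_current.shape} != ({T}, {net.sizes[0]})"
        )
    if not per_step and encoder_current.shape != (net.sizes[0],):
        raise ValueError(
            f"current length {encoder_current.shape} != first layer size {net.sizes[0]}"
        )

    states = [LayerState.zeros(n) for n in net.sizes]
    rasters = [np.zeros((T, n), dtype=np.int8) for n in net.sizes]
    for t in range(T):
        current = encoder_current[t] if per_step else encoder_current
        spikes, states[0] = lif_step(states[0], current, net.params)
        rasters[0][t] = spikes
        for layer, w in enumerate(net.weights):
            spikes, states[layer + 1] = layer_forward(
                w, spikes, states[layer + 1], net.params
            )
            rasters[layer + 1][t] = spikes
    return [SpikeRaster(r) for r in rasters]


@dataclass
class SpikingNet:
    """An ordered stack of LIF layers joined by dense synaptic weights.

    ``sizes`` lists every LIF layer (the first one receives external
    current); ``weights[i]`` maps spikes of layer ``i`` to currents of
    layer ``i+1`` and is shaped (sizes[i+1], sizes[i]).
    """

    sizes: list[int]
    weights: list[np.ndarray] = field(default_factory=list)
    params: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self) -> None:
        if len(self.weights) != max(len(self.sizes) - 1, 0):
            raise ValueError("need exactly len(sizes)-1 weight matrices")
        for i, w in enumerate(self.weights):
            expected = (self.sizes[i + 1], self.sizes[i])
            if w.shape != expected:
                raise ValueError(f"weights[{i}] shape {w.shape}, expected {expected}")


def classify_by_votes(output_raster: SpikeRaster) -> int:
    """Class decision by total spike count, ties broken to the lowest index."""
    counts = output_raster.counts
    if counts.size == 0:
        raise ValueError("empty raster")
    return int(np.argmax(counts))


def firing_rate(raster: SpikeRaster) -> float:
    """Mean spike probability per neuron per timestep, in [0, 1]."""
    if raster.s.size == 0:
        raise ValueError("empty raster")
    return float(raster.s.mean())
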