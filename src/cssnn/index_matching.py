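"""Behavioral simulator of the index-matching processor dataflow.

The processor stores the binary measurement matrix not as an m×n bitmap
but as the sorted coordinates of its ones: entries ordered along the
pixel axis n, each holding the gap (``diff_pixel``) to the previously
sampled pixel and the measurement row (``addr_neuron``) it feeds. As
pixels stream in one per cycle, a gap counter is compared against the
next table entry; on a match the pixel value is accumulated into that
measurement neuron's membrane potential, repeatedly for every row
sampling the same pixel. One cycle per streamed pixel plus one per table
entry gives the m·Sample + n cycle model.

The SNN side follows the spike-driven flow: each timestep re-accumulates
the streamed measurements (CS_IN), then sweeps every neuron in layer
order (V_CALCU) — a firing neuron resets and pushes its outgoing weight
column into the post-layer (W_ACC); a silent one just leaks. Output
spikes are tallied by the voting stage (EXPORT). The simulator runs the
same saturated integer arithmetic as the dense fixed-point reference, so
predictions and spike rasters agree exactly; it additionally counts
cycles and memory traffic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .quantization import QuantizedCSSNN, round_half_away

__all__ = [
    "IndexTable",
    "ProcessorCounters",
    "build_index_table",
    "reconstruct",
    "stream_cs_encode",
    "simulate_inference",
    "predicted_rw_counts",
]


@dataclass
class IndexTable:
    """Relative-index representation of a binary measurement matrix.

    Entry ``i`` describes the ``i``-th one of the matrix in pixel-major
    order: ``diff_pixel[i]`` is the pixel-index gap to the previous entry
    (baseline 0 before the first), ``addr_neuron[i]`` the measurement row.
    Pixel indices are recovered as the running sum of the gaps.
    """

    diff_pixel: np.ndarray
    addr_neuron: np.ndarray
    n: int
    m: int
    sample: int
    bits_per_entry: int = 14

    def __post_init__(self) -> None:
        self.diff_pixel = np.asarray(self.diff_pixel, dtype=np.int64)
        self.addr_neuron = np.asarray(self.addr_neuron, dtype=np.int64)
        if self.diff_pixel.shape != self.addr_neuron.shape:
            raise ValueError("diff_pixel and addr_neuron must align")

    def __len__(self) -> int:
        return len(self.diff_pixel)

    @property
    def idx_matrix(self) -> np.ndarray:
        """Running entry index of the sorted, flattened matrix."""
        return np.arange(len(self), dtype=np.int64)

    @property
    def pixel_index(self) -> np.ndarray:
        """Absolute sampled-pixel index of each entry (cumulative gaps)."""
        return np.cumsum(self.diff_pixel)

    @property
    def last_sampled_pixel(self) -> int:
        """Index of the final pixel the encoder waits for; the result is
        available as soon as it has arrived."""
        return int(self.pixel_index[-1]) if len(self) else -1

    @property
    def storage_bits(self) -> int:
        return len(self) * self.bits_per_entry

    def save(self, path: str | Path) -> None:
        """CSV with an (m, n, Sample, bits) header row then per-entry rows."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["m", "n", "sample", "bits_per_entry"])
            w.writerow([self.m, self.n, self.sample, self.bits_per_entry])
            w.writerow(["diff_pixel", "addr_neuron"])
            for d, a in zip(self.diff_pixel, self.addr_neuron):
                w.writerow([int(d), int(a)])

    @classmethod
    def load(cls, path: str | Path) -> "IndexTable":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        m, n, sample, bits = (int(v) for v in rows[1])
        entries = [(int(d), int(a)) for d, a in rows[3:]]
        diffs = [e[0] for e in entries]
        addrs = [e[1] for e in entries]
        return cls(diffs, addrs, n=n, m=m, sample=sample, bits_per_entry=bits)


@dataclass
class ProcessorCounters:
    """Cycle and memory-traffic tallies of one simulated run."""

    cycles: int = 0
    matrix_reads: int = 0
    weight_reads: int = 0
    neuron_reads: int = 0
    neuron_writes: int = 0

    def as_dict(self) -> dict:
        return {
            "cycles": self.cycles,
            "matrix_reads": self.matrix_reads,
            "weight_reads": self.weight_reads,
            "neuron_reads": self.neuron_reads,
            "neuron_writes": self.neuron_writes,
        }


def build_index_table(B: np.ndarray, bits_per_entry: int = 14) -> IndexTable:
    """Sort the ones of a binary matrix along the pixel axis and delta-encode.

    Ones in the same column are emitted consecutively in ascending row
    (neuron-address) order with zero gaps between them.
    """
    B = np.asarray(B)
    if not np.isin(B, (0, 1)).all():
        raise ValueError("measurement matrix must be binary {0,1}")
    m, n = B.shape
    rows, cols = np.nonzero(B)
    order = np.lexsort((rows, cols))  # pixel-major, then neuron address
    cols, rows = cols[order], rows[order]
    diffs = np.diff(cols, prepend=0)
    per_row = B.sum(axis=1)
    sample = int(per_row[0]) if m else 0
    return IndexTable(
        diff_pixel=diffs,
        addr_neuron=rows,
        n=n,
        m=m,
        sample=sample,
        bits_per_entry=bits_per_entry,
    )


def reconstruct(table: IndexTable) -> np.ndarray:
    """Rebuild the dense binary matrix from its index table."""
    B = np.zeros((table.m, table.n), dtype=np.int8)
    if len(table):
        B[table.addr_neuron, table.pixel_index] = 1
    return B


def stream_cs_encode(
    table: IndexTable,
    pixel_stream: np.ndarray,
    mp: np.ndarray | None = None,
    counters: ProcessorCounters | None = None,
) -> tuple[np.ndarray, ProcessorCounters]:
    """Run the streaming encoder FSM over one image.

    Pixels arrive sequentially (one load cycle each); the gap counter is
    compared against the current table entry and, on equality, the pixel
    value is accumulated into the addressed measurement neuron (one save
    cycle and one matrix read per entry), repeating while further entries
    sample the same pixel. The accumulated potentials equal the dense
    product B·x exactly; total cycles are ``n + m·Sample``.

    ``mp`` lets a caller accumulate into existing neuron state (the
    per-timestep CS_IN phase); by default a zero vector is used.
    """
    pixel_stream = np.asarray(pixel_stream)
    if pixel_stream.ndim != 1 or len(pixel_stream) != table.n:
        needed = table.last_sampled_pixel
        raise ValueError(
            f"pixel stream length {pixel_stream.shape} != n={table.n} "
            f"(last sampled pixel index {needed})"
        )
    dtype = pixel_stream.dtype if np.issubdtype(pixel_stream.dtype, np.integer) else float
    mp = np.zeros(table.m, dtype=dtype) if mp is None else mp
    ctr = counters or ProcessorCounters()
    diffs = table.diff_pixel
    addrs = table.addr_neuron
    k = 0  # idx_matrix: next table entry
    gap = 0  # diff counter: pixels since the last save
    for px in pixel_stream:  # INPUT_LOAD
        ctr.cycles += 1
        while k < len(diffs) and gap == diffs[k]:  # INPUT_SAVE (repeats)
            mp[addrs[k]] += px
            ctr.cycles += 1
            ctr.matrix_reads += 1
            ctr.neuron_reads += 1
            ctr.neuron_writes += 1
            gap = 0
            k += 1
        gap += 1
    return mp, ctr


def simulate_inference(
    q: QuantizedCSSNN,
    image: np.ndarray,
    T: int | None = None,
    table: IndexTable | None = None,
    record_rasters: bool = False,
):
    """Full spike-driven inference of one image on the processor model.

    Only fixed-point models run on the processor; pass a
    :class:`~cssnn.quantization.QuantizedCSSNN`. Each timestep streams the
    pixel codes through the CS encoder FSM, sweeps all layers updating
    MPs with saturated integer arithmetic, accumulates outgoing weight
    columns for firing neurons only, and tallies output votes. Returns
    the predicted class and the traffic counters (plus the per-layer
    spike rasters, (T, size) each, when ``record_rasters`` is set).
    """
    if not isinstance(q, QuantizedCSSNN):
        raise TypeError(
            "the processor simulator is fixed-point only; quantize the model first"
        )
    T = T or q.T
    image = np.asarray(image, dtype=float).ravel()
    px_codes = q.input_codes(image)
    if table is None:
        table = build_index_table(q.encoder_B)
    sizes = q.layer_sizes
    stored = [np.zeros(n, dtype=np.int64) for n in sizes]  # NPU_INIT
    votes = np.zeros(sizes[-1], dtype=np.int64)
    rasters = [np.zeros((T, n), dtype=np.int8) for n in sizes]
    ctr = ProcessorCounters()
    for t in range(T):
        # CS_IN: re-stream the measurements into the encoder MPs
        current0, ctr = stream_cs_encode(table, px_codes, counters=ctr)
        incoming = current0  # pending accumulation for the layer being swept
        for layer, n in enumerate(sizes):
            post_acc = (
                np.zeros(sizes[layer + 1], dtype=np.int64)
                if layer + 1 < len(sizes)
                else None
            )
            spikes_here = np.zeros(n, dtype=np.int8)
            for i in range(n):  # V_CALCU: sequential neuron sweep
                ctr.neuron_reads += 1
                v = min(max(stored[layer][i] + incoming[i], q.mp_min), q.mp_max)
                if v >= q.th_code:  # fire, reset, W_ACC
                    spikes_here[i] = 1
                    stored[layer][i] = 0
                    if post_acc is not None:
                        post_acc += q.weight_codes[layer][:, i]
                        ctr.weight_reads += post_acc.size
                else:  # leak
                    leaked = int(round_half_away(q.decay * v))
                    stored[layer][i] = min(max(leaked, q.mp_min), q.mp_max)
                ctr.neuron_writes += 1
            rasters[layer][t] = spikes_here
            incoming = post_acc if post_acc is not None else None
        votes += rasters[-1][t]  # EXPORT: output-layer spikes of this timestep
    pred = int(np.argmax(votes))
    if record_rasters:
        return pred, ctr, rasters
    return pred, ctr


def predicted_rw_counts(
    m: int,
    n: int,
    sample: int,
    firing_rate: float | list[float],
    layers: list[tuple[int, int]] | None = None,
) -> dict:
    """Closed-form memory-traffic model.

    Encoder (m×n, ``sample`` ones per row): matrix reads and neuron
    read/writes are both ``m·Sample``. Each SNN layer of dimension
    (n_in, n_out): weight reads ``n_in·n_out·rate`` and neuron read/writes
    ``n_in·n_out·rate + n_out``, with ``rate`` the whole-inference average
    firing rate of the pre-layer. Rates may be given per layer.
    """
    layers = layers or []
    rates = firing_rate if isinstance(firing_rate, (list, tuple)) else [
        firing_rate
    ] * len(layers)
    if len(rates) != len(layers):
        raise ValueError("need one firing rate per layer")
    for r in rates:
        if not 0 <= r <= 1:
            raise ValueError(f"firing rate {r} outside [0, 1]")
    weight_reads = [n_in * n_out * r for (n_in, n_out), r in zip(layers, rates)]
    neuron_rw = [n_in * n_out * r + n_out for (n_in, n_out), r in zip(layers, rates)]
    return {
        "measurement_matrix_reads": m * sample,
        "encoder_neuron_rw": m * sample,
        "snn_weight_reads": weight_reads,
        "snn_neuron_rw": neuron_rw,
        "total_weight_reads": sum(weight_reads),
        "total_neuron_rw": m * sample + sum(neuron_rw),
    }
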