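"""Leaky integrate-and-fire basics: integration, leak, threshold, reset.

A single neuron driven by a constant current accumulates membrane
potential, leaks by exp(-1/tau) each step, and fires/resets on crossing
the unit threshold. The printed trace shows the characteristic
charge-fire-recharge cycle.
"""

import numpy as np

from cssnn import LIFParams, LayerState, lif_step

params = LIFParams(v_th=1.0, tau=2.0)  # decay = exp(-0.5) ~ 0.6065
state = LayerState.zeros(1)
current = np.array([0.6])

print(f"constant current {current[0]}, decay {params.decay:.4f}")
print(" t   v_before  spike  v_after")
v = 0.0
for t in range(8):
    spikes, state = lif_step(state, current, params)
    v = v * params.decay + current[0] if t else current[0]
    print(f"{t:2d}   {v:8.4f}   {spikes[0]:3d}   {state.v[0]:7.4f}")
    if spikes[0]:
        v = 0.0

# The membrane needs three steps to reach threshold from rest
# (0.6 -> 0.964 -> 1.185 >= 1), then the cycle repeats from reset.
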