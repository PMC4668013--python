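"""Firing rate and irregularity of the CN neuron across input-gain levels.

Simulates the CN neuron for 20 s under each synaptic gain condition (low,
medium, high) with an unsynchronized 200-train PN population, and in the
in vitro-like mode with all synapses silent.
"""

import numpy as np

from pausecode import CNModelConfig, simulate_trial
from pausecode.experiments import make_population

DUR = 20_000.0

res = simulate_trial(CNModelConfig(), [], 0, 10_000.0, silence_synapses=True)
t = res.cn_spike_times
t = t[t > 3000.0]
isis = np.diff(t)
print(f"in vitro mode: {1000 * t.size / 7000:.1f} Hz, "
      f"ISI CV = {isis.std() / isis.mean():.4f} (regular pacemaking)")

templates, _ = make_population(200, DUR, seed=42)
for gain in ("low", "medium", "high"):
    res = simulate_trial(CNModelConfig(gain_condition=gain), templates, 7, DUR)
    isis = np.diff(res.cn_spike_times)
    print(f"{gain:6s} gain   : {1000 * res.cn_spike_times.size / DUR:5.1f} Hz, "
          f"ISI CV = {isis.std() / isis.mean():.3f}")
print(
    "\nSynaptic input makes the intrinsically clock-like neuron fire"
    "\nirregularly near the in vivo rate; irregularity grows with the"
    "\nstrength (gain) of the synaptic conductances."
)
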