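"""Time-locking of CN neuron spikes to synchronous pause beginnings.

Runs 50 trials of the full pipeline at high input gain: a 200-train PN
population with 100% of pauses synchronized by their beginning spikes
(20 ms pause), each trial simulated together with its matched control, and
quantifies the first-spike latency and its vector strength on the pause
circle.
"""

import numpy as np

from pausecode.experiments import run_cell

cell = {
    "sync_type": "beginning",
    "fraction": 1.0,
    "pause_threshold": 20.0,
    "gain": "high",
}
res = run_cell(cell, n_trials=50, seed=11)

vs = res["vector_strength"]
lat = res["latency_sample"]
print(f"trials               : {res['n_trials']} (censored: {lat.n_censored})")
print(f"in-pause rate change : {res['rate_increase_hz'].mean():+.1f} "
      f"+- {res['rate_increase_hz'].std():.1f} Hz vs control")
print(f"reliability          : {res['reliability_pct']:.0f}% of trials increased")
print(f"first-spike latency  : {np.median(lat.latencies):.2f} ms (median)")
print(f"vector strength      : R = {vs.R:.3f} (threshold {vs.threshold_R:.3f}, "
      f"Z = {vs.Z:.1f}, p = {vs.p:.2g})")
print(
    "\nR near 1 with p << 0.01 means the CN neuron fires at almost the same"
    "\nlatency after every synchronous pause onset: the pause timing is"
    "\ntransmitted as a time code, on top of the firing-rate increase."
)
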