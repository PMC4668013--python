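# Methods

This note documents the models behind `pausecode`: their assumptions, the
parameters that matter, how the stand-in CN neuron was calibrated, the
numerical choices, and what the synthetic data do and do not capture.

## Synthetic Purkinje-neuron spike trains

PN simple-spike trains are modeled as a renewal process with two interval
classes. Each ISI is independently a **pause** with probability
`pause_fraction` (default 0.5 — half the ISIs by count) or a **regular**
interval otherwise. Regular ISIs are gamma draws of order
`regular_order = 8`; pause ISIs are a floor (`pause_floor_ms = 20`, the
minimum interval that counts as a pause) plus a gamma excess of order
`pause_order = 1.5`. The mean pause ISI is `pause_mean_ratio = 3` times the
mean regular ISI, and the regular mean is solved so the overall rate equals
`rate_hz` (default 50 Hz, giving regular ISIs of 10 ms and pauses of 30 ms
mean). Runs of regular ISIs between pauses form the "regular patterns". The
high/low gamma orders make patterns clock-like and pauses broad, which is
the qualitative structure reported for these neurons in vivo.

**Segmentation.** An ISI is classified as a pause when it is at least
`pause_floor_ms` long *and* its local CV2 — the larger of its two
adjacent-pair values CV2 = 2|a−b|/(a+b) — exceeds `cv2_threshold = 0.2`
(edge ISIs use their single available pair). Inside multi-pause epochs,
adjacent pauses of similar length can have pairwise CV2 below threshold, so
detected pauses are flood-filled through neighboring intervals that exceed
the floor; the epoch edges always border regular firing and are detected
directly. Both thresholds are configuration, not fitted values.

**Synthesis.** Every template segment is replaced by the same number of
gamma draws of its kind. The target mean of a segment is an empirical-Bayes
compromise: a segment of L ISIs gets weight `L / (L + 25)` on its own
empirical mean and the rest on the pooled mean of all same-kind segments.
Long segments are therefore matched individually, while one-interval
segments (most pauses, short patterns) borrow strength from the whole
train. The shrinkage matters: matching a single-ISI segment's "mean"
exactly would make the synthetic marginal a compound gamma with visibly
heavier tails, and a two-sample KS test at n ≈ 3000 ISIs detects that
reliably. With shrinkage, the KS pass rate at α = 0.01 is at the nominal
~99% across seeds. An `order_sampler` hook can draw per-segment gamma
orders to mimic the spread of orders seen across real patterns; by default
orders are fixed.

## Imposing pause synchrony

One synchronous event is imposed per trial at `event_time` (default 1.5 s
into a 3 s trial — at least 0.5 s after start and 1 s before the end so a
1 s rebound window fits). A fraction of trains (round-half-up of
`fraction × n`) participates; each contributes one pause longer than
`pause_threshold` (20 or 40 ms), selected uniformly among its eligible
pauses.

Alignment is implemented as **relocation in ISI space**: the pause interval
(and, in forced-rate mode, the contiguous run of intervals covering its
preceding 100 ms of spikes) is removed from the ISI sequence and
re-inserted so that the pause-start spike lands exactly on its target; the
sub-interval mismatch is absorbed by displacing a single nearby spike
within its neighboring intervals. Consequences: spike count and train
duration are conserved, ISIs immediately before and after the relocated
pause remain as random as in the source train, and — important for the
control comparison — every spike outside the span between the pause's old
and new location keeps its exact original time. A matched control (the
un-relocated population, simulated with the identical mossy-fiber
realization) therefore differs from the synchronized run only locally
around the event, which is what makes small rebound effects measurable
above the trial-to-trial count noise.

Targets per type: `beginning` puts the pause-start spike at `event_time`
(zero variance across participants); `ending` puts the pause-end spike at
`event_time + pause_threshold`; `overlapping` staggers the onset uniformly
at random subject to the pause strictly containing the common window
`[event_time, event_time + threshold]`, so no spike is aligned; `mixed`
splits participants equally among the three. Beginning-spike jitter delays
each aligned start spike by an independent Uniform[0, J] draw (one-sided,
so "after the jitter period" is well defined); pauses are selected longer
than `threshold + J` so they still exceed the threshold after the delay.
Re-applying the same specification is a no-op: trains that already satisfy
the alignment are left untouched.

**Forced pre-pause rate.** For rebound experiments the pause is chosen among
those whose preceding 100 ms contains `fPN × 0.1 s ± 1` spikes. fPN is
sampled uniformly per trial from 40–100 Hz: values much above 100 Hz are
unrealizable in a 50 Hz train whose ISIs are half pauses (a 100 ms window
with ≥ 11 spikes requires an improbably long regular run), and trains where
no compliant pause exists fall back to an unconstrained eligible pause
(logged and counted).

## The CN neuron stand-in

The neuron is deliberately simple: a soma with Hodgkin–Huxley-style fast
Na/K spiking plus a lumped passive dendrite, coupled by a fixed
conductance. It expresses the two mechanisms the coding phenomena here rest
on — release from chloride-bounded inhibition, and hyperpolarization-gated
recovery of rebound conductances — without attempting morphological or
kinetic fidelity to any detailed reconstruction.

Quantities taken from experimental reports: 200 PN synapses of maximal
conductance 11.7 nS reversing at −75 mV; frequency-dependent depression
R_ss(r) = 0.08 + 0.60 e^(−2.84r) + 0.32 e^(−0.02r) with time constant
τ(r) = 2 + 2500 e^(−0.274r) + 100 e^(−0.022r) (r in Hz, τ in ms; the
per-synapse release state relaxes toward R_ss with τ, driven by the
instantaneous rate 1000/ISI of that synapse's last interval); 100
mossy-fiber synapses firing 5 Hz Poisson; NMDA voltage dependence
f(V) = 1/(1 + s₁e^(−s₂V)); synaptic kinetics Q10 = 2, model temperature
32 °C; gain conditions (inhibitory %, excitatory %) = (10, 7), (70, 12),
(150, 24) of the maximal conductances.

Everything else is a calibration parameter of the stand-in (all
configurable on `CNModelConfig`):

| parameter | value | role |
|---|---|---|
| C_soma, C_dend | 100, 150 pF | compartment sizes |
| g_leak (each) | 10 nS, E = −65 mV | input resistance |
| g_couple | 70 nS | soma–dendrite coupling |
| g_Na, g_K | 3500, 900 nS | spike currents (E = +55/−90 mV) |
| I_tonic | 500 pA | intrinsic pacemaker drive |
| AHP | +4.5 nS per spike, τ 400 ms, E = −90 mV | firing-rate homeostasis |
| GABA kinetics | rise 0.1, decay 2.5 ms (37 °C) | fast IPSG |
| GABA spillover | peak 4% of fast, rise 1, decay 25 ms | slow IPSG floor |
| somatic inhibition | 5% of each IPSG | proximal synapses |
| AMPA / NMDA-fast / NMDA-slow max | 113.7 / 34.1 / 45.5 nS | excitation |
| NMDA s₁, s₂ | fast 0.4, 0.015; slow 0.28, 0.062 | voltage dependence |
| HCN | m∞ half −80 mV, τ 300 ms, E = −43 mV | rebound set |
| CaLVA | m² half −48 mV τ 8 ms; h half −80 mV k 10, τ 120 ms | rebound set |
| NaP | m half −50 mV instant; h half −80 mV k 10, τ 500 ms | rebound set |
| rebound presets | m1 (1.5, 20, 6), m2 (3, 30, 8), m3 (3, 15, 12) nS | HCN/CaLVA/NaP triples |

The three presets reproduce the qualitative rebound phenotypes (fast burst
with a pause before prolonged spiking; the same with a stronger prolonged
phase; burst merging into prolonged spiking). The half-inactivation of
CaLVA and NaP sits at −80 mV, below the −75 mV chloride reversal, so
inhibition alone produces only partial recovery from inactivation — the
property that makes rebound amplitude depend on how strongly the membrane
was held down beforehand.

**Calibration.** With synapses silent the neuron is a clock-like pacemaker
(ISI CV ≈ 10⁻⁴, ~8 Hz). The excitatory maxima were set so that the *high*
gain condition fires 37.5 Hz with an unsynchronized 50 Hz population; the
AHP strength and tonic drive were chosen so the other conditions land near
the same band and irregularity (ISI CV) grows with gain for rate-matched
conditions. Two honest deviations remain. First, in this architecture the
excitatory gain needed for a given rate is an affine function of the
inhibitory gain, and the three nominal gain pairs are not collinear in that
sense: at its nominal 7% the low condition fires ~41 Hz and is rate-matched
at ~5.4% instead (`TUNED_EXC_GAIN_PCT`); medium and high sit at 37.0 and
37.5 Hz at their nominal gains. Second, rebound responses are weaker than
in a detailed neuron (the 1 s post-pause rate increase is of order ±1 Hz,
not several Hz) because the stand-in's interspike voltage rides relatively
high, leaving a small CaLVA/NaP dynamic range; the *correlation* between
pre-pause PN rate and rebound size — the claim of interest — is robustly
positive, but its magnitude should not be compared to a detailed model.

The GABA spillover component and the small proximal (somatic) share of
inhibition are part of the stand-in's realism with a specific dynamical
role: immediately before an aligned pause-beginning spike, the renewal
structure of the trains produces a few milliseconds of population silence
(gamma ISI densities vanish at short intervals, so the interval *ending* at
the aligned spike is rarely short). Without a slow inhibitory floor the CN
neuron reads this dip as the start of the pause and occasionally fires
right at the nominal onset, contaminating the latency distribution with
near-zero values. The spillover floor and the fast somatic clamp of the
onset volley reduce this contamination to a few percent of trials; it is
the main residual limitation of the time-locking statistics (it caps the
100%-synchrony vector strength at roughly 0.82–0.98 depending on the seed,
around the expected ~0.91).

## Analysis conventions

* **Rate increase**: (spike count in the window of the synchronized run −
  count in the matched control) / window length; the window is the pause
  window for in-pause analyses and 1 s from onset for rebound analyses.
  Reliability is the percentage of trials with a positive increase.
* **Latencies**: first CN spike in `[onset, onset + pause)`; trials with no
  in-pause spike are censored (excluded from latency and vector-strength
  statistics but counted). Spread is the sample SD if every distribution
  being compared passes Lilliefors' normality test at α = 0.01, else the
  median absolute deviation.
* **Vector strength**: latencies map to angles 2π·latency/pause_duration
  (the full circle is the pause), R is the mean resultant length, Z = nR².
  Significance uses the finite-n corrected approximation
  p = exp(√(1 + 4n + 4(n² − n²R²)) − (1 + 2n)), which at n = 100 and
  α = 0.01 gives the threshold pair R = 0.2139, Z = 4.575; the uncorrected
  large-sample formula would give Z = 4.605 and is not used. The threshold
  is inverted in closed form.
* **Condition comparisons**: percentile bootstrap (10⁴ resamples of the mean
  difference under null-centering) or Welch's one-tailed t, both at
  α = 0.05. The bootstrap's type-I error is verified ≤ 0.07 on null data.
* **Jitter analyses** report the percentage of trials whose first in-pause
  spike falls before `onset + jitter`.

## Numerics

Fixed-step integration at dt = 0.025 ms with exponential-Euler updates for
every gating variable and compartment voltage (each step uses the other
compartment's previous voltage). Synaptic events are queued per kernel
class as rise/decay accumulator pairs, so cost per step is independent of
the synapse count; per-synapse depression scales each PN spike's weight
multiplicatively before queuing. Spikes are detected as upward crossings of
−15 mV (safely below the lowest spike peaks under load, above subthreshold
excursions) with a 1.5 ms refractory guard; the AHP increments on
detection. A non-finite membrane potential raises immediately with the
offending settings. Halving dt changes the pacemaker's 2 s spike count by
at most one. The integrator and the depression recursion are numba-compiled
(first call compiles; results are bit-reproducible for fixed inputs).

## Problem sizes

Tests and the acceptance script run at desk scale: 3 s trials, 200-train
populations, 25–120 trials per condition (100 for the headline
vector-strength number), 30–60 s trains for ISI-statistics checks, and 100
template/synthetic pairs for the KS fidelity suite. The full experiment
grids (`reproduce(...)`, 100 trials per cell at scale 1.0) reproduce the
complete condition sweeps and run in tens of minutes on one core.

## What the synthetic data do not capture

Templates are stationary renewal processes: no slow rate modulation, no
complex spikes (and hence no complex-spike-triggered pauses), no serial ISI
correlations, and pause statistics identical across the population.
Passing tests therefore demonstrate the mechanics of pause-synchrony coding
under controlled statistics, not performance on recorded data. The CN
stand-in omits morphology, spatial synapse placement (two compartments with
a fixed proximal share), GABA-B/metabotropic effects, and climbing-fiber
input altogether.
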