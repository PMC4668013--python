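"""Synaptic kinetics: double-exponential conductances, GABAergic short-term
depression, NMDA voltage dependence and Q10 temperature correction.

The PN -> CN synapse is GABAergic (reversal -75 mV) and depressing: the
release scale of each synapse relaxes toward a frequency-dependent steady
state ``R_ss(r)`` with a frequency-dependent time constant ``tau_dep(r)``,
where ``r`` is the instantaneous presynaptic frequency (1000 / last ISI).
Mossy-fiber excitation combines AMPA with a fast, weakly voltage-dependent
and a slow, strongly voltage-dependent NMDA component.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SynapseKinetics",
    "double_exp_conductance",
    "steady_state_release",
    "depression_tau",
    "update_release",
    "release_sequence",
    "nmda_factor",
    "q10_scale",
]


def q10_scale(tau_ref: float, t_ref_c: float, t_target_c: float, q10: float = 2.0) -> float:
    """Temperature-correct a time constant: ``tau * q10**((t_ref - t_target)/10)``.

    Cooling below the reference temperature slows kinetics (larger tau).
    """
    if tau_ref <= 0:
        raise ValueError("tau must be positive")
    return tau_ref * q10 ** ((t_ref_c - t_target_c) / 10.0)


@dataclass(frozen=True)
class SynapseKinetics:
    """Double-exponential synapse kinetics (all times ms, conductance nS)."""

    g_max: float
    tau_rise: float
    tau_decay: float
    e_rev: float
    q10: float = 2.0
    t_experiment_c: float = 37.0
    t_model_c: float = 32.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")

    def at_model_temperature(self) -> "SynapseKinetics":
        """Kinetics with both time constants Q10-corrected to the model's
        temperature (peak conductance is not temperature-scaled)."""
        return replace(
            self,
            tau_rise=q10_scale(self.tau_rise, self.t_experiment_c, self.t_model_c, self.q10),
            tau_decay=q10_scale(self.tau_decay, self.t_experiment_c, self.t_model_c, self.q10),
        )

    @property
    def t_peak(self) -> float:
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def norm(self) -> float:
        """Normalization N making the kernel peak equal g_max."""
        tp = self.t_peak
        return 1.0 / (np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise))


def double_exp_conductance(t_since_spike, kin: SynapseKinetics):
    """Conductance of one synaptic event, ``g_max * N * (e^{-t/tau_d} - e^{-t/tau_r})``.

    Zero at ``t = 0``, peaks at exactly ``g_max`` at ``t_peak``, decays to
    zero afterwards.  Vectorized over ``t_since_spike`` (ms).
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since spike must be non-negative")
    g = kin.g_max * kin.norm * (np.exp(-t / kin.tau_decay) - np.exp(-t / kin.tau_rise))
    return g if g.ndim else float(g)


def steady_state_release(r) -> float:
    """Steady-state release probability of the PN->CN synapse at rate ``r`` Hz.

    ``R_ss(r) = 0.08 + 0.60 exp(-2.84 r) + 0.32 exp(-0.02 r)``; monotone
    decreasing from 1 at rest to an asymptote of 0.08 at high rates.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    out = 0.08 + 0.60 * np.exp(-2.84 * r) + 0.32 * np.exp(-0.02 * r)
    return out if out.ndim else float(out)


def depression_tau(r) -> float:
    """Time constant (ms) of depression onset/recovery at rate ``r`` Hz.

    ``tau(r) = 2 + 2500 exp(-0.274 r) + 100 exp(-0.022 r)``; about 2.6 s at
    rest, floored at 2 ms for fast drive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    out = 2.0 + 2500.0 * np.exp(-0.274 * r) + 100.0 * np.exp(-0.022 * r)
    return out if out.ndim else float(out)


def update_release(release_state: float, r: float, dt: float) -> float:
    """One first-order relaxation step of the release scale.

    The state relaxes toward ``R_ss(r)`` with time constant ``tau_dep(r)``;
    the exact exponential update is used so the step size is unrestricted.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rss = steady_state_release(r)
    return rss + (release_state - rss) * np.exp(-dt / depression_tau(r))


def release_sequence(spike_times: np.ndarray, mean_rate_hz: float) -> np.ndarray:
    """Per-spike release scale of one depressing synapse.

    The first spike is released at the steady state for the train's mean
    rate; every later spike relaxes the state over the preceding ISI using
    the instantaneous frequency ``r = 1000 / ISI``.
    """
    t = np.asarray(spike_times, dtype=float)
    out = np.empty(t.size)
    if t.size == 0:
        return out
    state = steady_state_release(mean_rate_hz)
    out[0] = state
    for k in range(1, t.size):
        isi = t[k] - t[k - 1]
        state = update_release(state, 1000.0 / isi, isi)
        out[k] = state
    return out


def nmda_factor(vm, s1: float, s2: float):
    """Sigmoidal NMDA voltage dependence ``f(V) = 1 / (1 + s1 exp(-s2 V))``.

    Strictly increasing in ``Vm`` with values in (0, 1); half activation at
    ``V = ln(s1) / s2``.
    """
    vm = np.asarray(vm, dtype=float)
    out = 1.0 / (1.0 + s1 * np.exp(-s2 * vm))
    return out if out.ndim else float(out)
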