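"""Conductance-based cerebellar nucleus (CN) neuron model.

A two-compartment (soma + lumped dendrite) stand-in for a detailed CN
neuron: the soma carries Hodgkin-Huxley-style fast Na/K spiking, a leak, a
tonic pacemaker current and the three *rebound* conductances (HCN, T-type
calcium CaLVA with an inactivation gate, persistent sodium NaP with slow
inactivation); the dendrite is passive and receives 200 depressing
GABAergic PN synapses and 100 mossy-fiber synapses (AMPA + fast/slow NMDA).
The neuron fires regularly in an in vitro-like mode (synapses silent) and is
calibrated so that, with the tuned gain conditions, it fires irregularly at
the in vivo rate of 37-38 Hz.

Numbers quoted from experiments: 11.7 nS maximal PN synaptic conductance,
-75 mV chloride reversal, 200 PN and 100 mossy-fiber synapses, 5 Hz Poisson
mossy-fiber background, Q10 = 2 synaptic kinetics at a model temperature of
32 degC.  All other densities and kinetics are calibration parameters of the
stand-in and are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from .synapses import SynapseKinetics
from .trains import SpikeTrain

__all__ = [
    "GAIN_CONDITIONS",
    "REBOUND_VARIANTS",
    "CNModelConfig",
    "TrialResult",
    "make_mossy_fiber_trains",
    "simulate_trial",
    "run_control_pair",
]

#: (inhibitory gain %, excitatory gain %) of maximal synaptic conductance.
GAIN_CONDITIONS = {"low": (10.0, 7.0), "medium": (70.0, 12.0), "high": (150.0, 24.0)}

#: Excitatory gains that rate-match this model's three inhibition levels to
#: the 37-38 Hz in vivo band (found with :func:`pausecode.tune_gains`).  The
#: medium and high conditions are rate-matched at their nominal gains; the
#: low-inhibition condition needs slightly less excitation than nominal.
TUNED_EXC_GAIN_PCT = {"low": 5.4, "medium": 12.0, "high": 24.0}

#: Rebound-conductance triples (g_HCN, g_CaLVA, g_NaP) in nS defining the
#: three rebound phenotypes: m1 burst + pause + prolonged rebound, m2 burst +
#: pause + strong prolonged rebound, m3 burst merging into prolonged rebound.
REBOUND_VARIANTS = {
    "m1": (1.5, 20.0, 6.0),
    "m2": (3.0, 30.0, 8.0),
    "m3": (3.0, 15.0, 12.0),
}

# --- calibration parameters of the stand-in neuron (see docs/methods.md) ---
_C_SOMA = 100.0          # pF
_C_DEND = 150.0          # pF
_G_LEAK_SOMA = 10.0      # nS
_E_LEAK = -65.0          # mV
_G_LEAK_DEND = 10.0      # nS
_G_COUPLE = 70.0         # nS, soma-dendrite coupling
_G_NA = 3500.0           # nS
_E_NA = 55.0             # mV
_G_K = 900.0             # nS
_E_K = -90.0             # mV
_I_TONIC = 500.0         # pA, pacemaker current
_G_AHP_INC = 4.5         # nS added to the AHP conductance per spike
_TAU_AHP = 400.0         # ms, AHP decay
_FRAC_INH_SOMA = 0.05    # fraction of PN inhibition on the proximal (somatic) compartment
_GABA_SLOW_FRAC = 0.04   # peak of the slow spillover IPSG relative to the fast one
_E_HCN = -43.0           # mV
_E_CA = 120.0            # mV

# maximal excitatory conductances per mossy-fiber synapse (100% gain), nS
_G_AMPA_MAX = 113.7
_G_NMDA_FAST_MAX = 34.1
_G_NMDA_SLOW_MAX = 45.5

#: NMDA voltage-dependence fit parameters (fast: weak dependence, slow:
#: strong dependence).
NMDA_S = {"fast": (0.4, 0.015), "slow": (0.28, 0.062)}

#: Synapse kinetics at experimental temperature; Q10-corrected to 32 degC at
#: simulation time.
GABA_KIN = SynapseKinetics(11.7, 0.1, 2.5, -75.0)
#: Slow spillover component of the PN synapse (GABA pooled over many release
#: sites); peak is a small fraction of gmax but the charge is substantial.
GABA_SLOW_KIN = SynapseKinetics(11.7, 1.0, 25.0, -75.0)
AMPA_KIN = SynapseKinetics(_G_AMPA_MAX, 0.2, 1.2, 0.0)
NMDA_FAST_KIN = SynapseKinetics(_G_NMDA_FAST_MAX, 1.0, 13.0, 0.0)
NMDA_SLOW_KIN = SynapseKinetics(_G_NMDA_SLOW_MAX, 5.0, 130.0, 0.0)


@dataclass(frozen=True)
class CNModelConfig:
    """Full configuration of one CN model neuron."""

    rebound_variant: str = "m2"
    gain_condition: str = "high"
    inhibitory_gain_pct: Optional[float] = None
    excitatory_gain_pct: Optional[float] = None
    block_rebound: bool = False
    n_pn_synapses: int = 200
    n_mf_synapses: int = 100
    mf_rate_hz: float = 5.0
    temperature_c: float = 32.0
    dt: float = 0.025
    i_tonic_pa: float = _I_TONIC
    g_ampa_max_ns: float = _G_AMPA_MAX
    g_nmda_fast_max_ns: float = _G_NMDA_FAST_MAX
    g_nmda_slow_max_ns: float = _G_NMDA_SLOW_MAX
    g_ahp_inc_ns: float = _G_AHP_INC
    tau_ahp_ms: float = _TAU_AHP
    g_couple_ns: float = _G_COUPLE
    c_dend_pf: float = _C_DEND
    frac_inh_soma: float = _FRAC_INH_SOMA
    gaba_slow_frac: float = _GABA_SLOW_FRAC

    def __post_init__(self) -> None:
        if self.rebound_variant not in REBOUND_VARIANTS:
            raise ValueError(f"unknown rebound variant {self.rebound_variant!r}")
        if self.gain_condition not in GAIN_CONDITIONS:
            raise ValueError(f"unknown gain condition {self.gain_condition!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def gains(self) -> tuple[float, float]:
        gi, ge = GAIN_CONDITIONS[self.gain_condition]
        if self.inhibitory_gain_pct is not None:
            gi = self.inhibitory_gain_pct
        if self.excitatory_gain_pct is not None:
            ge = self.excitatory_gain_pct
        if gi < 0 or ge < 0:
            raise ValueError("gains must be non-negative")
        return gi, ge


@dataclass
class TrialResult:
    """Spikes and state traces of one simulated trial."""

    cn_spike_times: np.ndarray
    trace_t: np.ndarray
    voltage: np.ndarray
    gate_calva_h: np.ndarray
    gate_nap_h: np.ndarray
    mf_seed: int
    config: CNModelConfig
    matched_control: Optional["TrialResult"] = None

    @property
    def rate_hz(self) -> float:
        return 1000.0 * self.cn_spike_times.size / (
            self.trace_t[-1] if self.trace_t.size else 1.0
        )

    def spikes_in(self, start: float, end: float) -> int:
        t = self.cn_spike_times
        return int(np.searchsorted(t, end) - np.searchsorted(t, start))


def make_mossy_fiber_trains(
    n_fibers: int, rate_hz: float, duration_ms: float, seed: int
) -> list[SpikeTrain]:
    """Independent homogeneous Poisson mossy-fiber trains."""
    rng = np.random.default_rng(seed)
    out = []
    mean = 1000.0 / rate_hz
    for k in range(n_fibers):
        n_guess = int(duration_ms / mean * 1.5) + 20
        t = np.cumsum(rng.exponential(mean, n_guess))
        while t.size and t[-1] < duration_ms:
            t = np.concatenate([t, t[-1] + np.cumsum(rng.exponential(mean, n_guess))])
        t = t[t < duration_ms]
        out.append(SpikeTrain(f"mf{k}", t, duration_ms))
    return out


@njit(cache=True)
def _release_weights(times, mean_rate):  # pragma: no cover - numba
    out = np.empty(times.size)
    if times.size == 0:
        return out
    state = 0.08 + 0.60 * np.exp(-2.84 * mean_rate) + 0.32 * np.exp(-0.02 * mean_rate)
    out[0] = state
    for k in range(1, times.size):
        isi = times[k] - times[k - 1]
        r = 1000.0 / isi
        rss = 0.08 + 0.60 * np.exp(-2.84 * r) + 0.32 * np.exp(-0.02 * r)
        tau = 2.0 + 2500.0 * np.exp(-0.274 * r) + 100.0 * np.exp(-0.022 * r)
        state = rss + (state - rss) * np.exp(-isi / tau)
        out[k] = state
    return out


def _inhibitory_events(
    pn_trains: list[SpikeTrain], g_per_event: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge PN spikes into one sorted event stream with depressing weights."""
    times, weights = [], []
    for tr in pn_trains:
        if tr.n_spikes == 0:
            continue
        rel = _release_weights(tr.times, tr.rate_hz)
        times.append(tr.times)
        weights.append(rel * g_per_event)
    if not times:
        return np.empty(0), np.empty(0)
    t = np.concatenate(times)
    w = np.concatenate(weights)
    order = np.argsort(t, kind="stable")
    return t[order], w[order]


@njit(cache=True)
def _integrate(  # pragma: no cover - numba
    duration, dt,
    inh_t, inh_w,
    exc_t, w_ampa, w_nf, w_ns,
    tr_gaba, td_gaba, n_gaba,
    tr_gs, td_gs, n_gs, slow_frac,
    tr_ampa, td_ampa, n_ampa,
    tr_nf, td_nf, n_nf, s1_nf, s2_nf,
    tr_ns, td_ns, n_ns, s1_ns, s2_ns,
    g_hcn, g_calva, g_nap, i_tonic,
    g_ahp_inc, tau_ahp,
    g_couple, c_dend, frac_inh_soma,
    record_every,
):
    n_steps = int(duration / dt)
    phi = 5.0

    # synaptic state accumulators (rise/decay pair per kernel class)
    a_r_g = 0.0; a_d_g = 0.0
    a_r_gs = 0.0; a_d_gs = 0.0
    a_r_a = 0.0; a_d_a = 0.0
    a_r_f = 0.0; a_d_f = 0.0
    a_r_s = 0.0; a_d_s = 0.0
    f_r_g = np.exp(-dt / tr_gaba); f_d_g = np.exp(-dt / td_gaba)
    f_r_gs = np.exp(-dt / tr_gs); f_d_gs = np.exp(-dt / td_gs)
    f_r_a = np.exp(-dt / tr_ampa); f_d_a = np.exp(-dt / td_ampa)
    f_r_f = np.exp(-dt / tr_nf); f_d_f = np.exp(-dt / td_nf)
    f_r_s = np.exp(-dt / tr_ns); f_d_s = np.exp(-dt / td_ns)

    v_s = -60.0
    v_d = -62.0
    h = 0.6
    n = 0.3
    mh = 0.05
    mt = 0.01
    ht = 0.05
    hnap = 0.1
    g_ahp = 0.0
    f_ahp = np.exp(-dt / tau_ahp)

    i_inh = 0
    i_exc = 0
    n_rec = n_steps // record_every + 1
    rec_t = np.empty(n_rec)
    rec_v = np.empty(n_rec)
    rec_ht = np.empty(n_rec)
    rec_hnap = np.empty(n_rec)
    k_rec = 0

    spikes = np.empty(int(duration) + 64)
    n_spk = 0
    last_spk = -1e9
    v_prev = v_s

    for step in range(n_steps):
        t = step * dt
        # deliver synaptic events scheduled before this step
        while i_inh < inh_t.size and inh_t[i_inh] <= t:
            a_r_g += inh_w[i_inh]; a_d_g += inh_w[i_inh]
            ws = inh_w[i_inh] * slow_frac
            a_r_gs += ws; a_d_gs += ws
            i_inh += 1
        while i_exc < exc_t.size and exc_t[i_exc] <= t:
            a_r_a += w_ampa[i_exc]; a_d_a += w_ampa[i_exc]
            a_r_f += w_nf[i_exc]; a_d_f += w_nf[i_exc]
            a_r_s += w_ns[i_exc]; a_d_s += w_ns[i_exc]
            i_exc += 1

        g_gaba_tot = n_gaba * (a_d_g - a_r_g) + n_gs * (a_d_gs - a_r_gs)
        g_gaba = g_gaba_tot * (1.0 - frac_inh_soma)
        g_gaba_s = g_gaba_tot * frac_inh_soma
        g_ampa = n_ampa * (a_d_a - a_r_a)
        f_fast = 1.0 / (1.0 + s1_nf * np.exp(-s2_nf * v_d))
        f_slow = 1.0 / (1.0 + s1_ns * np.exp(-s2_ns * v_d))
        g_nmda = n_nf * (a_d_f - a_r_f) * f_fast + n_ns * (a_d_s - a_r_s) * f_slow

        # passive dendrite
        g_tot_d = _G_LEAK_DEND + g_couple + g_gaba + g_ampa + g_nmda
        v_inf_d = (
            _G_LEAK_DEND * _E_LEAK + g_couple * v_s + g_gaba * (-75.0)
        ) / g_tot_d
        v_d = v_inf_d + (v_d - v_inf_d) * np.exp(-dt * g_tot_d / c_dend)

        # soma gates (Hodgkin-Huxley style fast Na / delayed-rectifier K)
        x = -0.1 * (v_s + 35.0)
        am = 1.0 if np.abs(x) < 1e-9 else x / (np.exp(x) - 1.0)
        bm = 4.0 * np.exp(-(v_s + 60.0) / 18.0)
        m_inf = am / (am + bm)
        ah = 0.07 * np.exp(-(v_s + 58.0) / 20.0)
        bh = 1.0 / (np.exp(-0.1 * (v_s + 28.0)) + 1.0)
        h_inf = ah / (ah + bh)
        tau_h = 1.0 / (phi * (ah + bh))
        h = h_inf + (h - h_inf) * np.exp(-dt / tau_h)
        x = -0.1 * (v_s + 34.0)
        an = 0.1 if np.abs(x) < 1e-9 else 0.1 * x / (np.exp(x) - 1.0)
        bn = 0.125 * np.exp(-(v_s + 44.0) / 80.0)
        n_inf = an / (an + bn)
        tau_n = 1.0 / (phi * (an + bn))
        n = n_inf + (n - n_inf) * np.exp(-dt / tau_n)

        # rebound gates
        mh_inf = 1.0 / (1.0 + np.exp((v_s + 80.0) / 7.0))
        mh = mh_inf + (mh - mh_inf) * np.exp(-dt / 300.0)
        mt_inf = 1.0 / (1.0 + np.exp(-(v_s + 48.0) / 6.2))
        mt = mt_inf + (mt - mt_inf) * np.exp(-dt / 8.0)
        ht_inf = 1.0 / (1.0 + np.exp((v_s + 80.0) / 10.0))
        ht = ht_inf + (ht - ht_inf) * np.exp(-dt / 120.0)
        hnap_inf = 1.0 / (1.0 + np.exp((v_s + 80.0) / 10.0))
        hnap = hnap_inf + (hnap - hnap_inf) * np.exp(-dt / 500.0)
        mnap_inf = 1.0 / (1.0 + np.exp(-(v_s + 50.0) / 5.0))

        g_na = _G_NA * m_inf * m_inf * m_inf * h
        g_k = _G_K * n * n * n * n
        g_h_eff = g_hcn * mh
        g_t_eff = g_calva * mt * mt * ht
        g_nap_eff = g_nap * mnap_inf * hnap

        g_ahp *= f_ahp

        g_tot_s = (
            _G_LEAK_SOMA + g_couple + g_na + g_k + g_h_eff + g_t_eff
            + g_nap_eff + g_ahp + g_gaba_s
        )
        v_inf_s = (
            _G_LEAK_SOMA * _E_LEAK
            + g_couple * v_d
            + g_na * _E_NA
            + (g_k + g_ahp) * _E_K
            + g_h_eff * _E_HCN
            + g_t_eff * _E_CA
            + g_nap_eff * _E_NA
            + g_gaba_s * (-75.0)
            + i_tonic
        ) / g_tot_s
        v_prev = v_s
        v_s = v_inf_s + (v_s - v_inf_s) * np.exp(-dt * g_tot_s / _C_SOMA)
        if not np.isfinite(v_s):
            return spikes[:0], rec_t[:k_rec], rec_v[:k_rec], rec_ht[:k_rec], rec_hnap[:k_rec], -1

        if v_prev < -15.0 <= v_s and (t - last_spk) > 1.5:
            if n_spk < spikes.size:
                spikes[n_spk] = t
                n_spk += 1
            last_spk = t
            g_ahp += g_ahp_inc

        # decay synaptic states
        a_r_g *= f_r_g; a_d_g *= f_d_g
        a_r_gs *= f_r_gs; a_d_gs *= f_d_gs
        a_r_a *= f_r_a; a_d_a *= f_d_a
        a_r_f *= f_r_f; a_d_f *= f_d_f
        a_r_s *= f_r_s; a_d_s *= f_d_s

        if step % record_every == 0:
            rec_t[k_rec] = t
            rec_v[k_rec] = v_s
            rec_ht[k_rec] = ht
            rec_hnap[k_rec] = hnap
            k_rec += 1

    return spikes[:n_spk], rec_t[:k_rec], rec_v[:k_rec], rec_ht[:k_rec], rec_hnap[:k_rec], 0


def _kin_params(kin: SynapseKinetics) -> tuple[float, float, float]:
    k = kin.at_model_temperature()
    return k.tau_rise, k.tau_decay, k.norm


def simulate_trial(
    config: CNModelConfig,
    pn_trains: list[SpikeTrain],
    mf_seed: int,
    duration: float,
    dt: float | None = None,
    record_every_ms: float = 0.25,
    silence_synapses: bool = False,
) -> TrialResult:
    """Simulate one trial of the CN neuron driven by a PN population.

    The result is deterministic given ``(config, pn_trains, mf_seed, dt)``.
    ``silence_synapses`` runs the in vitro-like mode (intrinsic pacemaking
    only).  Raises on a non-finite membrane potential.
    """
    if not silence_synapses and len(pn_trains) != config.n_pn_synapses:
        raise ValueError(
            f"expected {config.n_pn_synapses} PN trains, got {len(pn_trains)}"
        )
    dt = config.dt if dt is None else dt
    gi, ge = config.gains

    if silence_synapses:
        inh_t = inh_w = np.empty(0)
        exc_t = np.empty(0)
    else:
        inh_t, inh_w = _inhibitory_events(pn_trains, GABA_KIN.g_max * gi / 100.0)
        mf = make_mossy_fiber_trains(
            config.n_mf_synapses, config.mf_rate_hz, duration, mf_seed
        )
        exc_t = np.sort(np.concatenate([m.times for m in mf]))
    w_ampa = np.full(exc_t.size, config.g_ampa_max_ns * ge / 100.0)
    w_nf = np.full(exc_t.size, config.g_nmda_fast_max_ns * ge / 100.0)
    w_ns = np.full(exc_t.size, config.g_nmda_slow_max_ns * ge / 100.0)

    g_hcn, g_calva, g_nap = REBOUND_VARIANTS[config.rebound_variant]
    if config.block_rebound:
        g_hcn = g_calva = g_nap = 0.0

    tr_g, td_g, n_g = _kin_params(GABA_KIN)
    tr_gs, td_gs, n_gs = _kin_params(GABA_SLOW_KIN)
    tr_a, td_a, n_a = _kin_params(AMPA_KIN)
    tr_f, td_f, n_f = _kin_params(NMDA_FAST_KIN)
    tr_s, td_s, n_s = _kin_params(NMDA_SLOW_KIN)
    s1f, s2f = NMDA_S["fast"]
    s1s, s2s = NMDA_S["slow"]

    rec_every = max(1, int(round(record_every_ms / dt)))
    spikes, rt, rv, rht, rhnap, flag = _integrate(
        duration, dt,
        inh_t, inh_w,
        exc_t, w_ampa, w_nf, w_ns,
        tr_g, td_g, n_g,
        tr_gs, td_gs, n_gs, config.gaba_slow_frac,
        tr_a, td_a, n_a,
        tr_f, td_f, n_f, s1f, s2f,
        tr_s, td_s, n_s, s1s, s2s,
        g_hcn, g_calva, g_nap, config.i_tonic_pa,
        config.g_ahp_inc_ns, config.tau_ahp_ms,
        config.g_couple_ns, config.c_dend_pf, config.frac_inh_soma,
        rec_every,
    )
    if flag != 0:
        raise RuntimeError(
            "unstable integration (non-finite membrane potential); "
            f"dt={dt} ms, gains=({gi}, {ge})%"
        )
    return TrialResult(spikes, rt, rv, rht, rhnap, mf_seed, config)


def run_control_pair(
    config: CNModelConfig,
    synced_trains: list[SpikeTrain],
    unsynced_trains: list[SpikeTrain],
    mf_seed: int,
    duration: float,
    dt: float | None = None,
) -> tuple[TrialResult, TrialResult]:
    """Run a synchronized trial and its matched control.

    Both runs use the identical mossy-fiber realization (same ``mf_seed``)
    and integration settings; the train sets should differ only by the
    synchronization transform.
    """
    if len(synced_trains) != len(unsynced_trains):
        raise ValueError("synced and control populations differ in size")
    sync = simulate_trial(config, synced_trains, mf_seed, duration, dt)
    ctrl = simulate_trial(config, unsynced_trains, mf_seed, duration, dt)
    sync.matched_control = ctrl
    return sync, ctrl
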