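"""Desk-scale orchestration of the simulation experiment grid.

Each named experiment enumerates a grid of conditions (synchrony type x
fraction x pause length x gain x rebound variant x blockade x jitter x
forced pre-pause rate), runs the full pipeline for every cell -- synthesize
PN trains, impose the synchronous pause, simulate the CN neuron with its
matched control, analyze -- and writes per-trial tables, per-cell summaries
and a seed/config manifest.

The default trial is 3 s long with one synchronous event at 1.5 s (at least
500 ms after trial start and 1 s before trial end, leaving room for the 1 s
rebound window), and 100 trials per cell at full scale; ``scale_factor``
shrinks the trial count proportionally for desk-scale runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import pn_synthesis as pns
from . import spikestats as sps
from .cn_model import CNModelConfig, run_control_pair, simulate_trial
from .synchrony import (
    ForcedRateResult,
    PrepauseRateSpec,
    SynchronySpec,
    align_pauses,
    force_prepause_rate,
)
from .trains import SpikeTrain

__all__ = [
    "EXPERIMENTS",
    "ExperimentPlan",
    "run_cell",
    "reproduce",
    "tune_gains",
]

log = logging.getLogger(__name__)

TRIAL_DURATION_MS = 3000.0
EVENT_TIME_MS = 1500.0
N_TRIALS_FULL = 100
N_PN = 200


@dataclass(frozen=True)
class ExperimentPlan:
    """A named grid of condition cells."""

    name: str
    grid: list[dict]
    n_trials: int = N_TRIALS_FULL


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def make_population(
    n_units: int,
    duration_ms: float,
    seed,
    rate_hz: float = 50.0,
) -> tuple[list[SpikeTrain], list[pns.Segmentation]]:
    """Template PN population with per-train segmentations."""
    rng = np.random.default_rng(seed)
    trains, segs = [], []
    for k in range(n_units):
        tr = pns.generate_template_train(
            rate_hz=rate_hz, duration_ms=duration_ms, seed=rng, unit_id=k
        )
        trains.append(tr)
        segs.append(pns.segment_isis(tr))
    return trains, segs


def _synthesize_population(
    templates: list[SpikeTrain],
    segs: list[pns.Segmentation],
    rng: np.random.Generator,
    min_pause_ms: float,
) -> list[SpikeTrain]:
    """Per-trial synthetic population; every train is guaranteed to hold at
    least one ISI exceeding ``min_pause_ms`` (re-drawn if necessary)."""
    out = []
    for tr, seg in zip(templates, segs):
        for _ in range(50):
            s = pns.synthesize_train(seg, tr, seed=rng)
            if np.any(s.isis > min_pause_ms):
                out.append(s)
                break
        else:
            raise RuntimeError(
                f"could not synthesize an eligible pause > {min_pause_ms} ms"
            )
    return out


def run_cell(
    cell: dict,
    n_trials: int,
    seed: int,
    duration_ms: float = TRIAL_DURATION_MS,
    event_time: float = EVENT_TIME_MS,
) -> dict:
    """Run one grid cell: trials with matched controls plus analysis.

    ``cell`` keys: ``sync_type``, ``fraction``, ``pause_threshold``, ``gain``,
    and optionally ``jitter_ms``, ``variant``, ``block_rebound``,
    ``f_pn_range``.
    """
    sync_type = cell.get("sync_type", "beginning")
    fraction = cell.get("fraction", 1.0)
    threshold = cell.get("pause_threshold", 40.0)
    jitter = cell.get("jitter_ms", 0.0)
    f_pn_range = cell.get("f_pn_range")
    config = CNModelConfig(
        rebound_variant=cell.get("variant", "m2"),
        gain_condition=cell.get("gain", "high"),
        block_rebound=cell.get("block_rebound", False),
    )

    root = np.random.SeedSequence([int(seed), 0xC311])
    tmpl_ss, *trial_ss = root.spawn(n_trials + 1)
    templates, segs = make_population(N_PN, duration_ms, tmpl_ss)
    sel_margin = jitter if sync_type in ("beginning", "mixed") else 0.0

    trials, f_pns, fallbacks = [], [], 0
    for ss in trial_ss:
        rng = np.random.default_rng(ss)
        trains = _synthesize_population(templates, segs, rng, threshold + sel_margin)
        spec = SynchronySpec(
            sync_type if sync_type != "none" else "none",
            fraction,
            threshold,
            jitter,
            event_time,
            seed=_seed_int(ss),
        )
        if f_pn_range is not None:
            f_pn = float(rng.uniform(*f_pn_range))
            forced: ForcedRateResult = force_prepause_rate(
                trains, spec, PrepauseRateSpec(f_pn)
            )
            synced = forced.trains
            fallbacks += len(forced.fallback_units)
            f_pns.append(f_pn)
        elif sync_type == "none":
            synced = trains
        else:
            synced = align_pauses(trains, spec)
        sync, _ = run_control_pair(
            config, synced, trains, _seed_int(ss.spawn(1)[0]), duration_ms
        )
        trials.append(sync)

    window = (event_time, event_time + threshold)
    out: dict = {"cell": dict(cell), "n_trials": n_trials, "window": window}
    out["rate_increase_hz"] = np.array([sps.rate_increase(t, window) for t in trials])
    out["reliability_pct"] = sps.reliability(trials, window)
    sample = sps.first_spike_latencies(trials, event_time, threshold)
    out["latency_sample"] = sample
    if sample.latencies.size >= 2:
        out["vector_strength"] = sps.vector_strength(sample)
    if sample.latencies.size >= 8:
        val, est = sps.latency_variability(sample)
        out["latency_variability_ms"], out["latency_estimator"] = val, est
    if jitter > 0 and sample.latencies.size:
        out["jitter_period_pct"] = sps.jitter_period_fraction(sample, jitter)
    if f_pn_range is not None:
        out["rebound"] = sps.rebound_analysis(trials, np.array(f_pns), event_time)
        out["f_pn_hz"] = np.array(f_pns)
        out["fallback_count"] = fallbacks
    out["trials"] = trials
    return out


# ----------------------------------------------------------------- grids --

def _grid_gain_cv() -> list[dict]:
    return [{"sync_type": "none", "gain": g} for g in ("low", "medium", "high")]


def _grid_rate_modulation() -> list[dict]:
    return [
        {"sync_type": s, "fraction": f, "pause_threshold": p, "gain": g}
        for s in ("beginning", "overlapping")
        for p in (20.0, 40.0)
        for g in ("low", "medium", "high")
        for f in (0.25, 0.5, 0.75, 1.0)
    ]


def _grid_blockade() -> list[dict]:
    return [
        {
            "sync_type": "beginning",
            "fraction": f,
            "pause_threshold": 20.0,
            "gain": g,
            "block_rebound": b,
        }
        for g in ("high", "medium")
        for b in (False, True)
        for f in (0.25, 0.5, 0.75, 1.0)
    ]


def _grid_timelocking() -> list[dict]:
    return [
        {"sync_type": s, "fraction": f, "pause_threshold": p, "gain": g}
        for s in ("beginning", "overlapping")
        for p in (20.0, 40.0)
        for g in ("low", "medium", "high")
        for f in (0.25, 0.5, 0.75, 1.0)
    ]


def _grid_jitter() -> list[dict]:
    return [
        {
            "sync_type": "beginning",
            "fraction": f,
            "pause_threshold": 40.0,
            "gain": g,
            "jitter_ms": j,
        }
        for g in ("low", "high")
        for j in (1.0, 3.0, 5.0, 7.0)
        for f in (0.25, 0.5, 0.75, 1.0)
    ]


def _grid_rebound() -> list[dict]:
    return [
        {
            "sync_type": "beginning",
            "fraction": f,
            "pause_threshold": 20.0,
            "gain": "high",
            "f_pn_range": (40.0, 120.0),
        }
        for f in (0.25, 0.5, 0.75, 1.0)
    ]


EXPERIMENTS = {
    "gain_cv": _grid_gain_cv,
    "rate_modulation": _grid_rate_modulation,
    "blockade": _grid_blockade,
    "timelocking": _grid_timelocking,
    "jitter": _grid_jitter,
    "rebound": _grid_rebound,
}


def _cell_hash(cell: dict) -> str:
    return hashlib.sha256(json.dumps(cell, sort_keys=True).encode()).hexdigest()[:12]


def _summarize(res: dict) -> dict:
    s: dict = {"cell": res["cell"], "n_trials": res["n_trials"]}
    ri = res["rate_increase_hz"]
    s["rate_increase_mean_hz"] = float(ri.mean())
    s["rate_increase_sd_hz"] = float(ri.std(ddof=1)) if ri.size > 1 else 0.0
    s["reliability_pct"] = res["reliability_pct"]
    s["n_censored"] = res["latency_sample"].n_censored
    if "vector_strength" in res:
        vs = res["vector_strength"]
        s.update(R=vs.R, Z=vs.Z, p=vs.p, threshold_R=vs.threshold_R)
    if "latency_variability_ms" in res:
        s["latency_variability_ms"] = res["latency_variability_ms"]
        s["latency_estimator"] = res["latency_estimator"]
    if "jitter_period_pct" in res:
        s["jitter_period_pct"] = res["jitter_period_pct"]
    if "rebound" in res:
        s["rebound_pearson_r"] = res["rebound"]["pearson_r"]
        s["fallback_count"] = res["fallback_count"]
    return s


def reproduce(
    experiment_name: str,
    scale_factor: float = 0.25,
    master_seed: int = 0,
    out_dir="runs",
) -> Path:
    """Run a named experiment grid and write its results directory.

    ``scale_factor`` shrinks the 100-trial cells proportionally (minimum 3
    trials); the manifest records every seed and config hash so a rerun with
    the same ``master_seed`` is byte-identical.
    """
    if experiment_name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment_name!r}; valid: {sorted(EXPERIMENTS)}"
        )
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    n_trials = max(3, int(round(N_TRIALS_FULL * scale_factor)))
    grid = EXPERIMENTS[experiment_name]()
    out = Path(out_dir) / experiment_name
    out.mkdir(parents=True, exist_ok=True)

    rows, summaries, manifest_cells = [], [], []
    gain_cv_mode = experiment_name == "gain_cv"
    for k, cell in enumerate(grid):
        cell_seed = int(
            np.random.SeedSequence([int(master_seed), k]).generate_state(1)[0]
            % (2**31)
        )
        manifest_cells.append({"cell": cell, "hash": _cell_hash(cell), "seed": cell_seed})
        if gain_cv_mode:
            summaries.append(_run_gain_cv_cell(cell, cell_seed, scale_factor))
            continue
        res = run_cell(cell, n_trials, cell_seed)
        summaries.append(_summarize(res))
        for i, (ri, t) in enumerate(zip(res["rate_increase_hz"], res["trials"])):
            rows.append(
                {
                    "cell_hash": _cell_hash(cell),
                    "trial": i,
                    "rate_increase_hz": ri,
                    "n_spikes": t.cn_spike_times.size,
                    **{k2: v for k2, v in cell.items() if not isinstance(v, tuple)},
                }
            )
        log.info("cell %d/%d done (%s)", k + 1, len(grid), _cell_hash(cell))

    if rows:
        pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summaries, fh, indent=1, default=_json_default)
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "experiment": experiment_name,
                "scale_factor": scale_factor,
                "master_seed": int(master_seed),
                "n_trials": n_trials,
                "cells": manifest_cells,
            },
            fh,
            indent=1,
            default=_json_default,
        )
    return out


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def _run_gain_cv_cell(cell: dict, seed: int, scale_factor: float) -> dict:
    """Long unsynchronized run measuring the CN ISI coefficient of variation."""
    duration = max(5_000.0, 60_000.0 * scale_factor)
    templates, _ = make_population(N_PN, duration, np.random.SeedSequence([seed, 1]))
    config = CNModelConfig(gain_condition=cell["gain"])
    res = simulate_trial(config, templates, seed, duration)
    isis = np.diff(res.cn_spike_times)
    cv = float(isis.std() / isis.mean()) if isis.size > 3 else float("nan")
    return {
        "cell": cell,
        "duration_ms": duration,
        "rate_hz": 1000.0 * res.cn_spike_times.size / duration,
        "isi_cv": cv,
    }


def tune_gains(
    config: CNModelConfig,
    target_rate_band: tuple[float, float] = (37.0, 38.0),
    max_iter: int = 20,
    seed: int = 0,
    sim_duration_ms: float = 20_000.0,
    n_reps: int = 3,
) -> tuple[float, float]:
    """Bisect the excitatory gain until the unsynchronized rate hits the band.

    The inhibitory gain stays at its condition value; the excitatory gain is
    searched over [0, 200]% (firing rate is monotone in it).  Returns
    ``(excitatory_gain_pct, achieved_rate_hz)``; raises if the band is
    unreachable.
    """

    def rate_at(ge: float) -> float:
        rates = []
        for rep in range(n_reps):
            ss = np.random.SeedSequence([seed, rep])
            templates, _ = make_population(N_PN, sim_duration_ms, ss)
            cfg = replace_gain(config, ge)
            res = simulate_trial(cfg, templates, _seed_int(ss.spawn(1)[0]), sim_duration_ms)
            rates.append(1000.0 * res.cn_spike_times.size / sim_duration_ms)
        return float(np.mean(rates))

    lo_band, hi_band = target_rate_band
    ge = config.gains[1]
    r = rate_at(ge)
    if lo_band <= r <= hi_band:
        return ge, r
    lo, hi = 0.0, 200.0
    r_lo = rate_at(lo)
    if r_lo > hi_band:
        raise ValueError("target band unreachable within gain in [0, 200]%")
    # very large excitatory gains drive the neuron into depolarization block,
    # so shrink the upper bracket until the rate there exceeds the band
    r_hi = rate_at(hi)
    while r_hi < lo_band and hi > 1.0:
        hi *= 0.6
        r_hi = rate_at(hi)
        if lo_band <= r_hi <= hi_band:
            return hi, r_hi
    if r_hi < lo_band:
        raise ValueError("target band unreachable within gain in [0, 200]%")
    for _ in range(max_iter):
        ge = 0.5 * (lo + hi)
        r = rate_at(ge)
        if r < lo_band:
            lo = ge
        elif r > hi_band:
            hi = ge
        else:
            return ge, r
    return ge, r


def replace_gain(config: CNModelConfig, excitatory_gain_pct: float) -> CNModelConfig:
    from dataclasses import replace

    return replace(config, excitatory_gain_pct=excitatory_gain_pct)
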