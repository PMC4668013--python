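"""Imposing pause synchrony on a population of PN spike trains.

A *synchronous pause event* aligns one pause (ISI longer than a threshold,
20 or 40 ms by default) from each participating train to a common anchor on
the population timeline.  Three alignment types are supported:

``beginning``
    the spike that starts the pause is identical across participants
    (optionally jittered by a one-sided uniform delay),
``ending``
    the spike that ends the pause is identical across participants,
``overlapping``
    every participating pause strictly contains the common window
    ``[event_time, event_time + pause_threshold]`` but no spike is aligned;
    pause onsets are staggered uniformly at random subject to containment.

``mixed`` splits the participants equally over the three types.

Alignment relocates the selected pause (and, in forced-rate mode, its
preceding 100 ms of spiking) within the train's ISI sequence: the pause is
removed from its original position and re-inserted so that it sits at the
anchor, with the sub-interval mismatch absorbed by moving a single nearby
spike.  Spike counts are conserved, times stay strictly increasing, the
ISIs before and after the pause remain randomized, and every spike outside
the affected span keeps exactly its original time -- so a matched control
run differs from the synchronized run only locally around the event.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .trains import SpikeTrain

__all__ = [
    "SynchronySpec",
    "PrepauseRateSpec",
    "ForcedRateResult",
    "select_pause",
    "align_pauses",
    "jitter_beginning_spikes",
    "force_prepause_rate",
]

log = logging.getLogger(__name__)

SYNC_TYPES = ("beginning", "ending", "overlapping", "mixed", "none")


@dataclass(frozen=True)
class SynchronySpec:
    """Parameters of one imposed synchronous-pause event."""

    sync_type: str = "beginning"
    fraction: float = 1.0
    pause_threshold: float = 40.0
    jitter_ms: float = 0.0
    event_time: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sync_type not in SYNC_TYPES:
            raise ValueError(f"sync_type must be one of {SYNC_TYPES}")
        if not 0.0 < self.fraction <= 1.0 and self.sync_type != "none":
            raise ValueError("fraction must lie in (0, 1]")
        if self.pause_threshold <= 0:
            raise ValueError("pause_threshold must be positive")
        if self.jitter_ms < 0:
            raise ValueError("jitter_ms must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass(frozen=True)
class PrepauseRateSpec:
    """Forced mean PN rate in the window preceding the aligned pause."""

    f_pn: float
    window_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.f_pn <= 0 or self.window_ms <= 0:
            raise ValueError("f_pn and window_ms must be positive")


@dataclass(frozen=True)
class ForcedRateResult:
    trains: list[SpikeTrain]
    fallback_units: list


def _eligible_pauses(train: SpikeTrain, threshold: float) -> np.ndarray:
    """Indices ``i`` such that ISI ``(t_i, t_{i+1})`` exceeds ``threshold``."""
    return np.flatnonzero(train.isis > threshold)


def select_pause(
    train: SpikeTrain, pause_threshold: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Uniformly select one pause longer than ``pause_threshold``.

    Returns the ``(start_ms, end_ms)`` of the chosen ISI; raises if the train
    holds no eligible pause (the caller may regenerate the train).
    """
    idx = _eligible_pauses(train, pause_threshold)
    if idx.size == 0:
        raise ValueError(
            f"train {train.unit_id!r}: no ISI exceeds {pause_threshold} ms"
        )
    i = int(rng.choice(idx))
    return float(train.times[i]), float(train.times[i + 1])


def _relocate_run(train: SpikeTrain, j0: int, i: int, target_start: float) -> SpikeTrain:
    """Relocate the ISI run ``j0..i`` (ending with the pause ISI ``i``) so the
    pause-start spike lands exactly at ``target_start``.

    The run is removed from the ISI sequence and re-inserted after the spike
    closest to the required position; the sub-ISI mismatch is absorbed by
    displacing that single spike within its neighbor intervals.  All spikes
    outside the span between the old and new location keep their exact
    original times.
    """
    t = train.times
    isis = np.diff(t)
    run = isis[j0 : i + 1]
    lead = float(run[:-1].sum())  # offset of the pause-start spike in the run
    rest = np.concatenate([isis[:j0], isis[i + 1 :]])
    t_rest = t[0] + np.concatenate([[0.0], np.cumsum(rest)])
    span = float(run.sum())

    anchor = target_start - lead
    if not t_rest[1] < anchor < t_rest[-2]:
        raise ValueError(
            f"train {train.unit_id!r}: anchor {anchor:.1f} ms outside the train"
        )
    order = np.argsort(np.abs(t_rest - anchor))
    for k in order:
        k = int(k)
        if k < 1 or k > t_rest.size - 2:
            continue
        delta = anchor - t_rest[k]
        if t_rest[k] + delta > t_rest[k - 1] and t_rest[k] + delta < t_rest[k + 1]:
            break
    else:  # pragma: no cover - anchor always representable in practice
        raise ValueError("no spike can absorb the alignment adjustment")

    new_times = np.concatenate(
        [
            t_rest[:k],
            anchor + np.concatenate([[0.0], np.cumsum(run)]),
            t_rest[k + 1 :] + span,
        ]
    )
    return train.with_times(new_times)


def _already_aligned(train: SpikeTrain, spec: SynchronySpec, kind: str) -> bool:
    """True when the train already satisfies the alignment post-condition."""
    t, thr, E = train.times, spec.pause_threshold, spec.event_time
    isis = train.isis
    if kind == "beginning":
        hi = E + spec.jitter_ms + 1e-9
        ok = (t[:-1] >= E - 1e-9) & (t[:-1] <= hi) & (isis > thr)
        return bool(np.any(ok))
    if kind == "ending":
        ok = (np.abs(t[1:] - (E + thr)) < 1e-9) & (isis > thr)
        return bool(np.any(ok))
    if kind == "overlapping":
        ok = (t[:-1] < E) & (t[1:] > E + thr)
        return bool(np.any(ok))
    raise ValueError(kind)


def _participants(n: int, spec: SynchronySpec, rng: np.random.Generator):
    k = int(np.floor(spec.fraction * n + 0.5))  # round half up
    idx = np.sort(rng.choice(n, size=k, replace=False))
    if spec.sync_type == "mixed":
        kinds = ["beginning", "ending", "overlapping"]
        assign = [kinds[j % 3] for j in range(k)]
    else:
        assign = [spec.sync_type] * k
    return idx, assign


def _align_one(
    train: SpikeTrain,
    kind: str,
    spec: SynchronySpec,
    rng: np.random.Generator,
    selection_threshold: float | None = None,
) -> SpikeTrain:
    if _already_aligned(train, spec, kind):
        return train
    thr = spec.pause_threshold if selection_threshold is None else selection_threshold
    ts, te = select_pause(train, thr, rng)
    i = int(np.searchsorted(train.times, ts))
    E = spec.event_time
    if kind == "beginning":
        target = E
    elif kind == "ending":
        target = (E + spec.pause_threshold) - (te - ts)
    else:  # overlapping: stagger the onset, keep the window strictly inside
        u = rng.uniform(1e-6, 1.0 - 1e-6)
        target = E - u * (te - ts - spec.pause_threshold)
    return _relocate_run(train, i, i, target)


def align_pauses(trains: list[SpikeTrain], spec: SynchronySpec) -> list[SpikeTrain]:
    """Impose one synchronous pause event on a population of trains.

    ``round(fraction * n)`` trains are drawn at random to participate; each
    has one eligible pause aligned to ``spec.event_time`` according to
    ``spec.sync_type``.  Non-participating trains are returned unchanged.
    For the ``beginning`` type a positive ``spec.jitter_ms`` then delays each
    aligned pause-start spike by an independent Uniform[0, jitter] draw.
    Applying the same spec twice is a no-op the second time.
    """
    if spec.sync_type == "none":
        return list(trains)
    rng = np.random.default_rng(spec.seed)
    idx, assign = _participants(len(trains), spec, rng)
    # jittered beginnings must keep > threshold after the delay
    sel_thr = spec.pause_threshold + (
        spec.jitter_ms if spec.sync_type in ("beginning", "mixed") else 0.0
    )
    out = list(trains)
    for j, kind in zip(idx, assign):
        thr = sel_thr if kind == "beginning" else spec.pause_threshold
        out[j] = _align_one(trains[j], kind, spec, rng, selection_threshold=thr)
    if spec.jitter_ms > 0:
        jrng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9E37]))
        out = jitter_beginning_spikes(out, spec.jitter_ms, jrng, spec.event_time)
    return out


def jitter_beginning_spikes(
    trains: list[SpikeTrain],
    jitter_ms: float,
    rng: np.random.Generator,
    event_time: float,
) -> list[SpikeTrain]:
    """Delay each aligned pause-beginning spike by Uniform[0, jitter] ms.

    Only trains holding a spike exactly at ``event_time`` (the aligned
    beginning spikes) are touched; each such spike is displaced by an
    independent draw.  A displacement that would cross the next spike raises.
    Trains whose beginning spike already lies inside ``(event_time,
    event_time + jitter]`` are treated as jittered and left unchanged.
    """
    if jitter_ms < 0:
        raise ValueError("jitter must be non-negative")
    if jitter_ms == 0:
        return list(trains)
    out = []
    for tr in trains:
        k = np.flatnonzero(np.abs(tr.times - event_time) < 1e-9)
        if k.size == 0:
            out.append(tr)
            continue
        i = int(k[0])
        d = rng.uniform(0.0, jitter_ms)
        t = tr.times.copy()
        if i + 1 < t.size and t[i] + d >= t[i + 1]:
            raise ValueError(
                f"train {tr.unit_id!r}: jitter {d:.2f} ms crosses the next spike"
            )
        t[i] += d
        out.append(tr.with_times(t))
    return out


def _window_count(train: SpikeTrain, t_start: float, window_ms: float) -> int:
    """Spikes in ``[t_start - window, t_start)``."""
    lo = np.searchsorted(train.times, t_start - window_ms)
    hi = np.searchsorted(train.times, t_start)  # excludes the start spike
    return int(hi - lo)


def force_prepause_rate(
    trains: list[SpikeTrain],
    spec: SynchronySpec,
    rate_spec: PrepauseRateSpec,
    rng: np.random.Generator | None = None,
) -> ForcedRateResult:
    """Beginning-align pauses whose preceding window fires at ``f_pn``.

    For each participant a pause exceeding the threshold *and* whose
    preceding ``window_ms`` of spiking has a count within +/-1 of
    ``f_pn * window`` is selected; the pause and its preceding window are
    moved together as a rigid block.  When no compliant pause exists the
    participant falls back to an unconstrained eligible pause (recorded in
    ``fallback_units`` and logged).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    idx, _ = _participants(len(trains), spec, rng)
    target = rate_spec.f_pn * rate_spec.window_ms / 1000.0
    out = list(trains)
    fallbacks = []
    for j in idx:
        tr = trains[j]
        elig = _eligible_pauses(tr, spec.pause_threshold)
        if elig.size == 0:
            raise ValueError(f"train {tr.unit_id!r}: no eligible pause")
        counts = np.array(
            [_window_count(tr, tr.times[i], rate_spec.window_ms) for i in elig]
        )
        ok = elig[np.abs(counts - target) <= 1.0]
        if ok.size:
            i = int(rng.choice(ok))
        else:
            i = int(rng.choice(elig))
            fallbacks.append(tr.unit_id)
        ts = tr.times[i]
        a = max(1, int(np.searchsorted(tr.times, ts - rate_spec.window_ms)))
        out[j] = _relocate_run(tr, a - 1, i, spec.event_time)
    if fallbacks:
        log.info(
            "force_prepause_rate: fallback selection for %d/%d participants "
            "(f_pn=%.1f Hz)", len(fallbacks), idx.size, rate_spec.f_pn,
        )
    return ForcedRateResult(out, fallbacks)
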