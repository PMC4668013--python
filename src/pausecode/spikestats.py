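"""Trial-level and across-trial spike statistics.

Covers the analyses used throughout the study: windowed firing-rate increase
versus a matched control, reliability of that increase, first-spike latency
variability with a Lilliefors normality gate (SD if normal, MAD otherwise),
population PSTHs, circular vector strength with Rayleigh significance, the
Pearson correlation, bootstrap / one-tailed t significance machinery, and
the rebound analysis relating pre-pause PN rate to the post-pause CN rate
increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .cn_model import TrialResult
from .trains import SpikeTrain

__all__ = [
    "LatencySample",
    "VectorStrengthResult",
    "rate_increase",
    "reliability",
    "first_spike_latencies",
    "latency_variability",
    "vector_strength",
    "rayleigh_p",
    "rayleigh_threshold",
    "psth",
    "pearson_r",
    "compare_conditions",
    "rebound_analysis",
    "jitter_period_fraction",
    "pause_complex_spike_ratio",
]


@dataclass(frozen=True)
class LatencySample:
    """First-spike latencies from pause onset, ms, over a set of trials.

    Trials where no CN spike fell inside the pause are censored: they are
    excluded from the latencies but counted in ``n_censored``.
    """

    latencies: np.ndarray
    pause_duration: float
    n_trials: int
    n_censored: int = 0

    def __post_init__(self) -> None:
        lat = np.asarray(self.latencies, dtype=float)
        object.__setattr__(self, "latencies", lat)
        if lat.size and (lat.min() < 0 or lat.max() >= self.pause_duration):
            raise ValueError("latencies must lie in [0, pause_duration)")


@dataclass(frozen=True)
class VectorStrengthResult:
    """Vector strength with Rayleigh significance."""

    R: float
    Z: float
    p: float
    threshold_R: float
    angles: np.ndarray
    n: int


def rate_increase(trial: TrialResult, window: tuple[float, float]) -> float:
    """Firing-rate change (Hz) inside ``window`` versus the matched control.

    ``(count_sync - count_control) / window_length``; antisymmetric under
    swapping the two runs.
    """
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    if trial.matched_control is None:
        raise ValueError("trial carries no matched control")
    dur = trial.trace_t[-1] if trial.trace_t.size else 0.0
    if start < 0 or end > dur + 1e-6:
        raise ValueError("window lies outside the simulated interval")
    d = trial.spikes_in(start, end) - trial.matched_control.spikes_in(start, end)
    return 1000.0 * d / (end - start)


def reliability(trials: list[TrialResult], window: tuple[float, float]) -> float:
    """Percentage of trials with a positive in-window rate increase."""
    if not trials:
        raise ValueError("need at least one trial")
    pos = sum(1 for tr in trials if rate_increase(tr, window) > 0)
    return 100.0 * pos / len(trials)


def first_spike_latencies(
    trials: list[TrialResult], pause_onset: float, pause_duration: float
) -> LatencySample:
    """First CN spike latency from pause onset for every trial.

    Spikes are searched inside ``[pause_onset, pause_onset + duration)``;
    trials without an in-pause spike are censored.
    """
    lats = []
    censored = 0
    for tr in trials:
        t = tr.cn_spike_times
        i = np.searchsorted(t, pause_onset)
        if i < t.size and t[i] < pause_onset + pause_duration:
            lats.append(t[i] - pause_onset)
        else:
            censored += 1
    return LatencySample(np.array(lats), pause_duration, len(trials), censored)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def latency_variability(
    sample: LatencySample,
    alpha_lilliefors: float = 0.01,
    companions: list[LatencySample] | None = None,
) -> tuple[float, str]:
    """Spread of first-spike latencies with a normality gate.

    Lilliefors' normality test (at ``alpha_lilliefors``, default a 99%
    confidence criterion) is applied to the sample and to every distribution
    it is being compared with (``companions``); the standard deviation is
    reported if all pass, otherwise the median absolute deviation.  Returns
    ``(value_ms, estimator)`` with estimator ``"SD"`` or ``"MAD"``.
    """
    all_samples = [sample] + list(companions or [])
    for s in all_samples:
        if s.latencies.size < 8:
            raise ValueError("need at least 8 latencies")
    normal = True
    for s in all_samples:
        if np.std(s.latencies) == 0.0:
            continue  # degenerate: either estimator returns 0
        _, p = lilliefors(s.latencies, dist="norm")
        if p <= alpha_lilliefors:
            normal = False
    x = sample.latencies
    if normal:
        return float(np.std(x, ddof=1)), "SD"
    return _mad(x), "MAD"


def rayleigh_p(R: float, n: int) -> float:
    """Rayleigh-test p-value with the standard finite-n correction.

    With resultant length ``Rn = n R`` and ``Z = n R^2``,
    ``p = exp(sqrt(1 + 4 n + 4 (n^2 - Rn^2)) - (1 + 2 n))``.
    """
    rn2 = (n * R) ** 2
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - rn2)
    if arg < 0:
        return 0.0
    return float(min(1.0, np.exp(np.sqrt(arg) - (1.0 + 2.0 * n))))


def rayleigh_threshold(n: int, alpha: float = 0.01) -> tuple[float, float]:
    """Critical vector strength and Z at significance ``alpha`` for ``n`` trials.

    Inverts the corrected Rayleigh p-value in closed form:
    ``Rn^2 = ((1+2n)^2 - (1+2n+ln alpha)^2) / 4``, ``Z = Rn^2 / n``.
    """
    if n < 1 or not 0 < alpha < 1:
        raise ValueError("need n >= 1 and alpha in (0, 1)")
    b = 1.0 + 2.0 * n
    rn2 = (b * b - (b + np.log(alpha)) ** 2) / 4.0
    z = rn2 / n
    return float(np.sqrt(rn2) / n), float(z)


def vector_strength(sample: LatencySample, alpha: float = 0.01) -> VectorStrengthResult:
    """Vector strength of first-spike latencies on the pause circle.

    Each latency maps to the angle ``2 pi latency / pause_duration`` (the
    entire circle is the duration of the synchronous pause); the vector
    strength is the resultant length of the unit phasors normalized to the
    number of trials, 1 for perfect time-locking and 0 for uniform timing.
    """
    x = sample.latencies
    if x.size < 2:
        raise ValueError("need at least 2 uncensored latencies")
    angles = 2.0 * np.pi * x / sample.pause_duration
    n = int(x.size)
    R = float(np.abs(np.exp(1j * angles).mean()))
    Z = n * R * R
    p = rayleigh_p(R, n)
    thr, _ = rayleigh_threshold(n, alpha)
    return VectorStrengthResult(R, Z, p, thr, angles, n)


def psth(
    trains: list[SpikeTrain], bin_ms: float = 1.0, t_max: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Population spike-timing histogram normalized to total spike count.

    Returns ``(bin_edges, heights)``; the heights sum to 1.
    """
    all_t = np.concatenate([tr.times for tr in trains]) if trains else np.empty(0)
    if all_t.size == 0:
        raise ValueError("no spikes to histogram")
    if t_max is None:
        t_max = max(tr.duration for tr in trains)
    edges = np.arange(0.0, t_max + bin_ms, bin_ms)
    counts, edges = np.histogram(all_t, bins=edges)
    return edges, counts / all_t.size


def pearson_r(x, y) -> float:
    """Pearson correlation ``cov(X, Y) / (sigma_X sigma_Y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


def compare_conditions(
    a,
    b,
    test: str = "bootstrap",
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float, bool]:
    """Significance of a difference in means between two conditions.

    ``bootstrap``: both samples are centered to the pooled mean (the null),
    resampled ``n_boot`` times, and the percentile of the observed mean
    difference under the null resamples is reported.  ``one_tailed_t`` uses
    Welch's t-test.  Returns ``(statistic, p, significant_at_alpha)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 observations per sample")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0, False
    diff = a.mean() - b.mean()
    if test == "one_tailed_t":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)
    if test != "bootstrap":
        raise ValueError("test must be 'bootstrap' or 'one_tailed_t'")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b]).mean()
    a0 = a - a.mean() + pooled
    b0 = b - b.mean() + pooled
    ra = rng.choice(a0, size=(n_boot, a.size), replace=True).mean(axis=1)
    rb = rng.choice(b0, size=(n_boot, b.size), replace=True).mean(axis=1)
    null = ra - rb
    if alternative == "greater":
        p = (np.sum(null >= diff) + 1) / (n_boot + 1)
    elif alternative == "less":
        p = (np.sum(null <= diff) + 1) / (n_boot + 1)
    else:
        p = (np.sum(np.abs(null) >= abs(diff)) + 1) / (n_boot + 1)
    return float(diff), float(p), bool(p < alpha)


def jitter_period_fraction(
    sample: LatencySample, jitter_ms: float
) -> float:
    """Percentage of trials whose first in-pause spike falls in the jitter
    period (earlier than ``pause onset + jitter_ms``)."""
    if sample.latencies.size == 0:
        raise ValueError("no uncensored latencies")
    return 100.0 * float(np.mean(sample.latencies < jitter_ms))


def rebound_analysis(
    trials: list[TrialResult],
    f_pn: np.ndarray,
    pause_onset: float,
    rebound_window_ms: float = 1000.0,
    prepause_window_ms: float = 100.0,
) -> dict:
    """Relate pre-pause PN rate to the 1 s post-onset CN rate increase.

    For each trial the CN rate increase over ``rebound_window_ms`` from the
    pause onset (versus the matched control) is computed; the Pearson
    correlation of that increase with the forced pre-pause PN rate ``f_pn``
    is reported, together with the mean CaLVA and NaP inactivation gates over
    the ``prepause_window_ms`` before the pause.
    """
    if len(trials) != len(np.atleast_1d(f_pn)):
        raise ValueError("one f_pn per trial required")
    increases = np.array(
        [rate_increase(tr, (pause_onset, pause_onset + rebound_window_ms)) for tr in trials]
    )
    ht_means, hnap_means = [], []
    for tr in trials:
        if tr.gate_calva_h.size == 0:
            raise ValueError("trial carries no gating traces")
        sel = (tr.trace_t >= pause_onset - prepause_window_ms) & (tr.trace_t < pause_onset)
        ht_means.append(float(tr.gate_calva_h[sel].mean()))
        hnap_means.append(float(tr.gate_nap_h[sel].mean()))
    r = pearson_r(np.asarray(f_pn, dtype=float), increases)
    return {
        "rate_increase_hz": increases,
        "pearson_r": r,
        "mean_calva_h": np.array(ht_means),
        "mean_nap_h": np.array(hnap_means),
    }


def pause_complex_spike_ratio(
    rate_hz: float = 50.0,
    pause_isi_fraction: float = 0.5,
    complex_spike_rate_hz: float = 1.0,
) -> float:
    """How many simple-spike pauses occur per complex spike.

    A PN firing at ``rate_hz`` produces ``rate_hz`` ISIs per second, of which
    ``pause_isi_fraction`` are pauses; dividing by the complex-spike rate
    gives the factor by which pauses outnumber complex spikes (25 for 50 Hz,
    half the ISIs in pauses and 1 Hz complex spikes).
    """
    if rate_hz <= 0 or complex_spike_rate_hz <= 0:
        raise ValueError("rates must be positive")
    if not 0 <= pause_isi_fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    return rate_hz * pause_isi_fraction / complex_spike_rate_hz
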