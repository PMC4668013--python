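import numpy as np
import pytest

from pausecode import (
    LatencySample,
    compare_conditions,
    first_spike_latencies,
    jitter_period_fraction,
    latency_variability,
    pause_complex_spike_ratio,
    pearson_r,
    psth,
    rate_increase,
    rayleigh_p,
    rayleigh_threshold,
    rebound_analysis,
    reliability,
    vector_strength,
)
from pausecode import SpikeTrain
from pausecode.cn_model import CNModelConfig, TrialResult


def make_trial(sync_times, ctrl_times, duration=3000.0):
    def mk(times):
        return TrialResult(
            np.asarray(times, float), np.array([0.0, duration]),
            np.zeros(2), np.zeros(2), np.zeros(2), 0, CNModelConfig(),
        )
    tr = mk(sync_times)
    tr.matched_control = mk(ctrl_times)
    return tr


class TestRateIncrease:
    def test_identical_runs_give_zero(self):
        tr = make_trial([100.0, 200.0], [100.0, 200.0])
        assert rate_increase(tr, (50.0, 250.0)) == 0.0

    def test_count_arithmetic(self):
        tr = make_trial([10.0, 20.0, 30.0], [15.0])
        assert rate_increase(tr, (0.0, 40.0)) == pytest.approx(50.0)

    def test_antisymmetric_under_swap(self):
        tr = make_trial([10.0, 20.0, 30.0], [15.0])
        rev = make_trial([15.0], [10.0, 20.0, 30.0])
        assert rate_increase(tr, (0.0, 40.0)) == -rate_increase(rev, (0.0, 40.0))

    def test_bad_windows_rejected(self):
        tr = make_trial([10.0], [10.0])
        with pytest.raises(ValueError):
            rate_increase(tr, (100.0, 100.0))
        with pytest.raises(ValueError):
            rate_increase(tr, (0.0, 99_999.0))


class TestReliability:
    def test_counting(self):
        up = make_trial([10.0, 12.0], [10.0])
        flat = make_trial([10.0], [10.0])
        assert reliability([up, up, flat], (0.0, 40.0)) == pytest.approx(200 / 3)
        assert reliability([up], (0.0, 40.0)) == 100.0
        assert reliability([flat], (0.0, 40.0)) == 0.0
        with pytest.raises(ValueError):
            reliability([], (0.0, 40.0))


class TestLatencies:
    def test_first_spike_and_censoring(self):
        trials = [make_trial([1505.0, 1512.0], []), make_trial([1499.0, 1541.0], [])]
        s = first_spike_latencies(trials, 1500.0, 40.0)
        np.testing.assert_allclose(s.latencies, [5.0])
        assert s.n_censored == 1

    def test_constant_latencies_have_zero_spread(self):
        s = LatencySample(np.full(20, 7.0), 20.0, 20)
        val, est = latency_variability(s)
        assert val == 0.0

    def test_heavy_tailed_sample_uses_mad(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(10, 0.5, 90), rng.uniform(0, 19, 10)])
        s = LatencySample(np.clip(x, 0, 19.9), 20.0, 100)
        val, est = latency_variability(s)
        assert est == "MAD"
        assert val < np.std(s.latencies)

    def test_gaussian_sample_uses_sd(self):
        rng = np.random.default_rng(1)
        s = LatencySample(np.clip(rng.normal(10, 1, 100), 0, 19.9), 20.0, 100)
        val, est = latency_variability(s)
        assert est == "SD"

    def test_default_gate_alpha_is_one_percent(self):
        import inspect
        sig = inspect.signature(latency_variability)
        assert sig.parameters["alpha_lilliefors"].default == 0.01

    def test_too_few_latencies_rejected(self):
        with pytest.raises(ValueError):
            latency_variability(LatencySample(np.arange(5.0), 20.0, 5))

    def test_jitter_period_fraction(self):
        s = LatencySample(np.array([1.0, 2.0, 6.0, 9.0]), 20.0, 4)
        assert jitter_period_fraction(s, 5.0) == pytest.approx(50.0)


class TestVectorStrength:
    def test_identical_latencies_give_unity(self):
        s = LatencySample(np.full(10, 3.0), 20.0, 10)
        assert vector_strength(s).R == pytest.approx(1.0)

    def test_antipodal_latencies_cancel(self):
        s = LatencySample(np.array([2.0, 12.0]), 20.0, 2)
        assert vector_strength(s).R == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_phasor_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = rng.integers(2, 50)
            lat = rng.uniform(0.0, 19.999, n)
            s = LatencySample(lat, 20.0, int(n))
            res = vector_strength(s)
            ang = 2 * np.pi * lat / 20.0
            brute = np.hypot(np.cos(ang).sum(), np.sin(ang).sum()) / n
            assert res.R == pytest.approx(brute, abs=1e-12)
            assert res.Z == pytest.approx(n * brute**2, abs=1e-9)

    def test_rayleigh_self_consistency(self):
        for n in (10, 50, 100, 500):
            for alpha in (0.05, 0.01):
                thr, z = rayleigh_threshold(n, alpha)
                assert z == pytest.approx(n * thr**2, rel=1e-4)
                # p at the threshold equals alpha
                assert rayleigh_p(thr, n) == pytest.approx(alpha, rel=1e-6)

    def test_censored_only_sample_rejected(self):
        with pytest.raises(ValueError):
            vector_strength(LatencySample(np.array([1.0]), 20.0, 5, 4))


class TestPSTH:
    def test_normalization(self, small_population):
        edges, h = psth(small_population, bin_ms=1.0)
        assert h.sum() == pytest.approx(1.0)
        for b in (0.5, 2.0, 5.0):
            _, hb = psth(small_population, bin_ms=b)
            assert hb.sum() == pytest.approx(1.0)

    def test_single_bin_concentration(self):
        t = SpikeTrain(0, [10.2, 10.4, 10.6], 20.0)
        edges, h = psth([t], bin_ms=1.0)
        assert h.max() == pytest.approx(1.0)

    def test_uniform_spikes_flatten(self):
        rng = np.random.default_rng(3)
        trains = [SpikeTrain(k, np.sort(rng.uniform(0, 1000.0, 5000)), 1000.0)
                  for k in range(20)]
        _, h = psth(trains, bin_ms=1.0)
        assert h.max() / h[h > 0].min() < 2.0

    def test_no_spikes_rejected(self):
        with pytest.raises(ValueError):
            psth([SpikeTrain(0, [], 10.0)])


class TestPearson:
    def test_exact_values(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCompareConditions:
    def test_identical_samples_not_significant(self):
        a = np.arange(10.0)
        stat, p, sig = compare_conditions(a, a.copy(), seed=1)
        assert not sig

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(3.0, 1.0, 100)
        b = rng.normal(0.0, 1.0, 100)
        for test in ("bootstrap", "one_tailed_t"):
            stat, p, sig = compare_conditions(a, b, test=test, seed=2)
            assert sig

    def test_default_alpha(self):
        import inspect
        assert inspect.signature(compare_conditions).parameters["alpha"].default == 0.05

    def test_type_one_error_calibrated(self):
        """False-positive rate of the bootstrap test stays near its nominal
        5% level on null (identical-distribution) data."""
        rng = np.random.default_rng(5)
        hits = 0
        reps = 400
        for k in range(reps):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            _, _, sig = compare_conditions(
                a, b, n_boot=800, seed=k, alternative="two-sided"
            )
            hits += sig
        assert hits / reps <= 0.07


class TestRatioAndRebound:
    def test_pause_complex_spike_ratio(self):
        assert pause_complex_spike_ratio(50.0, 0.5, 1.0) == pytest.approx(25.0)

    def test_rebound_recovers_injected_linear_dependence(self):
        rng = np.random.default_rng(6)
        f_pn = rng.uniform(40, 100, 30)
        trials = []
        for f in f_pn:
            n_extra = int(round(f / 10.0))
            sync_times = np.sort(rng.uniform(1500.0, 2500.0, 10 + n_extra))
            ctrl_times = np.sort(rng.uniform(1500.0, 2500.0, 10))
            tr = make_trial(sync_times, ctrl_times)
            tr.trace_t = np.linspace(0.0, 3000.0, 100)
            tr.gate_calva_h = np.full(100, 0.05)
            tr.gate_nap_h = np.full(100, 0.05)
            tr.matched_control.trace_t = tr.trace_t
            trials.append(tr)
        out = rebound_analysis(trials, f_pn, 1500.0)
        inc = np.array([rate_increase(t, (1500.0, 2500.0)) for t in trials])
        from scipy import stats
        assert out["pearson_r"] == pytest.approx(
            stats.pearsonr(f_pn, inc).statistic, abs=1e-12
        )

    def test_identical_trials_surface_error(self):
        trials = []
        for _ in range(5):
            tr = make_trial([1600.0], [1600.0])
            tr.trace_t = np.linspace(0, 3000, 50)
            tr.gate_calva_h = np.zeros(50)
            tr.gate_nap_h = np.zeros(50)
            tr.matched_control.trace_t = tr.trace_t
            trials.append(tr)
        with pytest.raises(ValueError):
            rebound_analysis(trials, np.full(5, 50.0), 1500.0)
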