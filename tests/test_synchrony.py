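import numpy as np
import pytest

from pausecode import (
    PrepauseRateSpec,
    SpikeTrain,
    SynchronySpec,
    align_pauses,
    force_prepause_rate,
    generate_template_train,
    jitter_beginning_spikes,
    select_pause,
)

E = 1500.0


def eligible(trains, thr):
    return [t for t in trains if np.any(t.isis > thr)]


class TestSelectPause:
    def test_unique_candidate_is_returned(self):
        times = np.concatenate([np.arange(0.0, 101.0, 10.0), [145.0, 155.0]])
        t = SpikeTrain(0, times, 200.0)
        rng = np.random.default_rng(0)
        start, end = select_pause(t, 40.0, rng)
        assert (start, end) == (100.0, 145.0)

    def test_no_candidate_raises(self):
        t = SpikeTrain(0, np.arange(0.0, 200.0, 35.0), 220.0)
        with pytest.raises(ValueError):
            select_pause(t, 40.0, np.random.default_rng(0))

    def test_selection_is_uniform(self):
        # 4 eligible pauses; each should be drawn ~25% of the time
        times = [0, 10, 60, 70, 125, 135, 190, 200, 260, 270]
        t = SpikeTrain(0, np.array(times, float), 300.0)
        rng = np.random.default_rng(1)
        counts = {}
        for _ in range(10_000):
            s, _ = select_pause(t, 40.0, rng)
            counts[s] = counts.get(s, 0) + 1
        assert len(counts) == 4
        for c in counts.values():
            assert abs(c / 10_000 - 0.25) < 0.02


class TestAlignPauses:
    def test_zero_participants_leaves_input_unchanged(self, small_population):
        trains = eligible(small_population, 20.0)
        spec = SynchronySpec("beginning", 0.001, 20.0, 0.0, E, seed=0)  # rounds to 0
        out = align_pauses(trains, spec)
        assert all(a is b for a, b in zip(out, trains))

    def test_beginning_start_spikes_have_zero_variance(self, small_population):
        trains = eligible(small_population, 20.0)
        spec = SynchronySpec("beginning", 1.0, 20.0, 0.0, E, seed=2)
        out = align_pauses(trains, spec)
        starts = []
        for tr in out:
            k = np.flatnonzero(np.abs(tr.times - E) < 1e-9)
            assert k.size == 1
            i = int(k[0])
            assert tr.times[i + 1] - tr.times[i] > 20.0
            starts.append(tr.times[i])
        assert np.var(starts) == 0.0

    def test_ending_spikes_aligned(self, small_population):
        trains = eligible(small_population, 20.0)
        spec = SynchronySpec("ending", 1.0, 20.0, 0.0, E, seed=3)
        out = align_pauses(trains, spec)
        for tr in out:
            k = np.flatnonzero(np.abs(tr.times - (E + 20.0)) < 1e-9)
            assert k.size == 1
            i = int(k[0])
            assert tr.times[i] - tr.times[i - 1] > 20.0

    def test_overlapping_window_contains_no_spikes(self, small_population):
        trains = eligible(small_population, 20.0)
        spec = SynchronySpec("overlapping", 1.0, 20.0, 0.0, E, seed=4)
        out = align_pauses(trains, spec)
        for tr in out:
            # no spike inside the common window
            assert not np.any((tr.times >= E) & (tr.times <= E + 20.0))
            # the window is strictly inside one ISI
            i = np.searchsorted(tr.times, E) - 1
            assert tr.times[i] < E and tr.times[i + 1] > E + 20.0

    def test_spike_count_and_duration_conserved(self, small_population):
        trains = eligible(small_population, 20.0)
        for sync in ("beginning", "ending", "overlapping", "mixed"):
            spec = SynchronySpec(sync, 0.5, 20.0, 0.0, E, seed=5)
            out = align_pauses(trains, spec)
            for a, b in zip(out, trains):
                assert a.n_spikes == b.n_spikes
                assert a.duration == b.duration
                assert np.all(np.diff(a.times) > 0)

    @pytest.mark.parametrize("sync", ["beginning", "ending", "overlapping"])
    def test_alignment_is_idempotent(self, small_population, sync):
        trains = eligible(small_population, 20.0)
        spec = SynchronySpec(sync, 0.5, 20.0, 0.0, E, seed=6)
        once = align_pauses(trains, spec)
        twice = align_pauses(once, spec)
        for a, b in zip(once, twice):
            assert np.array_equal(a.times, b.times)

    def test_monotone_containment_in_threshold(self, small_population):
        for tr in small_population:
            n20 = int(np.sum(tr.isis > 20.0))
            n40 = int(np.sum(tr.isis > 40.0))
            assert n40 <= n20

    def test_insufficient_pauses_raise(self):
        t = SpikeTrain(0, np.arange(0.0, 3000.0, 10.0), 3000.0)
        spec = SynchronySpec("beginning", 1.0, 40.0, 0.0, E, seed=0)
        with pytest.raises(ValueError):
            align_pauses([t] * 3, spec)


class TestJitter:
    @pytest.fixture()
    def aligned(self, small_population):
        trains = eligible(small_population, 27.0)
        spec = SynchronySpec("beginning", 1.0, 20.0, 0.0, E, seed=7)
        # select pauses longer than 27 so a 7 ms jitter always fits
        from pausecode.synchrony import _align_one
        rng = np.random.default_rng(7)
        return [
            _align_one(t, "beginning", spec, rng, selection_threshold=27.0)
            for t in trains
        ]

    def test_zero_jitter_is_identity(self, aligned):
        out = jitter_beginning_spikes(aligned, 0.0, np.random.default_rng(0), E)
        for a, b in zip(out, aligned):
            assert np.array_equal(a.times, b.times)

    def test_displacements_bounded_by_jitter(self, aligned):
        out = jitter_beginning_spikes(aligned, 7.0, np.random.default_rng(1), E)
        d = []
        for tr in out:
            k = np.searchsorted(tr.times, E - 1e-9)
            d.append(tr.times[k] - E)
        d = np.array(d)
        assert np.all((d >= 0.0) & (d <= 7.0))

    def test_mean_displacement_is_half_jitter(self):
        rng = np.random.default_rng(2)
        t = SpikeTrain(0, [1000.0, E, E + 50.0, 2000.0], 3000.0)
        d = []
        for _ in range(10_000):
            out = jitter_beginning_spikes([t], 4.0, rng, E)
            d.append(out[0].times[1] - E)
        assert np.mean(d) == pytest.approx(2.0, abs=0.05)

    def test_crossing_neighbor_raises(self):
        t = SpikeTrain(0, [1000.0, E, E + 0.5, 2000.0], 3000.0)
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            for _ in range(100):
                jitter_beginning_spikes([t], 5.0, rng, E)


class TestForcePrepauseRate:
    def test_compliant_window_counts(self, small_population):
        trains = eligible(small_population, 20.0)
        spec = SynchronySpec("beginning", 1.0, 20.0, 0.0, E, seed=8)
        res = force_prepause_rate(trains, spec, PrepauseRateSpec(50.0))
        compliant = 0
        for tr in res.trains:
            if tr.unit_id in res.fallback_units:
                continue
            count = int(np.sum((tr.times >= E - 100.0) & (tr.times < E)))
            assert abs(count - 5.0) <= 1.0
            compliant += 1
        assert compliant > 0

    def test_unattainable_rate_falls_back(self, small_population, caplog):
        import logging
        trains = eligible(small_population, 20.0)
        spec = SynchronySpec("beginning", 1.0, 20.0, 0.0, E, seed=9)
        with caplog.at_level(logging.INFO, logger="pausecode.synchrony"):
            res = force_prepause_rate(trains, spec, PrepauseRateSpec(300.0))
        assert len(res.fallback_units) == len(trains)
        assert any("fallback" in r.message for r in caplog.records)

    def test_pause_still_aligned(self, small_population):
        trains = eligible(small_population, 20.0)
        spec = SynchronySpec("beginning", 1.0, 20.0, 0.0, E, seed=10)
        res = force_prepause_rate(trains, spec, PrepauseRateSpec(50.0))
        for tr in res.trains:
            k = np.flatnonzero(np.abs(tr.times - E) < 1e-9)
            assert k.size == 1
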