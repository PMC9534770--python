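import numpy as np
import pytest
from scipy.signal import savgol_filter
from scipy.stats import poisson

from oracles import naive_assembly, naive_detect, naive_extrema
from popassembly.events import (DetectionConfig, PopulationEvent,
                                _local_extrema, asls_baseline,
                                detect_events, detection_threshold,
                                detect_population_events, event_assembly,
                                event_stats, evoked_assembly, shuffle_isi)
from popassembly.preprocess import PopulationRateTrace, SpikeRaster, population_rate
from popassembly.synthetic import SimulationConfig, make_protocol, simulate_raster, spontaneous_protocol


def _raster(spikes):
    return SpikeRaster(np.asarray(spikes, dtype=np.uint8), frame_rate=30.0)


class TestShuffleIsi:
    def test_single_spike_neuron_unchanged(self):
        spikes = np.zeros((1, 50), dtype=np.uint8)
        spikes[0, 17] = 1
        rates = shuffle_isi(_raster(spikes), n_shuffles=20, rng=0)
        assert (rates[:, 17] == 1).all()
        assert rates.sum() == 20

    def test_per_neuron_spike_counts_conserved(self, rng):
        spikes = (rng.random((15, 300)) < 0.05).astype(np.uint8)
        total = spikes.sum()
        rates = shuffle_isi(_raster(spikes), n_shuffles=30, rng=1)
        assert (rates.sum(axis=1) == total).all()

    def test_two_spike_isi_enumeration(self):
        """Spikes at frames 3 and 8: intervals {4, 5} (first latency from
        frame -1), so surrogates land at {3, 8} or {4, 8}; both must occur."""
        spikes = np.zeros((1, 20), dtype=np.uint8)
        spikes[0, [3, 8]] = 1
        rates = shuffle_isi(_raster(spikes), n_shuffles=200, rng=2)
        seen = {tuple(np.flatnonzero(r)) for r in rates}
        assert seen == {(3, 8), (4, 8)}
        assert (rates[:, 8] == 1).all()  # last spike frame is invariant

    def test_rejects_no_shuffles(self):
        with pytest.raises(ValueError):
            shuffle_isi(_raster(np.zeros((1, 5))), n_shuffles=0)


class TestAslsBaseline:
    def test_constant_signal_fixed_point(self):
        z = asls_baseline(np.full(200, 4.2), lam=1e6)
        assert np.allclose(z, 4.2, atol=1e-6)

    def test_linear_ramp_preserved(self):
        y = np.linspace(0.0, 10.0, 300)
        z = asls_baseline(y, lam=1e6)
        assert np.allclose(z, y, atol=1e-3)

    def test_recovers_flat_baseline_under_sparse_peaks(self, rng):
        y = np.full(600, 2.0)
        peaks = rng.choice(600, size=12, replace=False)
        y[peaks] += 30.0
        z = asls_baseline(y, p=0.01, lam=1e6)
        away = np.ones(600, dtype=bool)
        for p in peaks:
            away[max(0, p - 10):p + 10] = False
        assert np.abs(z[away] - 2.0).max() < 0.1

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            asls_baseline(np.array([1.0, np.nan, 2.0, 3.0]))


class TestDetectionThreshold:
    def test_all_zero_raster_threshold_zero(self):
        raster = _raster(np.zeros((4, 100)))
        rate = population_rate(raster)
        surr = shuffle_isi(raster, 10, rng=0)
        thr = detection_threshold(rate, surr)
        assert np.allclose(thr, 0.0, atol=1e-8)

    def test_poisson_offset_matches_analytic_quantile(self):
        """Stationary Poisson raster: the surrogate offset approximates the
        99th percentile of a Poisson(n * lambda * dt) count."""
        rng = np.random.default_rng(3)
        n, frames, rate_hz, fs = 200, 6000, 0.5, 30.0
        p = 1 - np.exp(-rate_hz / fs)
        spikes = (rng.random((n, frames)) < p).astype(np.uint8)
        raster = SpikeRaster(spikes, fs)
        rate = population_rate(raster)
        surr = shuffle_isi(raster, 100, rng=4)
        thr = detection_threshold(rate, surr)
        mu = n * p
        analytic_q99 = poisson.ppf(0.99, mu)
        offset = thr - rate.baseline
        assert abs(offset.mean() - analytic_q99) <= 1.5

    def test_self_surrogate_offset_is_trace_mean(self):
        """With the trace itself as the only surrogate, the per-frame 99th
        percentile is the trace, so the offset equals the trace mean."""
        counts = np.array([0, 1, 3, 2, 0, 5, 1, 0, 2, 1], dtype=float)
        rate = PopulationRateTrace(counts=counts, frame_rate=30.0)
        thr = detection_threshold(rate, counts[None, :])
        assert np.allclose(thr - rate.baseline, counts.mean())

    def test_mismatched_lengths_raise(self):
        rate = PopulationRateTrace(counts=np.zeros(10), frame_rate=30.0)
        with pytest.raises(ValueError):
            detection_threshold(rate, np.zeros((5, 9)))


class TestLocalExtrema:
    def test_matches_naive_scan_on_random_traces(self, rng):
        for _ in range(100):
            x = np.round(rng.normal(size=rng.integers(10, 60)), 1)
            maxima, minima = _local_extrema(x)
            n_max, n_min = naive_extrema(x)
            assert list(maxima) == n_max
            assert list(minima) == n_min

    def test_plateau_midpoint(self):
        x = np.array([0, 1, 2, 2, 2, 1, 0], dtype=float)
        maxima, _ = _local_extrema(x)
        assert list(maxima) == [3]


class TestDetectEvents:
    def _rate(self, counts):
        return PopulationRateTrace(counts=np.asarray(counts, float), frame_rate=30.0)

    def test_subthreshold_trace_gives_no_events(self):
        rate = self._rate(np.ones(50))
        assert detect_events(rate, np.full(50, 10.0)) == []

    def test_single_triangular_bump(self):
        counts = np.zeros(60)
        counts[20:31] = [2, 4, 6, 8, 10, 12, 10, 8, 6, 4, 2]
        rate = self._rate(counts)
        events = detect_events(rate, np.full(60, 5.0))
        assert len(events) == 1
        ev = events[0]
        assert ev.start <= 20 and ev.end >= 30
        assert 23 <= ev.peak <= 27

    def test_matches_naive_reference_on_random_traces(self, rng):
        cfg = DetectionConfig()
        for _ in range(100):
            n = int(rng.integers(30, 120))
            counts = rng.poisson(2.0, size=n).astype(float)
            counts[rng.integers(5, n - 5)] += rng.integers(5, 15)
            rate = self._rate(counts)
            thr = np.full(n, float(rng.uniform(3, 6)))
            events = detect_events(rate, thr, cfg)
            smoothed = savgol_filter(counts, cfg.sg_window, cfg.sg_order)
            expected = naive_detect(list(smoothed), list(thr))
            assert [(e.start, e.end, e.peak) for e in events] == expected

    def test_window_longer_than_trace_raises(self):
        with pytest.raises(ValueError):
            detect_events(self._rate(np.zeros(5)), np.zeros(5))


class TestAssemblies:
    def test_event_over_silent_frames_gives_zero_vector(self):
        raster = _raster(np.zeros((5, 20)))
        ev = PopulationEvent(start=3, end=7, peak=5, frame_rate=30.0)
        assert event_assembly(raster, ev).sum() == 0

    def test_boundary_frames_inclusive(self):
        spikes = np.zeros((2, 20), dtype=np.uint8)
        spikes[0, 3] = 1   # at event start
        spikes[1, 7] = 1   # at event end
        ev = PopulationEvent(start=3, end=7, peak=5, frame_rate=30.0)
        vec = event_assembly(_raster(spikes), ev)
        assert vec.tolist() == [1, 1]

    def test_matches_bruteforce_any_scan(self, rng):
        for _ in range(100):
            spikes = (rng.random((10, 50)) < 0.1).astype(np.uint8)
            s = int(rng.integers(0, 40))
            e = int(rng.integers(s, 49))
            ev = PopulationEvent(start=s, end=e, peak=s, frame_rate=30.0)
            vec = event_assembly(_raster(spikes), ev)
            assert vec.tolist() == naive_assembly(spikes.tolist(), s, e)


class TestEvokedAssembly:
    def _protocol(self):
        return make_protocol(2, 1, 0.5, 1.0, 30.0, (("stim", 30.0),), rng=0)

    def test_silent_window_absent(self):
        proto = self._protocol()
        raster = _raster(np.zeros((4, proto.n_frames)))
        assert evoked_assembly(raster, proto, 0) is None

    def test_all_neurons_spiking(self):
        proto = self._protocol()
        spikes = np.zeros((4, proto.n_frames), dtype=np.uint8)
        onset = int(proto.trials["onset_frame"].iloc[0])
        spikes[:, onset + 2] = 1
        vec = evoked_assembly(_raster(spikes), proto, 0)
        assert vec.tolist() == [1, 1, 1, 1]

    def test_matches_bruteforce_window_scan(self, rng):
        proto = self._protocol()
        window = 15
        for _ in range(50):
            spikes = (rng.random((6, proto.n_frames)) < 0.05).astype(np.uint8)
            for row in proto.trials.itertuples(index=False):
                vec = evoked_assembly(_raster(spikes), proto, int(row.trial))
                onset = int(row.onset_frame)
                expected = naive_assembly(spikes.tolist(), onset,
                                          onset + window - 1)
                if sum(expected) == 0:
                    assert vec is None
                else:
                    assert vec.tolist() == expected


class TestEventStats:
    def test_empty_list(self):
        stats = event_stats([], 100, 600.0)
        assert stats["rate_hz"] == 0
        assert np.isnan(stats["duration_mean_ms"])

    def test_two_event_arithmetic(self):
        fr = 30.0
        # 300 ms event: 9 frames; 420 ms: about 12.6 -> use exact frames
        e1 = PopulationEvent(start=0, end=8, peak=4, frame_rate=fr)     # 300 ms
        e2 = PopulationEvent(start=100, end=112, peak=105, frame_rate=fr)
        stats = event_stats([e1, e2], 100, 600.0)
        assert stats["rate_hz"] == pytest.approx(2 / 600.0)
        assert stats["duration_mean_ms"] == pytest.approx(
            (e1.duration_ms + e2.duration_ms) / 2)


class TestFullDetection:
    def test_determinism_given_seed(self):
        proto = spontaneous_protocol(120.0)
        raster, _ = simulate_raster(SimulationConfig(n_neurons=100, seed=9), proto)
        cfg = DetectionConfig(seed=13)
        ev1, _ = detect_population_events(raster, cfg)
        ev2, _ = detect_population_events(raster, cfg)
        assert [(e.start, e.end) for e in ev1] == [(e.start, e.end) for e in ev2]

    def test_recovery_of_planted_events(self):
        """Events at >=3x background coactivation: >=90% recovered, each by
        exactly one detected event."""
        proto = spontaneous_protocol(600.0)
        raster, truth = simulate_raster(
            SimulationConfig(n_neurons=300, seed=10), proto)
        events, _ = detect_population_events(raster, DetectionConfig(seed=11))
        det = np.array([(e.start, e.end) for e in events])
        overlaps = [
            int(((det[:, 0] <= e) & (det[:, 1] >= s)).sum())
            for s, e in truth.event_intervals
        ]
        exactly_one = np.mean([o == 1 for o in overlaps])
        assert exactly_one >= 0.9
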