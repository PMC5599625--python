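"""Firing-rate, synchrony, burst and feature statistics."""

import numpy as np
import pytest

from synaptonet import (
    SpikeRaster,
    afr_trace,
    detect_bursts,
    detect_bursts_raster,
    detect_network_bursts,
    mean_firing_rate,
    synchronous_event_rate,
    unit_features,
)


def make_raster(units, times, n_units, duration):
    order = np.argsort(times, kind="stable")
    return SpikeRaster(
        units=np.asarray(units)[order],
        times=np.asarray(times, dtype=float)[order],
        n_units=n_units,
        duration_s=duration,
    )


class TestMeanFiringRate:
    def test_empty_raster(self):
        r = make_raster([], [], 10, 10.0)
        assert mean_firing_rate(r) == 0.0

    def test_half_active(self):
        r = make_raster([0] * 10, np.linspace(0.1, 9.9, 10), 2, 10.0)
        assert mean_firing_rate(r) == pytest.approx(0.5)

    def test_poisson_rate_recovery(self):
        rng = np.random.default_rng(0)
        lam, n_units, dur = 2.0, 50, 100.0
        counts = rng.poisson(lam * dur, n_units)
        units = np.repeat(np.arange(n_units), counts)
        times = rng.uniform(0, dur, counts.sum())
        r = make_raster(units, times, n_units, dur)
        se = lam / np.sqrt(n_units * lam * dur)
        assert abs(mean_firing_rate(r) - lam) <= 3 * np.sqrt(lam / (n_units * dur))


class TestAfrTrace:
    def test_all_units_every_ms(self):
        n_units, dur = 5, 1.0
        steps = np.arange(1000)
        units = np.tile(np.arange(n_units), 1000)
        times = np.repeat((steps + 0.5) / 1000.0, n_units)
        r = make_raster(units, times, n_units, dur)
        _, a = afr_trace(r, 10)
        assert np.allclose(a, 1000.0)

    def test_empty_raster_zero_trace(self):
        r = make_raster([], [], 10, 5.0)
        _, a = afr_trace(r, 10)
        assert np.all(a == 0)

    def test_mean_equals_mfr_identity(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(0, 60.0, 4000)
        units = rng.integers(0, 30, 4000)
        r = make_raster(units, times, 30, 60.0)  # 10 ms divides 60 s exactly
        _, a = afr_trace(r, 10)
        assert a.mean() == pytest.approx(mean_firing_rate(r), rel=1e-9)

    def test_nonpositive_bin_rejected(self):
        r = make_raster([], [], 2, 5.0)
        with pytest.raises(ValueError):
            afr_trace(r, 0)


class TestSynchronousEvents:
    def test_flat_zero_trace(self):
        t = np.arange(100) * 0.01
        rate, ev = synchronous_event_rate(t, np.zeros(100), threshold=1.0)
        assert rate == 0.0 and ev == []

    def test_periodic_population_spikes(self):
        # one sharp excursion every 20 s over 900 s -> 3 events/min
        bin_s = 0.01
        n = int(900 / bin_s)
        t = np.arange(n) * bin_s
        a = np.zeros(n)
        a[::2000] = 100.0
        rate, ev = synchronous_event_rate(t, a)
        assert len(ev) == 45
        assert rate == pytest.approx(3.0, rel=1e-3)

    def test_matches_brute_force_run_counting(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 0.3, 20000)
        t = np.arange(20000) * 0.01
        thr = a.mean() + 3 * a.std()
        _, events = synchronous_event_rate(t, a, threshold=thr, merge_gap_s=0.0)
        # oracle: count maximal supra-threshold runs directly
        above = a > thr
        runs = int(np.sum(np.diff(above.astype(int)) == 1) + above[0])
        assert len(events) == runs

    def test_gaussian_tail_excursion_count(self):
        rng = np.random.default_rng(3)
        n = 200000
        a = rng.normal(0.0, 1.0, n)
        t = np.arange(n) * 0.01
        thr = 3.0
        above = (a > thr).sum()
        from scipy.stats import norm
        expect = n * norm.sf(3.0)
        assert abs(above - expect) <= 4 * np.sqrt(expect)


class TestBurstDetection:
    def test_single_spike_no_burst(self):
        ann = detect_bursts(np.array([1.0]), duration_s=10.0)
        assert ann.bursts == []

    def test_constructed_burst_statistics(self):
        times = 1.0 + np.arange(10) * 0.01  # 10 spikes at 10 ms ISI
        ann = detect_bursts(times, duration_s=10.0, max_isi_ms=100, min_spikes=5)
        assert len(ann.bursts) == 1
        b = ann.bursts[0]
        assert b.n_spikes == 10
        assert b.duration_s == pytest.approx(0.09)
        assert b.mif_hz == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_run_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 30.0, 300))
        max_isi_ms, min_spikes = 100.0, 5
        ann = detect_bursts(times, duration_s=30.0, max_isi_ms=max_isi_ms,
                            min_spikes=min_spikes)
        # O(n^2) oracle: for each start, extend while ISI <= limit; keep
        # maximal runs
        oracle = []
        i = 0
        n = len(times)
        while i < n:
            j = i
            while j + 1 < n and times[j + 1] - times[j] <= max_isi_ms / 1000.0:
                j += 1
            if j - i + 1 >= min_spikes:
                oracle.append((times[i], times[j], j - i + 1))
            i = j + 1
        got = [(b.start_s, b.end_s, b.n_spikes) for b in ann.bursts]
        assert got == pytest.approx(oracle)

    def test_trailing_sparse_spikes_do_not_change_bursts(self):
        core = 1.0 + np.arange(8) * 0.02
        ann1 = detect_bursts(core, duration_s=60.0)
        extended = np.concatenate([core, [10.0, 20.0, 30.0]])
        ann2 = detect_bursts(extended, duration_s=60.0)
        assert [(b.start_s, b.end_s) for b in ann1.bursts] == [
            (b.start_s, b.end_s) for b in ann2.bursts
        ]


class TestNetworkBursts:
    def _co_burst_raster(self, n_units, event_times, duration):
        units, times = [], []
        for t0 in event_times:
            for u in range(n_units):
                units.extend([u] * 6)
                times.extend(t0 + np.arange(6) * 0.01)
        return make_raster(units, times, n_units, duration)

    def test_single_unit_every_burst_is_network_burst(self):
        r = self._co_burst_raster(1, [5.0, 25.0, 45.0], 60.0)
        anns = detect_bursts_raster(r)
        nb = detect_network_bursts(anns, min_fraction=0.25)
        assert len(nb.events) == 3

    def test_three_co_bursts_in_minute(self):
        r = self._co_burst_raster(10, [5.0, 25.0, 45.0], 60.0)
        anns = detect_bursts_raster(r)
        nb = detect_network_bursts(anns, min_fraction=0.25)
        assert len(nb.events) == 3
        assert nb.rate_per_min == pytest.approx(3.0)
        assert all(f == 1.0 for _, _, f in nb.events)

    def test_rate_bounded_by_unit_burst_rate_when_all_required(self):
        rng = np.random.default_rng(4)
        units, times = [], []
        for u in range(5):
            for t0 in rng.uniform(0, 290, 8):
                units.extend([u] * 6)
                times.extend(t0 + np.arange(6) * 0.01)
        r = make_raster(units, times, 5, 300.0)
        anns = detect_bursts_raster(r)
        nb = detect_network_bursts(anns, min_fraction=1.0)
        assert nb.rate_per_min <= min(a.rate_per_min for a in anns) + 1e-9


class TestUnitFeatures:
    def test_regular_train_zero_fano(self):
        times = np.arange(60) + 0.5
        r = make_raster(np.zeros(60, dtype=int), times, 1, 60.0)
        f = unit_features(r, rate_bin_s=1.0)[0]
        assert f.mfr_hz == pytest.approx(1.0)
        assert f.var_hz2 == pytest.approx(0.0)
        assert f.ff == pytest.approx(0.0)
        assert f.active

    def test_poisson_fano_near_one(self):
        rng = np.random.default_rng(5)
        dur = 600.0
        times = np.sort(rng.uniform(0, dur, rng.poisson(5 * dur)))
        r = make_raster(np.zeros(len(times), dtype=int), times, 1, dur)
        f = unit_features(r, rate_bin_s=1.0)[0]
        se = np.sqrt(2.0 / (dur - 1))  # var of FF estimate for Poisson
        assert abs(f.ff - 1.0) <= 4 * se

    def test_low_rate_unit_flagged_inactive(self):
        times = np.arange(0, 100, 10.5)  # ~0.095 Hz
        r = make_raster(np.zeros(len(times), dtype=int), times, 1, 100.0)
        f = unit_features(r)[0]
        assert not f.active

    def test_silent_unit_ff_undefined(self):
        r = make_raster([0], [1.0], 2, 100.0)
        f = unit_features(r)[1]
        assert np.isnan(f.ff) and not f.active


def test_metrics_invariant_under_unit_permutation():
    rng = np.random.default_rng(6)
    units = rng.integers(0, 12, 600)
    times = np.sort(rng.uniform(0, 120.0, 600))
    r = make_raster(units, times, 12, 120.0)
    perm = rng.permutation(12)
    r2 = make_raster(perm[units], times, 12, 120.0)
    assert mean_firing_rate(r) == pytest.approx(mean_firing_rate(r2))
    _, a1 = afr_trace(r, 10)
    _, a2 = afr_trace(r2, 10)
    assert np.allclose(a1, a2)
    f1 = sorted(round(f.mfr_hz, 9) for f in unit_features(r))
    f2 = sorted(round(f.mfr_hz, 9) for f in unit_features(r2))
    assert f1 == f2
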