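"""Activity maps, ISI machinery, band occupancy and synchrony."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import slicephys as sp
from slicephys.network import (
    band_fraction,
    band_occupancy,
    build_activity_map,
    classify_activity,
    cumulative_isi,
    electrode_subset_analysis,
    high_freq_fraction,
    isi_histogram,
    polarity_stats,
    synchrony_index,
)

from oracles import naive_isi_list


def trains_from_times(times_by_elec, n_electrodes=None, duration=600.0, segments=True):
    n = n_electrodes or (max(times_by_elec) + 1)
    events = [
        sp.SpikeEvent(e, t, -1, -0.05)
        for e, ts in times_by_elec.items()
        for t in ts
    ]
    segs = [(float(i), 1.0) for i in range(int(duration))] if segments else []
    return sp.SpikeTrainSet(
        events=events, n_electrodes=n, total_duration_s=duration,
        sampling_rate_hz=20000.0, segments=segs,
    )


@st.composite
def random_trains(draw):
    n_elec = draw(st.integers(1, 5))
    duration = 20.0
    times = {}
    for e in range(n_elec):
        n_ev = draw(st.integers(0, 30))
        ts = draw(
            st.lists(
                st.floats(0, duration - 1e-6, allow_nan=False),
                min_size=n_ev, max_size=n_ev,
            )
        )
        times[e] = sorted(ts)
    return trains_from_times(times, n_electrodes=n_elec, duration=duration, segments=False)


class TestActivityMap:
    def test_empty_trains_give_zero_map(self):
        trains = trains_from_times({e: [] for e in range(61)}, n_electrodes=61)
        amap = build_activity_map(trains)
        assert amap.counts.shape == (61, 600)
        assert amap.counts.sum() == 0
        assert amap.slice_mean_rate_hz == 0.0
        assert classify_activity(amap) == "low"

    def test_one_event_per_second_is_rate_one(self):
        trains = trains_from_times({0: [i + 0.5 for i in range(600)]}, n_electrodes=1)
        amap = build_activity_map(trains)
        assert amap.per_electrode_rate_hz[0] == pytest.approx(1.0)
        assert np.all(amap.counts[0] == 1)

    def test_slice_mean_is_mean_of_electrode_rates(self):
        trains = trains_from_times({0: [0.5, 1.5], 1: []}, n_electrodes=2, duration=2.0)
        amap = build_activity_map(trains)
        assert amap.slice_mean_rate_hz == pytest.approx(
            amap.per_electrode_rate_hz.mean()
        )

    def test_simulated_rates_recovered_within_3_se(self, cfg):
        rates = np.array([1.0, 2.0, 4.0, 0.5])
        p = sp.SpontaneousSimParams(
            geometry=sp.ArrayGeometry.grid(2, 2, 70.0),
            duration_s=120.0,
            per_electrode_rate_hz=rates,
            sync_fraction=0.0,
            noise_sd_mv=0.0,
            seed=3,
        )
        _, truth = sp.simulate_spontaneous(p)
        amap = build_activity_map(truth)
        for r, got in zip(rates, amap.per_electrode_rate_hz):
            se = np.sqrt(r * 120.0) / 120.0
            assert abs(got - r) <= 3 * se + r * p.refractory_ms * 1e-3


class TestClassifyActivity:
    @pytest.mark.parametrize("rate,expected", [(0.0, "low"), (0.99, "low"), (1.0, "high"), (1.5, "high")])
    def test_boundary_rule_strict_below_one(self, rate, expected):
        trains = trains_from_times({0: []}, n_electrodes=1, duration=1.0)
        amap = build_activity_map(trains)
        amap.slice_mean_rate_hz = rate
        assert classify_activity(amap) == expected

    def test_monotone_in_single_electrode_rate(self):
        lo = trains_from_times({0: [0.5], 1: [0.2]}, n_electrodes=2, duration=2.0)
        hi = trains_from_times({0: [0.5, 1.0, 1.7], 1: [0.2]}, n_electrodes=2, duration=2.0)
        assert (
            build_activity_map(hi).slice_mean_rate_hz
            > build_activity_map(lo).slice_mean_rate_hz
        )


class TestPolarityStats:
    def test_rates_split_by_polarity(self):
        events = [sp.SpikeEvent(0, i * 0.1, 1, 0.04) for i in range(10)]
        events += [sp.SpikeEvent(0, 1.05 + i * 0.1, -1, -0.05) for i in range(30)]
        trains = sp.SpikeTrainSet(events, 1, 10.0, 20000.0)
        st_ = polarity_stats(trains)
        assert st_.pos_rate_hz == pytest.approx(1.0)
        assert st_.neg_rate_hz == pytest.approx(3.0)
        assert st_.overall_rate_hz == pytest.approx(4.0)

    def test_missing_polarity_flagged_with_nan(self):
        events = [sp.SpikeEvent(0, 0.1, 1, 0.04)]
        st_ = polarity_stats(sp.SpikeTrainSet(events, 1, 1.0, 20000.0))
        assert st_.neg_rate_hz == 0.0
        assert np.isnan(st_.neg_amp_mean_mv)

    def test_simulated_amplitudes_recovered_within_3_se(self):
        p = sp.SpontaneousSimParams(
            geometry=sp.ArrayGeometry.grid(2, 2, 70.0),
            duration_s=100.0,
            per_electrode_rate_hz=4.0,
            pos_fraction=0.0,
            neg_amp_mean_mv=0.04,
            neg_amp_sd_mv=0.002,
            sync_fraction=0.0,
            noise_sd_mv=0.0,
            seed=6,
        )
        _, truth = sp.simulate_spontaneous(p)
        st_ = polarity_stats(truth)
        se = 0.002 / np.sqrt(st_.n_neg)
        assert abs(st_.neg_amp_mean_mv - 0.04) <= 3 * se


class TestISIHistogram:
    def test_small_example_lands_in_expected_bins(self):
        trains = trains_from_times({0: [0.0, 0.1, 0.3]}, n_electrodes=1, duration=1.0, segments=False)
        h = isi_histogram(trains, 0.005, 2.0)
        assert h.n_isis == 2
        assert h.counts[20] == 1  # 0.1 s -> bin [0.100, 0.105)
        assert h.counts[40] == 1  # 0.2 s
        assert h.counts.sum() == 2

    def test_isis_above_max_excluded(self):
        trains = trains_from_times({0: [0.0, 3.0]}, n_electrodes=1, duration=4.0, segments=False)
        h = isi_histogram(trains, 0.005, 2.0)
        assert h.n_isis == 0
        with pytest.raises(ValueError):
            cumulative_isi(h)

    def test_isis_never_span_electrodes(self):
        trains = trains_from_times({0: [0.0], 1: [0.05]}, n_electrodes=2, duration=1.0, segments=False)
        assert isi_histogram(trains, 0.005, 2.0).n_isis == 0

    @given(random_trains())
    def test_count_conservation_matches_oracle(self, trains):
        h = isi_histogram(trains, 0.005, 2.0)
        oracle = naive_isi_list(trains.times_by_electrode(), 2.0)
        assert h.counts.sum() == h.n_isis == len(oracle)

    def test_cumulative_shape(self):
        trains = trains_from_times(
            {0: [0.0, 0.001, 0.007, 0.013, 0.0195]}, n_electrodes=1, duration=1.0, segments=False
        )
        h = isi_histogram(trains, 0.005, 0.02)
        c = cumulative_isi(h)
        assert c[-1] == pytest.approx(1.0)
        assert np.all(np.diff(c) >= 0)

    def test_uniform_counts_cumulate_evenly(self):
        h = sp.ISIHistogram(bin_width_s=0.005, max_isi_s=0.02, counts=np.array([1, 1, 1, 1]), n_isis=4)
        assert np.allclose(cumulative_isi(h), [0.25, 0.5, 0.75, 1.0])


class TestBandOccupancy:
    def test_example_fractions(self):
        isis = np.array([0.04, 0.5, 1.0])
        assert high_freq_fraction(isis, 20.0) == pytest.approx(1 / 3)
        assert band_fraction(isis, (0.6, 4.0)) == pytest.approx(2 / 3)

    def test_all_fast_events_fill_high_band(self):
        isis = np.full(10, 0.01)
        assert high_freq_fraction(isis, 20.0) == 1.0

    def test_band_edges(self):
        # ISI exactly 0.05 s is not >20 Hz (strict); 0.25 s is outside the
        # delta mapping (open lower edge), 1/0.6 s is inside (closed upper)
        assert high_freq_fraction(np.array([0.05]), 20.0) == 0.0
        assert band_fraction(np.array([0.25]), (0.6, 4.0)) == 0.0
        assert band_fraction(np.array([1.0 / 0.6]), (0.6, 4.0)) == 1.0

    @given(random_trains())
    def test_partition_sums_to_one(self, trains):
        out = band_occupancy(trains, max_isi_s=2.0)
        if out["n_isis"] == 0:
            assert out["high_fraction"] is None
        else:
            total = out["high_fraction"] + out["delta_fraction"] + out["other_fraction"]
            assert total == pytest.approx(1.0)

    def test_poisson_simulation_matches_enumeration(self):
        rng = np.random.default_rng(8)
        times = np.cumsum(rng.exponential(1 / 2.0, size=400))
        trains = trains_from_times({0: list(times)}, n_electrodes=1,
                                   duration=times[-1] + 1, segments=False)
        out = band_occupancy(trains, max_isi_s=2.0)
        isis = [b - a for a, b in zip(times, times[1:]) if b - a <= 2.0]
        manual_delta = sum(1 for i in isis if 0.25 < i <= 1 / 0.6) / len(isis)
        assert out["delta_fraction"] == pytest.approx(manual_delta)


class TestElectrodeSubset:
    def test_full_subset_equals_full_analysis(self):
        trains = trains_from_times(
            {0: [0.1, 0.4], 1: [0.2]}, n_electrodes=2, duration=2.0, segments=False
        )
        sub = electrode_subset_analysis(trains, [0, 1])
        assert sub["polarity"].overall_rate_hz == polarity_stats(trains).overall_rate_hz
        assert sub["isi_histogram"].n_isis == isi_histogram(trains, 0.001, 2.0).n_isis

    def test_silent_electrode_flagged_empty(self):
        trains = trains_from_times({0: [0.1], 1: []}, n_electrodes=2, duration=1.0, segments=False)
        sub = electrode_subset_analysis(trains, [1])
        assert sub["isi_histogram"].n_isis == 0
        assert sub["bands"]["n_isis"] == 0

    def test_invalid_subset_rejected(self):
        trains = trains_from_times({0: [0.1]}, n_electrodes=1, duration=1.0, segments=False)
        with pytest.raises(ValueError):
            trains.subset([])
        with pytest.raises(IndexError):
            trains.subset([5])


class TestSynchrony:
    def test_fully_synchronous_trains_index_one(self):
        times = {e: [0.1, 0.5, 0.9] for e in range(4)}
        trains = trains_from_times(times, n_electrodes=4, duration=1.0, segments=False)
        res = synchrony_index(trains, window_ms=5.0, k=4)
        assert res.index == 1.0

    def test_empty_trains_flagged(self):
        trains = trains_from_times({0: [], 1: []}, n_electrodes=2, duration=1.0, segments=False)
        res = synchrony_index(trains)
        assert res.index == 0.0 and not res.defined

    def test_relabeling_invariance(self, rng):
        times = {0: sorted(rng.uniform(0, 10, 40)), 1: sorted(rng.uniform(0, 10, 25)),
                 2: sorted(rng.uniform(0, 10, 30))}
        trains = trains_from_times(times, n_electrodes=3, duration=10.0, segments=False)
        permuted = trains_from_times(
            {0: times[2], 1: times[0], 2: times[1]}, n_electrodes=3, duration=10.0, segments=False
        )
        assert synchrony_index(trains, 5.0, 2).index == pytest.approx(
            synchrony_index(permuted, 5.0, 2).index
        )

    def test_independent_trains_near_analytic_chance(self):
        # two independent Poisson electrodes: an event participates iff the
        # other electrode fires within the +/- w/2 window -> 1 - exp(-r*w)
        rate, window, duration = 10.0, 0.005, 400.0
        rng = np.random.default_rng(17)
        times = {
            e: list(np.cumsum(rng.exponential(1 / rate, size=int(rate * duration * 1.2))))
            for e in range(2)
        }
        times = {e: [t for t in ts if t < duration] for e, ts in times.items()}
        trains = trains_from_times(times, n_electrodes=2, duration=duration, segments=False)
        res = synchrony_index(trains, window_ms=window * 1e3, k=2)
        p_chance = 1 - np.exp(-rate * window)
        se = np.sqrt(p_chance * (1 - p_chance) / res.n_events)
        assert abs(res.index - p_chance) <= 4 * se

    def test_monotone_in_simulator_sync_fraction(self):
        indices = []
        for sf in (0.0, 0.5, 1.0):
            p = sp.SpontaneousSimParams(
                geometry=sp.ArrayGeometry.grid(2, 3, 70.0),
                duration_s=60.0,
                per_electrode_rate_hz=3.0,
                sync_fraction=sf,
                sync_jitter_ms=0.5,
                noise_sd_mv=0.0,
                seed=21,
            )
            _, truth = sp.simulate_spontaneous(p)
            indices.append(synchrony_index(truth, window_ms=5.0).index)
        assert indices[0] < indices[1] < indices[2]
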