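"""MEA spike-train metrics: bursts, network bursts, synchrony, evoked, QC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neuroquant import mea, synth
from conftest import brute_force_bursts, brute_force_network_bursts


def make_well(trains, duration=600.0, n_electrodes=16):
    trains = list(trains) + [np.array([])] * (n_electrodes - len(trains))
    return mea.WellRecording(trains=trains, duration=duration)


# ---------------------------------------------------------------------------
# electrode bursts
# ---------------------------------------------------------------------------

class TestBurstDetection:
    def test_minimal_five_spike_burst(self):
        bursts = mea.detect_bursts(np.array([0, 0.05, 0.10, 0.15, 0.20]))
        assert len(bursts) == 1
        b = bursts[0]
        assert (b.start, b.end, b.n_spikes) == (0.0, 0.20, 5)
        assert b.duration == pytest.approx(0.20)

    def test_four_spikes_do_not_burst(self):
        assert mea.detect_bursts(np.array([0, 0.05, 0.10, 0.15])) == []

    def test_isi_exactly_100ms_breaks_run(self):
        # strict "< 100 ms": a run of ISIs at exactly 0.100 never bursts
        times = np.arange(10) * 0.100
        assert mea.detect_bursts(times) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            mea.detect_bursts(np.array([1.0, 0.5]))

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        # mix Poisson background with dense bursty stretches
        t = np.sort(np.concatenate([
            rng.uniform(0, 60, 400),
            rng.uniform(10, 12, 200),  # dense region
        ]))
        got = [(b.start, b.end, b.n_spikes) for b in mea.detect_bursts(t)]
        assert got == pytest.approx(brute_force_bursts(t))

    def test_spikes_belong_to_at_most_one_burst(self, rng):
        t = np.sort(rng.uniform(0, 20, 2000))
        bursts = mea.detect_bursts(t)
        # disjoint and time ordered
        for b1, b2 in zip(bursts[:-1], bursts[1:]):
            assert b1.end < b2.start

    def test_raising_max_isi_never_decreases_burst_count(self, rng):
        t = np.sort(rng.uniform(0, 30, 1500))
        counts = [len(mea.detect_bursts(t, mea.BurstConfig(max_isi=isi)))
                  for isi in (0.02, 0.05, 0.1, 0.2)]
        # total bursted spikes grows; count can merge, so compare spike totals
        spikes = [sum(b.n_spikes
                      for b in mea.detect_bursts(t, mea.BurstConfig(max_isi=isi)))
                  for isi in (0.02, 0.05, 0.1, 0.2)]
        assert spikes == sorted(spikes)
        assert all(c >= 0 for c in counts)

    @given(st.lists(st.floats(min_value=0, max_value=50), min_size=0,
                    max_size=300))
    def test_oracle_equivalence_property(self, raw):
        t = np.sort(np.asarray(raw))
        got = [(b.start, b.end, b.n_spikes) for b in mea.detect_bursts(t)]
        assert got == brute_force_bursts(list(t))


# ---------------------------------------------------------------------------
# network bursts
# ---------------------------------------------------------------------------

class TestNetworkBursts:
    def _interleaved_well(self, n_participating, spikes_each=10, spacing=0.005):
        pooled = spacing * np.arange(n_participating * spikes_each)
        trains = [[] for _ in range(16)]
        for k, t in enumerate(pooled):
            trains[k % n_participating].append(t)
        return make_well([np.array(sorted(tr)) for tr in trains], duration=10)

    def test_six_of_sixteen_participation_accepted(self):
        nbs = mea.detect_network_bursts(self._interleaved_well(6))
        assert len(nbs) == 1
        assert nbs[0].n_spikes == 60
        assert nbs[0].participation == pytest.approx(6 / 16)

    def test_five_of_sixteen_participation_rejected(self):
        assert mea.detect_network_bursts(self._interleaved_well(5)) == []

    def test_spike_count_equals_member_contributions(self):
        well = self._interleaved_well(8)
        nb = mea.detect_network_bursts(well)[0]
        contributed = sum(
            np.sum((tr >= nb.start) & (tr <= nb.end)) for tr in well.trains)
        assert nb.n_spikes == contributed

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_equivalence_random_wells(self, seed):
        rng = np.random.default_rng(100 + seed)
        trains = [np.sort(rng.uniform(0, 30, rng.integers(50, 200)))
                  for _ in range(16)]
        well = make_well(trains, duration=30)
        got = [(nb.start, nb.end, nb.n_spikes, nb.electrodes)
               for nb in mea.detect_network_bursts(well)]
        assert got == pytest.approx(brute_force_network_bursts(trains, 16))


# ---------------------------------------------------------------------------
# synchrony
# ---------------------------------------------------------------------------

class TestSynchrony:
    def test_identical_trains_give_unity(self):
        # spikes farther apart than max_lag: all correlogram mass at lag 0
        t = np.arange(0, 600, 1.5)
        well = make_well([t.copy() for _ in range(4)], duration=600)
        assert mea.synchrony_index(well) == pytest.approx(1.0)

    def test_independent_poisson_reaches_flat_limit(self, rng):
        well = make_well([np.sort(rng.uniform(0, 600, 1200))
                          for _ in range(8)], duration=600)
        idx = mea.synchrony_index(well)
        # flat correlogram: mass in +/-20 ms of +/-500 ms = 0.04
        assert idx == pytest.approx(0.04, abs=0.01)

    def test_jitter_monotonicity(self, rng):
        base = np.sort(rng.uniform(0, 600, 600))
        def jittered(sd):
            a = base
            b = np.sort(base + rng.normal(0, sd, len(base)))
            return mea.synchrony_index(make_well([a, b], duration=600))
        assert jittered(0.005) > jittered(0.050)

    def test_index_bounded(self, rng):
        well = make_well([np.sort(rng.uniform(0, 60, 200)) for _ in range(4)],
                         duration=60)
        assert 0.0 <= mea.synchrony_index(well) <= 1.0

    def test_too_few_active_electrodes_rejected(self):
        well = make_well([np.array([1.0, 2.0])], duration=10)
        with pytest.raises(ValueError):
            mea.synchrony_index(well)


# ---------------------------------------------------------------------------
# spike detection from raw traces
# ---------------------------------------------------------------------------

class TestSpikeDetection:
    def test_recovery_at_high_snr(self, rng):
        true = np.sort(rng.uniform(0.1, 59.9, 50))
        true = true[np.concatenate([[True], np.diff(true) > 0.005])]
        trace = synth.gen_raw_trace(true, fs=12500, duration=60,
                                    spike_amplitude=50, noise_sd=5, seed=7)
        det = mea.detect_spikes(trace)
        recovered = sum(np.min(np.abs(det - t)) < 0.001 for t in true)
        extra = sum(np.min(np.abs(true - t)) > 0.001 for t in det)
        assert recovered >= 0.98 * len(true)
        assert extra == 0

    def test_noiseless_trace_recovers_all_spikes_exactly(self):
        true = np.arange(0.5, 10.0, 0.5)
        trace = synth.gen_raw_trace(true, fs=12500, duration=10.5,
                                    spike_amplitude=50, noise_sd=0.5, seed=1)
        det = mea.detect_spikes(trace)
        assert len(det) == len(true)
        assert np.all([np.min(np.abs(det - t)) < 0.001 for t in true])

    def test_pure_noise_false_positive_rate(self):
        trace = synth.gen_raw_trace([], fs=12500, duration=60,
                                    noise_sd=5, seed=3)
        det = mea.detect_spikes(trace)
        assert len(det) / 60 < 0.1

    def test_all_zero_trace_yields_no_spikes(self):
        assert len(mea.detect_spikes(np.zeros(12500))) == 0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            mea.SpikeDetectConfig(fs=5000.0)


# ---------------------------------------------------------------------------
# evoked metrics, QC, normalization
# ---------------------------------------------------------------------------

class TestEvoked:
    def test_fixed_latency_response(self):
        stims = np.arange(1.0, 11.0)
        trains = [stims + 0.010]
        ev = mea.evoked_metrics(make_well(trains, duration=12), stims)
        assert ev.mean_count[0] == pytest.approx(1.0)
        assert ev.mean_latency[0] == pytest.approx(0.010)
        assert ev.n_responding_stimuli[0] == 10

    def test_no_response_flags_latency_undefined(self):
        stims = np.arange(1.0, 11.0)
        ev = mea.evoked_metrics(make_well([np.array([0.5])], duration=12), stims)
        assert ev.mean_count[0] == 0.0
        assert np.isnan(ev.mean_latency[0])

    def test_poisson_rate_expectation(self, rng):
        train = np.sort(rng.uniform(0, 600, 6000))  # 10 Hz
        stims = np.arange(1.0, 501.0, 5.0)
        ev = mea.evoked_metrics(make_well([train], duration=600), stims)
        assert ev.mean_count[0] == pytest.approx(10 * 0.1, rel=0.2)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            mea.evoked_metrics(make_well([np.array([1.0, 2.0])], duration=10),
                               np.array([1.0, 1.05]))


class TestWellQC:
    def make_rate_well(self, rates_per_min, duration=60.0):
        trains = [np.linspace(0, duration, int(r * duration / 60),
                              endpoint=False) if r else np.array([])
                  for r in rates_per_min]
        return mea.WellRecording(trains=trains, duration=duration)

    def test_all_active_included(self):
        well = self.make_rate_well([60] * 16)  # 1 Hz each
        n, include = mea.well_qc(well)
        assert (n, include) == (16, True)

    def test_exactly_twelve_active_excluded(self):
        well = self.make_rate_well([60] * 12 + [1] * 4)
        n, include = mea.well_qc(well)
        assert (n, include) == (12, False)

    def test_thirteen_active_included(self):
        well = self.make_rate_well([60] * 13 + [1] * 3)
        n, include = mea.well_qc(well)
        assert (n, include) == (13, True)


class TestNormalizeGroup:
    def test_control_mean_becomes_unity(self):
        out = mea.normalize_group([6.0], [2.0, 4.0])
        assert out[0] == pytest.approx(2.0)
        ctrl = mea.normalize_group([2.0, 4.0], [2.0, 4.0])
        assert ctrl.mean() == pytest.approx(1.0)
        assert list(ctrl) == pytest.approx([2 / 3, 4 / 3])

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            mea.normalize_group([1.0], [])


def test_well_metrics_schema(rng):
    cfg = synth.bursty_well_config(120.0, 0.1, seed=5)
    well, _ = synth.gen_spike_well(cfg)
    row = mea.well_metrics(well)
    for key in ("burst_frequency_hz", "network_burst_frequency_hz",
                "synchrony_index", "n_active", "included"):
        assert key in row
    assert row["burst_frequency_hz"] > 0
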