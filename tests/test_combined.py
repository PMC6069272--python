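"""Combined detectors: adaptive AP/LFP detection against ground truth and a
double-precision oracle, burst envelope and spike cleaning, synchronization
windows, smoothed rates, slow-potential extrema, and channel sorting."""

import numpy as np
import pytest
from scipy.signal import lfilter

from meaflow import (
    APDetector,
    BurstDetector,
    ChannelSorter,
    ConfigurationError,
    EventFrequencyMeter,
    LFPDetector,
    PlateauFraction,
    SlowPotentialDetector,
    SortBank,
    SyncDetector,
    SynthSpec,
    generate,
    sort_channels,
)
from meaflow.combined import EpochStats, combine_banks

RATE = 10_000.0
SETTLE = 10_000  # 1 s for the closed-loop sigma estimate to converge


def match_events(detected, truth, tol):
    det = np.asarray(detected)
    tru = np.asarray(truth)
    tp = sum(1 for t in tru if det.size and np.abs(det - t).min() <= tol)
    matched = sum(1 for e in det if tru.size and np.abs(tru - e).min() <= tol)
    return tp, matched


class TestAPDetection:
    def test_zero_input_no_events(self):
        det = APDetector("linear")
        assert det.process([0] * 5000) == []

    def test_recovery_at_snr6(self):
        # 120 LSB biphasic template on 20 LSB Gaussian noise, multiplier 4
        spec = SynthSpec(
            n_channels=1, duration_s=12.0, noise_sigma=20.0,
            ap_amplitude=120.0, ap_rate_hz=10.0, seed=11,
        )
        _, frames, truth = generate(spec)
        det = APDetector("linear", refractory_ticks=30)
        events = [t for t in det.process(frames[:, 0].tolist()) if t >= SETTLE]
        tru = truth.ticks("AP", 0)
        tru = tru[tru >= SETTLE]
        tp, matched = match_events(events, tru, tol=10)
        assert tp / len(tru) >= 0.95
        assert matched / len(events) >= 0.95

    def test_agrees_with_double_precision_oracle(self):
        spec = SynthSpec(
            n_channels=1, duration_s=12.0, noise_sigma=20.0,
            ap_amplitude=120.0, ap_rate_hz=10.0, seed=13,
        )
        _, frames, truth = generate(spec)
        x = frames[:, 0].astype(float)

        # same band-pass (k=[2,4]) in double precision; threshold at 4x the
        # true std of the filtered noise, measured on a noise-only record
        def bandpass(sig):
            y1 = lfilter([1 / 4], [1, -(1 - 1 / 4)], sig)
            y2 = lfilter([1 / 16], [1, -(1 - 1 / 16)], y1)
            return y1 - y2

        noise_only = generate(
            SynthSpec(n_channels=1, duration_s=12.0, noise_sigma=20.0, seed=13)
        )[1][:, 0].astype(float)
        thr = 4.0 * bandpass(noise_only)[SETTLE:].std()
        bp = bandpass(x)
        above = bp >= thr
        edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        oracle, last = [], -(10**9)
        for e in edges:
            if e - last > 30:
                oracle.append(e)
                last = e
        oracle = [e for e in oracle if e >= SETTLE]

        det = APDetector("linear", refractory_ticks=30)
        events = [t for t in det.process(frames[:, 0].tolist()) if t >= SETTLE]
        tp, _ = match_events(events, oracle, tol=2)
        assert tp / len(oracle) >= 0.95

    def test_wavelet_variant_recovers_spikes(self):
        spec = SynthSpec(
            n_channels=1, duration_s=12.0, noise_sigma=20.0,
            ap_amplitude=120.0, ap_rate_hz=10.0, seed=17,
        )
        _, frames, truth = generate(spec)
        det = APDetector("wavelet", refractory_ticks=30)
        events = [t for t in det.process(frames[:, 0].tolist()) if t >= SETTLE]
        tru = truth.ticks("AP", 0)
        tru = tru[tru >= SETTLE]
        tp, _ = match_events(events, tru, tol=10)
        assert tp / len(tru) >= 0.95

    def test_fixed_threshold_variant_is_plain_comparator(self):
        det = APDetector("fixed_threshold", filter_unit=None, fixed_threshold=100)
        xs = [0, 50, 120, 130, 40, 150]
        events = [det.step(x) for x in xs]
        assert events == [False, False, True, False, False, True]


class TestLFPDetection:
    def test_damped_oscillations_detected(self):
        # well-separated 10 Hz damped oscillations, amplitude 10x noise sigma:
        # every episode is detected, and nothing fires between episodes
        rng = np.random.default_rng(3)
        n = 300_000
        x = np.rint(rng.normal(0, 20, n)).astype(float)
        dur = 3000  # 3 cycles of 10 Hz
        t = np.arange(dur) / RATE
        wave = 200.0 * np.exp(-t * 10.0) * np.sin(2 * np.pi * 10.0 * t)
        onsets = np.arange(SETTLE + 2000, n - 2 * dur, 25_000)
        for t0 in onsets:
            x[t0 : t0 + dur] += wave
        det = LFPDetector(refractory_ticks=5000)
        events = [e for e in det.process(np.rint(x).astype(int).tolist()) if e >= SETTLE]
        hits = [
            any(t0 <= e <= t0 + dur // 2 for e in events) for t0 in onsets
        ]
        assert all(hits)
        # no detection outside an episode (tail crossings included)
        for e in events:
            assert any(t0 - 100 <= e <= t0 + 2 * dur for t0 in onsets)

    def test_spike_band_content_rejected(self):
        # filter-attenuation oracle: 1 kHz transients that exceed a fixed
        # comparator threshold in the spike band leave < 10 LSB in the LFP
        # band (second-order upper edge, ~40 dB down two decades up)
        n = 30_000
        x = np.zeros(n)
        for t0 in range(2000, n - 10, 2000):
            x[t0 : t0 + 10] = 300 * np.sin(2 * np.pi * 1000.0 * np.arange(10) / RATE)
        xs = np.rint(x).astype(int).tolist()
        from meaflow.combined import default_ap_filter, default_lfp_filter

        lfp_det = APDetector(
            "fixed_threshold", filter_unit=default_lfp_filter(),
            band="bp", fixed_threshold=50,
        )
        ap_det = APDetector(
            "fixed_threshold", filter_unit=default_ap_filter(),
            band="bp", fixed_threshold=50,
        )
        assert lfp_det.process(xs) == []
        assert len(ap_det.process(xs)) >= 10

    def test_zero_input_no_events(self):
        assert LFPDetector().process([0] * 2000) == []


class TestBurstDetection:
    def test_clean_window_drops_second_event(self):
        b = BurstDetector(clean_window=20)
        out1 = b.step(1)
        out2 = b.step(1)  # 1 tick later: inside the refractory
        assert out1[1] is True and out2[1] is False

    def test_cleaned_stream_min_interval(self):
        rng = np.random.default_rng(8)
        b = BurstDetector(clean_window=20)
        cleaned = [t for t in range(3000) if b.step(int(rng.random() < 0.2))[1]]
        assert min(np.diff(cleaned)) >= 21

    def test_50hz_train_single_contiguous_burst(self):
        # 1 s of 50 Hz firing then 3 s silence: counter (s_u=500, s_d=1,
        # reference 20 Hz) rises during the train only
        n = 40_000
        events = [1 if (t < 10_000 and t % 200 == 0) else 0 for t in range(n)]
        b = BurstDetector()
        level = [b.step(e)[0] for e in range(0)]  # noqa: F841 (clarity)
        level = [b.step(e)[0] for e in events]
        rises = [t for t in range(1, n) if level[t] and not level[t - 1]]
        falls = [t for t in range(1, n) if not level[t] and level[t - 1]]
        assert len(rises) == 1 and len(falls) == 1
        assert rises[0] < 10_000 < falls[0]  # covers the train, ends after

    def test_sparse_firing_never_bursts(self):
        # 0.5 Hz: count decays to zero long before the next event
        n = 60_000
        b = BurstDetector()
        level = [b.step(1 if t % 20_000 == 0 else 0)[0] for t in range(n)]
        assert not any(level)


class TestSyncDetection:
    def fig15_detector(self):
        # more than four APs across six selected channels in a 25 ms window
        return SyncDetector.window_rule([True] * 6, min_events=4, window_ticks=250)

    def test_five_simultaneous_aps_fire(self):
        det = self.fig15_detector()
        assert det.step([True] * 5 + [False]) is True
        assert set(det.last_contributors) == {0, 1, 2, 3, 4}

    def test_four_spread_aps_do_not_fire(self):
        det = self.fig15_detector()
        fired = []
        for t in range(1000):
            flags = [False] * 6
            if t in (0, 333, 666, 999):
                flags[t % 6] = True
            fired.append(det.step(flags))
        assert not any(fired)

    def test_five_aps_within_window_fire(self):
        det = self.fig15_detector()
        fired = []
        for t in range(300):
            flags = [False] * 6
            if t in (0, 10, 20, 30, 40):
                flags[t % 6] = True
            fired.append(det.step(flags))
        assert any(fired)

    def test_silence_never_fires(self):
        det = self.fig15_detector()
        assert not any(det.step([False] * 6) for _ in range(1000))

    def test_single_event_threshold(self):
        from meaflow import LeakyCounter

        det = SyncDetector([True] * 3, LeakyCounter(s_u=1, s_d=0, q=1))
        assert det.step([False, True, False]) is True
        assert det.last_contributors == (1,)


class TestRateMeters:
    def test_no_events_zero_hz(self):
        m = EventFrequencyMeter(RATE, k=10)
        assert all(m.step(0) == 0.0 for _ in range(5000))

    def test_periodic_events_converge_to_true_rate(self):
        # one event every 100 ticks at 10 kHz = 100 Hz; k=10 -> tau 0.1 s
        m = EventFrequencyMeter(RATE, k=10)
        out = [m.step(1 if t % 100 == 0 else 0) for t in range(60_000)]
        avg = np.mean(out[-10_000:])
        assert avg == pytest.approx(100.0, rel=0.05)

    def test_bernoulli_events_match_realized_rate(self):
        rng = np.random.default_rng(21)
        n = 300_000
        events = (rng.random(n) < 0.001).astype(int)
        m = EventFrequencyMeter(RATE, k=13, order=2)
        out = [m.step(int(e)) for e in events]
        realized = events[n // 2 :].sum() / (n // 2) * RATE
        avg = np.mean(out[n // 2 :])
        assert avg == pytest.approx(realized, rel=0.10)
        assert realized == pytest.approx(10.0, rel=0.25)

    def test_fopp_extremes(self):
        f = PlateauFraction(k=10)
        for _ in range(30_000):
            hi = f.step(1)
        assert hi == pytest.approx(1.0, abs=0.01)
        f2 = PlateauFraction(k=10)
        assert all(f2.step(0) == 0.0 for _ in range(1000))

    def test_fopp_duty_cycle(self):
        # 30% duty square envelope with period << time constant
        f = PlateauFraction(k=13)
        out = [f.step(1 if (t % 1000) < 300 else 0) for t in range(150_000)]
        assert np.mean(out[-30_000:]) == pytest.approx(0.30, abs=0.02)


class TestSlowPotentialDetection:
    def sine(self, freq, amp, dur):
        t = np.arange(int(dur * RATE)) / RATE
        return np.rint(amp * np.sin(2 * np.pi * freq * t)).astype(int).tolist()

    def test_one_event_per_cycle(self):
        # 1 Hz, filtered peak-to-peak ~10 delta: exactly one max per cycle
        delta = 150
        det = SlowPotentialDetector(delta=delta)
        xs = self.sine(1.0, 1200, 25.0)
        events = [t for t, x in enumerate(xs) if det.step(x)]
        interior = [t for t in events if t >= 5 * RATE]
        assert len(interior) == 20

    def test_subthreshold_ripple_ignored(self):
        det = SlowPotentialDetector(delta=1000)
        xs = self.sine(1.0, 300, 10.0)  # filtered p2p < delta
        assert [t for t, x in enumerate(xs) if det.step(x)] == []

    def test_ap_train_does_not_perturb_count(self):
        delta = 150
        xs = np.array(self.sine(1.0, 1200, 25.0))
        with_aps = xs.copy()
        for t0 in range(0, len(xs) - 10, 1000):  # 1 kHz-content transients
            with_aps[t0 : t0 + 10] += np.rint(
                400 * np.sin(2 * np.pi * 1000.0 * np.arange(10) / RATE)
            ).astype(int)
        d1 = SlowPotentialDetector(delta=delta)
        d2 = SlowPotentialDetector(delta=delta)
        n1 = sum(d1.step(int(x)) for x in xs)
        n2 = sum(d2.step(int(x)) for x in with_aps)
        assert n1 == n2

    def test_min_polarity_configurable(self):
        det = SlowPotentialDetector(delta=150, polarity="min")
        xs = self.sine(1.0, 1200, 12.0)
        events = [t for t, x in enumerate(xs) if det.step(x)]
        assert len(events) >= 9


class TestChannelSorting:
    def stats(self):
        s = EpochStats(8)
        s.max_abs = [10, 300, 20, 500, 40, 700, 60, 900]
        s.event_counts = {"AP": [0, 5, 10, 15, 20, 25, 30, 35]}
        s.sync_flagged = [False, False, True, False, False, True, False, False]
        return s

    def banks(self):
        return [
            SortBank("amplitude_exceeds", threshold=250),
            SortBank("event_count_exceeds", threshold=6, event_type="AP"),
            SortBank("synchronization_flagged"),
            SortBank("amplitude_exceeds", threshold=10**6),
        ]

    def test_tautology_selects_all(self):
        res = sort_channels(self.banks(), "b1 or not b1", self.stats())
        assert res.final == [True] * 8

    def test_event_count_threshold(self):
        res = sort_channels(self.banks(), "b2", self.stats())
        assert res.final == [c > 6 for c in self.stats().event_counts["AP"]]

    def test_sync_flag_bank(self):
        res = sort_channels(self.banks(), "b3", self.stats())
        assert res.final == self.stats().sync_flagged

    def test_combined_expression(self):
        res = sort_channels(self.banks(), "(b1 and b2) or b3", self.stats())
        want = [
            (a > 250 and c > 6) or s
            for a, c, s in zip(
                self.stats().max_abs,
                self.stats().event_counts["AP"],
                self.stats().sync_flagged,
            )
        ]
        assert res.final == want

    def test_malformed_expression_rejected(self):
        with pytest.raises(ConfigurationError):
            combine_banks("b1 +", [[True]] * 4)
        with pytest.raises(ConfigurationError):
            combine_banks("b9", [[True]] * 4)
        with pytest.raises(ConfigurationError):
            combine_banks("__import__('os')", [[True]] * 4)

    def test_result_latched_until_epoch_end(self):
        sorter = ChannelSorter(2, self.banks()[:3] + [SortBank("amplitude_exceeds")],
                               "b1", epoch_ticks=100)
        first = None
        for t in range(150):
            res = sorter.observe(raw_values=[1000, 0])
            if t < 99:
                assert res.epoch == -1 and res.final == [False, False]
            elif first is None:
                first = res
        assert first.final == [True, False]
        # mid-epoch statistics do not leak into the latched result
        assert sorter.result.epoch == 0
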