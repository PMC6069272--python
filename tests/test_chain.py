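"""Chain assembly, execution semantics (determinism, causality), and
runtime parameter updates at tick boundaries."""

import copy

import numpy as np
import pytest

from meaflow import (
    Chain,
    ChainConfig,
    ConfigurationError,
    DataError,
    ParameterError,
    UnitDescriptor,
    build_chain,
)


def cfg(units, taps=None, n=2, rate=10_000.0):
    return ChainConfig(n_channels=n, sample_rate_hz=rate, units=units, taps=taps or [])


def lowpass_cfg(n=2):
    return cfg(
        [UnitDescriptor("lp", "lowpass_chain", {"k_list": [3]}, ["input"])],
        taps=["lp.lp"],
        n=n,
    )


class TestBuild:
    def test_minimal_chain_builds_with_zero_state(self):
        chain = build_chain(lowpass_cfg())
        unit = chain.units["lp"]
        assert all(core.stages[0].acc == 0 for core in unit.cores)
        assert chain.order == ["lp"]

    def test_missing_reference_rejected(self):
        with pytest.raises(ConfigurationError, match="missing unit"):
            build_chain(
                cfg([UnitDescriptor("a", "hysteresis", {"t_set": 1}, ["ghost"])])
            )

    def test_cycle_rejected(self):
        with pytest.raises(ConfigurationError, match="cycle"):
            build_chain(
                cfg(
                    [
                        UnitDescriptor("a", "hysteresis", {"t_set": 1}, ["b.level"]),
                        UnitDescriptor("b", "hysteresis", {"t_set": 1}, ["a.level"]),
                    ]
                )
            )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown unit kind"):
            build_chain(cfg([UnitDescriptor("a", "warp_drive", {}, ["input"])]))

    def test_unknown_port_rejected(self):
        with pytest.raises(ConfigurationError, match="no output port"):
            build_chain(
                cfg(
                    [
                        UnitDescriptor("lp", "lowpass_chain", {"k_list": [2]}, ["input"]),
                        UnitDescriptor("h", "hysteresis", {"t_set": 1}, ["lp.zap"]),
                    ]
                )
            )

    def test_spiking_architecture_on_60_channels(self):
        # filters -> AP/LFP/burst detectors -> recording taps
        config = cfg(
            [
                UnitDescriptor("bp", "filter_unit", {"k_list": [2, 4], "lp_tap": 1, "hp_tap": 2}, ["input"]),
                UnitDescriptor("ap", "ap_detect", {"multiplier": 4.0}, ["input"]),
                UnitDescriptor("lfp", "lfp_detect", {}, ["input"]),
                UnitDescriptor("burst", "burst_detect", {"clean_window": 20}, ["ap.event"]),
            ],
            taps=["bp.bp", "ap.event", "lfp.event", "burst.level"],
            n=60,
        )
        chain = build_chain(config)
        out = chain.step([0] * 60)
        assert set(out) == {"bp.bp", "ap.event", "lfp.event", "burst.level"}
        assert all(len(v) == 60 for v in out.values())


class TestFullUnitLibraryWiring:
    def test_feature_extraction_chain_runs(self):
        # every remaining unit kind wired into one chain: sigma, counter,
        # extrema, averager, sync, rate meters, SP detection and sorting
        config = cfg(
            [
                UnitDescriptor("ap", "ap_detect", {}, ["input"]),
                UnitDescriptor("sg", "sigma", {}, ["input"]),
                UnitDescriptor("hy", "hysteresis", {"t_set": 100, "t_clear": 50}, ["input"]),
                UnitDescriptor("ct", "leaky_counter", {"s_u": 1, "q": 3}, ["ap.event"]),
                UnitDescriptor("ex", "extrema", {"delta": 50}, ["input"]),
                UnitDescriptor("av", "spatial_avg", {"selection": [0, 1, 2]}, ["input"]),
                UnitDescriptor("sy", "sync_detect", {"min_events": 2, "window_ticks": 100}, ["ap.event"]),
                UnitDescriptor("fr", "event_freq", {"k": 8}, ["ap.event"]),
                UnitDescriptor("bu", "burst_detect", {}, ["ap.event"]),
                UnitDescriptor("fp", "fopp", {"k": 8}, ["bu.level"]),
                UnitDescriptor("sp", "sp_detect", {"delta": 100}, ["input"]),
                UnitDescriptor(
                    "so", "sorter",
                    {
                        "banks": [
                            {"criterion": "amplitude_exceeds", "threshold": 100},
                            {"criterion": "event_count_exceeds", "threshold": 0, "event_type": "AP"},
                            {"criterion": "synchronization_flagged"},
                            {"criterion": "amplitude_exceeds", "threshold": 10**6},
                        ],
                        "logic": "b1 or b2 or b3",
                        "event_types": ["AP"],
                        "has_raw": True,
                        "has_sync": True,
                        "epoch_ticks": 50,
                    },
                    ["input", "ap.event", "sy.contributors"],
                ),
            ],
            n=4,
        )
        chain = build_chain(config)
        rng = np.random.default_rng(6)
        frames = rng.integers(-500, 500, size=(120, 4)).tolist()
        outs = chain.run(frames)
        last = outs[-1]
        assert len(last["av.out"]) == 1
        assert len(last["so.selected"]) == 4
        assert isinstance(last["fr.hz"][0], float)
        assert isinstance(last["fp.fraction"][0], float)
        # sorter latched a result at the first 50-tick epoch boundary
        assert chain.units["so"].core.epoch >= 2


class TestExecution:
    def test_zero_input_propagates_zeros(self):
        config = cfg(
            [
                UnitDescriptor("f", "filter_unit", {"k_list": [2, 5], "lp_tap": 1, "hp_tap": 2}, ["input"]),
                UnitDescriptor("w", "swt", {"levels": 3}, ["input"]),
            ],
            taps=["f.lp", "f.hp", "f.bp", "w.d1", "w.a3"],
        )
        chain = build_chain(config)
        for _ in range(50):
            out = chain.step([0, 0])
            assert all(v == [0, 0] for v in out.values())

    def test_frame_length_mismatch_raises(self):
        chain = build_chain(lowpass_cfg(n=3))
        with pytest.raises(DataError):
            chain.step([1, 2])

    def test_replay_determinism(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(-2000, 2000, size=(2000, 2)).tolist()
        runs = []
        for _ in range(2):
            chain = build_chain(
                cfg(
                    [
                        UnitDescriptor("ap", "ap_detect", {}, ["input"]),
                        UnitDescriptor("s", "sigma", {}, ["input"]),
                    ],
                    taps=["ap.event", "s.sigma"],
                )
            )
            runs.append(chain.run(frames))
        assert runs[0] == runs[1]

    def test_numpy_int16_frames_match_python_ints(self):
        # frames straight off a raw recording are int16 numpy rows; the
        # chain must not let fixed-width scalars wrap in shift arithmetic
        rng = np.random.default_rng(15)
        arr = rng.integers(-30000, 30000, size=(300, 2)).astype(np.int16)
        config = cfg(
            [UnitDescriptor("f", "filter_unit", {"k_list": [3], "lp_tap": 1}, ["input"])],
            taps=["f.lp"],
        )
        out_np = build_chain(config).run(list(arr))
        out_py = build_chain(config).run(arr.tolist())
        assert out_np == out_py

    def test_causality_prefix_invariance(self):
        rng = np.random.default_rng(1)
        frames = rng.integers(-5000, 5000, size=(400, 1)).tolist()
        altered = [list(f) for f in frames]
        for f in altered[200:]:
            f[0] = -f[0]
        config = cfg(
            [UnitDescriptor("f", "filter_unit", {"k_list": [3], "lp_tap": 1}, ["input"])],
            taps=["f.lp"],
            n=1,
        )
        out_full = build_chain(config).run(frames)
        out_altered = build_chain(config).run(altered)
        assert out_full[:200] == out_altered[:200]


class TestParameterUpdates:
    def test_update_applies_at_next_tick_boundary(self):
        def run(frames, update_at=None):
            chain = build_chain(
                cfg(
                    [UnitDescriptor("h", "hysteresis", {"t_set": 50, "t_clear": 50}, ["input"])],
                    taps=["h.level"],
                    n=1,
                )
            )
            out = []
            for i, f in enumerate(frames):
                if update_at is not None and i == update_at:
                    chain.update_param("h", "t_set", 80)
                    chain.update_param("h", "t_clear", 80)
                out.append(chain.step(f))
            return out

        frames = [[60]] * 20
        mid = run(frames, update_at=10)
        assert [o["h.level"][0] for o in mid[:10]] == [True] * 10
        assert [o["h.level"][0] for o in mid[10:]] == [False] * 10

    def test_two_half_runs_equal_one_with_update(self):
        rng = np.random.default_rng(4)
        xs = rng.integers(-100, 100, 300).tolist()
        # reference: two comparators run back to back over the halves
        from meaflow import HysteresisComparator

        ref = []
        h1 = HysteresisComparator(40, 20)
        for x in xs[:150]:
            ref.append(h1.step(x)[0])
        h2 = HysteresisComparator(70, 10)
        h2.level = h1.level
        for x in xs[150:]:
            ref.append(h2.step(x)[0])

        chain = build_chain(
            cfg(
                [UnitDescriptor("h", "hysteresis", {"t_set": 40, "t_clear": 20}, ["input"])],
                taps=["h.level"],
                n=1,
            )
        )
        got = []
        for i, x in enumerate(xs):
            if i == 150:
                chain.update_param("h", "t_set", 70)
                chain.update_param("h", "t_clear", 10)
            got.append(chain.step([x])["h.level"][0])
        assert got == ref

    def test_static_parameter_rejected(self):
        chain = build_chain(lowpass_cfg())
        with pytest.raises(ParameterError, match="static"):
            chain.update_param("lp", "n_channels", 4)

    def test_out_of_range_value_clamped_with_warning(self):
        chain = build_chain(lowpass_cfg())
        with pytest.warns(UserWarning):
            assert chain.update_param("lp", "k0", 99) == 17

    def test_multiplier_update_leaves_filter_state_untouched(self):
        rng = np.random.default_rng(9)
        xs = rng.integers(-500, 500, size=(100, 1)).tolist()
        chain = build_chain(
            cfg([UnitDescriptor("ap", "ap_detect", {}, ["input"])], taps=["ap.event"], n=1)
        )
        for x in xs[:50]:
            chain.step(x)
        state_before = copy.deepcopy(chain.units["ap"].cores[0].filter_unit)
        chain.update_param("ap", "multiplier", 6.0)
        chain.step(xs[50])
        after = chain.units["ap"].cores[0].filter_unit
        # one more input has been absorbed; replay it on the snapshot
        state_before.step(xs[50][0])
        assert [s.acc for s in after.stages] == [s.acc for s in state_before.stages]
        assert chain.units["ap"].cores[0].multiplier_q == 6 * 256

    def test_update_log_records_applied_tick(self, tmp_path):
        from meaflow import write_param_log

        chain = build_chain(lowpass_cfg())
        chain.step([0, 0])
        chain.update_param("lp", "k0", 5)
        chain.step([0, 0])
        assert chain.param_log == [(1, "lp", "k0", 5)]
        log = tmp_path / "params.csv"
        assert write_param_log(log, chain.param_log) == 1
        assert log.read_text().splitlines() == ["tick,unit,param,value", "1,lp,k0,5"]
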