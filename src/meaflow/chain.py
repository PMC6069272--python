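"""Chain assembly and sample-synchronous execution.

A processing chain is a DAG of processing units declared in a
:class:`ChainConfig`.  Every unit advances exactly once per *tick* (one
sample period) in fixed topological order, so two runs over the same input
with the same configuration produce bit-identical outputs.  Units expose

* *static* parameters, fixed when the chain is built (channel count, data
  width, filter order, wavelet levels, ...), and
* *dynamic* parameters, updatable while the chain runs.  Updates are queued
  by :meth:`Chain.update_param` and applied atomically at the next tick
  boundary, never mid-tick, so no unit ever observes a half-applied value.
  Values are quantized to the parameter's fixed-point grid and clamped to
  its documented range (with a warning), and every applied update is
  recorded in :attr:`Chain.param_log`.

Wiring strings reference a unit's default output as ``"unitid"``, a named
port as ``"unitid.port"``, and the raw input frame as ``"input"``.
"""

from __future__ import annotations

import graphlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

from . import combined as cmb
from .control import BLANKING_MAX_MS, BLANKING_STEP_MS, Blanker, TriggerRouter
from .detectors import (
    AvgPlan,
    ExtremaDetector,
    HysteresisComparator,
    LeakyCounter,
    SigmaEstimator,
)
from .errors import ConfigurationError, DataError, ParameterError
from .filters import FilterUnit, StationaryWaveletTransform
from .frames import DEFAULT_WIDTH, SampleFrame

INPUT_TAG = "input"


# --------------------------------------------------------------------------
# Configuration


@dataclass
class UnitDescriptor:
    """Declarative description of one unit: its kind, parameters, wiring."""

    unit_id: str
    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)


@dataclass
class ChainConfig:
    """Complete chain description.

    ``taps`` lists the ``"unit.port"`` (or ``"unit"``) streams exposed in the
    tick outputs; an empty list exposes every port of every unit.
    """

    n_channels: int
    sample_rate_hz: float
    units: list[UnitDescriptor] = field(default_factory=list)
    taps: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "channels": self.n_channels,
            "rate_hz": self.sample_rate_hz,
            "units": [
                {
                    "id": u.unit_id,
                    "kind": u.kind,
                    "params": dict(u.params),
                    "inputs": list(u.inputs),
                }
                for u in self.units
            ],
            "taps": list(self.taps),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ChainConfig":
        try:
            units = [
                UnitDescriptor(
                    unit_id=u["id"],
                    kind=u["kind"],
                    params=dict(u.get("params", {})),
                    inputs=list(u.get("inputs", [INPUT_TAG])),
                )
                for u in data.get("units", [])
            ]
            return cls(
                n_channels=int(data["channels"]),
                sample_rate_hz=float(data["rate_hz"]),
                units=units,
                taps=list(data.get("taps", [])),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid chain config: {exc}") from exc


# --------------------------------------------------------------------------
# Dynamic parameters


@dataclass(frozen=True)
class ParamSpec:
    """Range and fixed-point grid of one dynamic parameter."""

    lo: float
    hi: float
    quantum: float = 1.0
    integer: bool = True

    def quantize(self, value: float, name: str) -> int | float:
        q = round(value / self.quantum) * self.quantum
        q = min(max(q, self.lo), self.hi)
        if self.integer:
            q = int(round(q))
        if not math.isclose(q, value, rel_tol=0.0, abs_tol=self.quantum * 1e-9):
            warnings.warn(
                f"parameter {name}={value!r} quantized/clamped to {q!r}",
                stacklevel=3,
            )
        return q


_POS_INT = ParamSpec(1, 2**31)
_NONNEG_INT = ParamSpec(0, 2**31)
_SAMPLE = ParamSpec(-(2**15), 2**15 - 1)
_K_RANGE = ParamSpec(0, 17)


class ChainUnit:
    """Executable unit inside a chain.  Subclasses define ``ports`` (output
    names, first is the default), ``dynamic`` (name -> ParamSpec), and
    per-tick behaviour in :meth:`step`."""

    kind: str = ""
    ports: tuple[str, ...] = ("out",)
    #: all units in the sample-rate model are combinational within a tick
    group_delay_ticks: int = 0

    def __init__(self) -> None:
        self.dynamic: dict[str, ParamSpec] = {}

    def check_param(self, name: str, value: Any) -> Any:
        spec = self.dynamic.get(name)
        if spec is None:
            raise ParameterError(
                f"{name!r} is not a dynamic parameter of {self.kind} "
                "(static parameters cannot change at runtime)"
            )
        return spec.quantize(value, name)

    def apply_param(self, name: str, value: Any) -> None:
        raise ParameterError(f"{self.kind} has no dynamic parameters")

    def step(self, tick: int, inputs: list[list]) -> dict[str, list]:
        raise NotImplementedError


class _PerChannel(ChainUnit):
    """Replicates a scalar core across channels."""

    def __init__(self, cores: Sequence[Any]):
        super().__init__()
        self.cores = list(cores)

    @property
    def n_channels(self) -> int:
        return len(self.cores)


class FilterChainUnit(_PerChannel):
    ports = ("lp", "hp", "bp")

    def __init__(self, kind: str, cores: Sequence[FilterUnit]):
        super().__init__(cores)
        self.kind = kind
        for i in range(len(cores[0].stages)):
            self.dynamic[f"k{i}"] = _K_RANGE

    def apply_param(self, name: str, value: int) -> None:
        idx = int(name[1:])
        for core in self.cores:
            core.set_stage_k(idx, value)

    def step(self, tick, inputs):
        lp, hp, bp = [], [], []
        for core, x in zip(self.cores, inputs[0]):
            l, h, b = core.step(x)
            lp.append(l)
            hp.append(h)
            bp.append(b)
        return {"lp": lp, "hp": hp, "bp": bp}


class SWTUnit(_PerChannel):
    kind = "swt"

    def __init__(self, cores: Sequence[StationaryWaveletTransform]):
        super().__init__(cores)
        levels = cores[0].levels
        self.ports = tuple(f"d{j}" for j in range(1, levels + 1)) + (f"a{levels}",)

    def step(self, tick, inputs):
        levels = self.cores[0].levels
        out: dict[str, list] = {p: [] for p in self.ports}
        for core, x in zip(self.cores, inputs[0]):
            d, a = core.step(x)
            for j in range(levels):
                out[f"d{j + 1}"].append(d[j])
            out[f"a{levels}"].append(a)
        return out


class SigmaUnit(_PerChannel):
    kind = "sigma"
    ports = ("sigma",)

    def __init__(self, cores: Sequence[SigmaEstimator]):
        super().__init__(cores)
        self.dynamic = {
            "s_up": _POS_INT,
            "s_dn": _POS_INT,
            "floor": _NONNEG_INT,
        }

    def apply_param(self, name, value):
        for core in self.cores:
            if name == "floor":
                core.floor_raw = value << core.fraction_bits
            else:
                setattr(core, name, value)

    def step(self, tick, inputs):
        out = []
        for core, x in zip(self.cores, inputs[0]):
            raw = core.step(x)
            out.append(raw >> core.fraction_bits)
        return {"sigma": out}


class HysteresisUnit(_PerChannel):
    kind = "hysteresis"
    ports = ("level", "event")

    def __init__(self, cores: Sequence[HysteresisComparator]):
        super().__init__(cores)
        self.dynamic = {"t_set": _SAMPLE, "t_clear": _SAMPLE}

    def apply_param(self, name, value):
        for core in self.cores:
            setattr(core, name, value)
            if core.t_set < core.t_clear:
                raise ParameterError("update would leave t_set < t_clear")

    def step(self, tick, inputs):
        levels, events = [], []
        for core, x in zip(self.cores, inputs[0]):
            lvl, ev = core.step(x)
            levels.append(lvl)
            events.append(ev)
        return {"level": levels, "event": events}


class CounterUnit(_PerChannel):
    kind = "leaky_counter"
    ports = ("count", "event")

    def __init__(self, cores: Sequence[LeakyCounter]):
        super().__init__(cores)
        self.dynamic = {"s_u": _POS_INT, "s_d": _NONNEG_INT, "q": _POS_INT}

    def apply_param(self, name, value):
        for core in self.cores:
            setattr(core, name, value)

    def step(self, tick, inputs):
        counts, events = [], []
        for core, x in zip(self.cores, inputs[0]):
            c, ev = core.step(1 if x else 0)
            counts.append(c)
            events.append(ev)
        return {"count": counts, "event": events}


class ExtremaUnit(_PerChannel):
    kind = "extrema"
    ports = ("max", "min")

    def __init__(self, cores: Sequence[ExtremaDetector]):
        super().__init__(cores)
        self.dynamic = {"delta": _POS_INT}

    def apply_param(self, name, value):
        for core in self.cores:
            core.delta = value

    def step(self, tick, inputs):
        maxima, minima = [], []
        for core, x in zip(self.cores, inputs[0]):
            mx, mn = core.step(x)
            maxima.append(mx)
            minima.append(mn)
        return {"max": maxima, "min": minima}


class SpatialAvgUnit(ChainUnit):
    kind = "spatial_avg"
    ports = ("out",)

    def __init__(self, selection: Sequence[int], n_channels: int, width: int):
        super().__init__()
        sel = [int(c) for c in selection]
        if not sel:
            raise ConfigurationError("spatial_avg selection must not be empty")
        if any(not 0 <= c < n_channels for c in sel):
            raise ConfigurationError("spatial_avg selection outside channel range")
        self.n_channels = n_channels
        self.width = width
        self.selection = sel
        self.plan = AvgPlan(len(sel), width)
        self.dynamic = {"selection": ParamSpec(0, n_channels - 1)}

    def check_param(self, name, value):
        if name != "selection":
            return super().check_param(name, value)
        sel = [int(c) for c in value]
        if not sel or any(not 0 <= c < self.n_channels for c in sel):
            raise ParameterError("selection must be non-empty channel indices")
        return sel

    def apply_param(self, name, value):
        self.selection = value
        self.plan = AvgPlan(len(value), self.width)

    def step(self, tick, inputs):
        total = sum(inputs[0][c] for c in self.selection)
        return {"out": [self.plan.average(total)]}


class APDetectUnit(_PerChannel):
    ports = ("event",)

    def __init__(self, kind: str, cores: Sequence[cmb.APDetector]):
        super().__init__(cores)
        self.kind = kind
        self.dynamic = {
            "multiplier": ParamSpec(1 / 256, 256, quantum=1 / 256, integer=False),
            "s_up": _POS_INT,
            "s_dn": _POS_INT,
        }

    def apply_param(self, name, value):
        for core in self.cores:
            if name == "multiplier":
                core.set_multiplier(value)
            else:
                setattr(core.sigma, name, value)

    def step(self, tick, inputs):
        return {"event": [core.step(x) for core, x in zip(self.cores, inputs[0])]}


class BurstDetectUnit(_PerChannel):
    kind = "burst_detect"
    ports = ("level", "cleaned", "start", "end")

    def __init__(self, cores: Sequence[cmb.BurstDetector]):
        super().__init__(cores)
        self.dynamic = {
            "clean_window": _NONNEG_INT,
            "t_set": ParamSpec(0, 2**31),
            "t_clear": ParamSpec(0, 2**31),
            "s_u": _POS_INT,
            "s_d": _NONNEG_INT,
        }

    def apply_param(self, name, value):
        for core in self.cores:
            if name == "clean_window":
                core.clean_window = value
            elif name in ("t_set", "t_clear"):
                setattr(core.hysteresis, name, value)
            else:
                setattr(core.counter, name, value)

    def step(self, tick, inputs):
        out: dict[str, list] = {p: [] for p in self.ports}
        for core, ev in zip(self.cores, inputs[0]):
            level, cleaned, start, end = core.step(1 if ev else 0)
            out["level"].append(level)
            out["cleaned"].append(cleaned)
            out["start"].append(start)
            out["end"].append(end)
        return out


class SyncDetectUnit(ChainUnit):
    kind = "sync_detect"
    ports = ("event", "contributors")

    def __init__(self, core: cmb.SyncDetector):
        super().__init__()
        self.core = core
        self.dynamic = {"s_u": _POS_INT, "s_d": _NONNEG_INT, "q": _POS_INT}

    def apply_param(self, name, value):
        setattr(self.core.counter, name, value)

    def step(self, tick, inputs):
        fired = self.core.step(inputs[0])
        n = len(self.core.channel_mask)
        contrib = [False] * n
        if fired:
            for ch in self.core.last_contributors:
                contrib[ch] = True
        return {"event": [fired], "contributors": contrib}


class EventFreqUnit(_PerChannel):
    kind = "event_freq"
    ports = ("hz",)

    def __init__(self, cores: Sequence[cmb.EventFrequencyMeter]):
        super().__init__(cores)
        self.dynamic = {"k": _K_RANGE}

    def apply_param(self, name, value):
        for core in self.cores:
            for stage in core.stages:
                stage.k = value

    def step(self, tick, inputs):
        return {"hz": [core.step(1 if e else 0) for core, e in zip(self.cores, inputs[0])]}


class FoppUnit(_PerChannel):
    kind = "fopp"
    ports = ("fraction",)

    def __init__(self, cores: Sequence[cmb.PlateauFraction]):
        super().__init__(cores)
        self.dynamic = {"k": _K_RANGE}

    def apply_param(self, name, value):
        for core in self.cores:
            for stage in core.stages:
                stage.k = value

    def step(self, tick, inputs):
        return {
            "fraction": [core.step(1 if e else 0) for core, e in zip(self.cores, inputs[0])]
        }


class SPDetectUnit(_PerChannel):
    kind = "sp_detect"
    ports = ("event",)

    def __init__(self, cores: Sequence[cmb.SlowPotentialDetector]):
        super().__init__(cores)
        self.dynamic = {
            "delta": _POS_INT,
            "min_amplitude": _NONNEG_INT,
            "refractory_ticks": _NONNEG_INT,
        }

    def apply_param(self, name, value):
        for core in self.cores:
            if name == "delta":
                core.extrema.delta = value
            else:
                setattr(core, name, value)

    def step(self, tick, inputs):
        return {"event": [core.step(x) for core, x in zip(self.cores, inputs[0])]}


class SorterUnit(ChainUnit):
    kind = "sorter"
    ports = ("selected",)

    def __init__(
        self,
        core: cmb.ChannelSorter,
        event_types: Sequence[str],
        has_raw: bool,
        has_sync: bool,
    ):
        super().__init__()
        self.core = core
        self.event_types = list(event_types)
        self.has_raw = has_raw
        self.has_sync = has_sync
        self.dynamic = {"epoch_ticks": _POS_INT}

    def apply_param(self, name, value):
        self.core.epoch_ticks = value

    def step(self, tick, inputs):
        idx = 0
        raw = None
        if self.has_raw:
            raw = inputs[idx]
            idx += 1
        events = {}
        for etype in self.event_types:
            events[etype] = inputs[idx]
            idx += 1
        contributors = None
        if self.has_sync:
            contributors = [ch for ch, f in enumerate(inputs[idx]) if f]
        result = self.core.observe(raw, events, contributors)
        return {"selected": list(result.final)}


class RouterUnit(ChainUnit):
    kind = "router"
    ports = ("triggers",)

    def __init__(self, core: TriggerRouter, input_names: Sequence[str]):
        super().__init__()
        self.core = core
        self.input_names = list(input_names)
        self.dynamic = {"pulse_ticks": _POS_INT}

    def apply_param(self, name, value):
        self.core.pulse_ticks = value

    def step(self, tick, inputs):
        sources = {
            name: any(vec) for name, vec in zip(self.input_names, inputs)
        }
        return {"triggers": self.core.step(tick, sources)}


class BlankerUnit(ChainUnit):
    kind = "blanker"
    ports = ("events",)

    def __init__(self, core: Blanker):
        super().__init__()
        self.core = core
        self.dynamic = {
            "window_ms": ParamSpec(
                0.0, BLANKING_MAX_MS, quantum=BLANKING_STEP_MS, integer=False
            )
        }

    def apply_param(self, name, value):
        from .control import blanking_ticks

        self.core.window_ms = value
        self.core.window_ticks = blanking_ticks(value, self._rate_hz)

    def step(self, tick, inputs):
        return {"events": self.core.step(inputs[0], inputs[1])}


# --------------------------------------------------------------------------
# Builders


def _per_channel(n: int, factory: Callable[[], Any]) -> list:
    return [factory() for _ in range(n)]


def _sigma_from(params: Mapping) -> Callable[[], SigmaEstimator]:
    return lambda: SigmaEstimator(
        s_up=params.get("s_up", 841),
        s_dn=params.get("s_dn", 159),
        floor=params.get("floor", 0),
        fraction_bits=params.get("fraction_bits", 8),
    )


def _filter_from(params: Mapping, width: int, lowpass_only: bool) -> Callable[[], FilterUnit]:
    k_list = params.get("k_list")
    if k_list is None:
        raise ConfigurationError("filter unit requires k_list")
    if lowpass_only:
        hp_tap, lp_tap = 0, len(k_list)
    else:
        hp_tap = params.get("hp_tap", 0)
        lp_tap = params.get("lp_tap", 0)
    return lambda: FilterUnit(k_list, hp_tap=hp_tap, lp_tap=lp_tap, width=width)


def _swt_from(params: Mapping) -> Callable[[], StationaryWaveletTransform]:
    wavelet = params.get("wavelet", "haar")
    if wavelet == "haar":
        g, h, scale = (1, -1), (1, 1), 2
    else:
        g, h = params["g"], params["h"]
        scale = params.get("scale", 1)
    return lambda: StationaryWaveletTransform(
        levels=params.get("levels", 4),
        g=params.get("g", g),
        h=params.get("h", h),
        coeff_scale=params.get("scale", scale),
        dilation_convention=params.get("dilation_convention", "paper"),
    )


def _build_unit(
    desc: UnitDescriptor, config: ChainConfig, width: int
) -> ChainUnit:
    n = config.n_channels
    rate = config.sample_rate_hz
    p = desc.params
    kind = desc.kind
    if kind in ("filter_unit", "lowpass_chain"):
        return FilterChainUnit(
            kind, _per_channel(n, _filter_from(p, width, kind == "lowpass_chain"))
        )
    if kind == "swt":
        return SWTUnit(_per_channel(n, _swt_from(p)))
    if kind == "sigma":
        return SigmaUnit(_per_channel(n, _sigma_from(p)))
    if kind == "hysteresis":
        return HysteresisUnit(
            _per_channel(
                n,
                lambda: HysteresisComparator(
                    t_set=p.get("t_set", 0), t_clear=p.get("t_clear")
                ),
            )
        )
    if kind == "leaky_counter":
        return CounterUnit(
            _per_channel(
                n,
                lambda: LeakyCounter(
                    s_u=p.get("s_u", 1),
                    s_d=p.get("s_d", 0),
                    q=p.get("q", 1),
                    reset_on_fire=p.get("reset_on_fire", True),
                ),
            )
        )
    if kind == "extrema":
        return ExtremaUnit(
            _per_channel(n, lambda: ExtremaDetector(delta=p.get("delta", 1)))
        )
    if kind == "spatial_avg":
        return SpatialAvgUnit(p.get("selection", list(range(n))), n, width)
    if kind in ("ap_detect", "lfp_detect"):
        variant = p.get("variant", "linear" if kind == "ap_detect" else "linear")
        multiplier = p.get("multiplier", 4.0)
        sigma_factory = _sigma_from(p.get("sigma", {}))
        refractory = p.get("refractory_ticks", 0)
        if kind == "lfp_detect":
            if variant == "wavelet":
                raise ConfigurationError("lfp_detect does not support wavelets")
            filt = p.get("filter")
            factory = lambda: cmb.LFPDetector(
                filter_unit=_filter_from(filt, width, False)()
                if filt
                else cmb.default_lfp_filter(width),
                sigma=sigma_factory(),
                multiplier=multiplier,
                band=p.get("band", "bp"),
                refractory_ticks=refractory,
            )
        elif variant == "wavelet":
            swt_factory = _swt_from(p.get("swt", {}))
            factory = lambda: cmb.APDetector(
                "wavelet",
                swt=swt_factory(),
                j_det=p.get("j_det"),
                j_thr=p.get("j_thr"),
                sigma=sigma_factory(),
                multiplier=multiplier,
                refractory_ticks=refractory,
            )
        else:
            filt = p.get("filter")
            factory = lambda: cmb.APDetector(
                variant,
                filter_unit=_filter_from(filt, width, False)()
                if filt
                else cmb.default_ap_filter(width),
                sigma=sigma_factory(),
                multiplier=multiplier,
                fixed_threshold=p.get("fixed_threshold", 0),
                band=p.get("band", "bp"),
                refractory_ticks=refractory,
            )
        return APDetectUnit(kind, _per_channel(n, factory))
    if kind == "burst_detect":
        factory = lambda: cmb.BurstDetector(
            counter=LeakyCounter(
                s_u=p.get("s_u", 500),
                s_d=p.get("s_d", 1),
                q=p.get("q", 1 << 30),
                reset_on_fire=False,
            ),
            hysteresis=HysteresisComparator(
                t_set=p.get("t_set", 1500), t_clear=p.get("t_clear", 750)
            ),
            clean_window=p.get("clean_window", 0),
        )
        return BurstDetectUnit(_per_channel(n, factory))
    if kind == "sync_detect":
        mask = p.get("channel_mask", [True] * n)
        if "min_events" in p and "window_ticks" in p:
            core = cmb.SyncDetector.window_rule(
                mask, p["min_events"], p["window_ticks"]
            )
        else:
            core = cmb.SyncDetector(
                mask,
                LeakyCounter(
                    s_u=p.get("s_u", 1),
                    s_d=p.get("s_d", 0),
                    q=p.get("q", 2),
                    reset_on_fire=True,
                ),
            )
        return SyncDetectUnit(core)
    if kind == "event_freq":
        return EventFreqUnit(
            _per_channel(
                n,
                lambda: cmb.EventFrequencyMeter(
                    rate, k=p.get("k", 13), order=p.get("order", 1)
                ),
            )
        )
    if kind == "fopp":
        return FoppUnit(
            _per_channel(
                n, lambda: cmb.PlateauFraction(k=p.get("k", 13), order=p.get("order", 1))
            )
        )
    if kind == "sp_detect":
        filt = p.get("filter")
        factory = lambda: cmb.SlowPotentialDetector(
            delta=p.get("delta", 1),
            filter_unit=_filter_from(filt, width, False)()
            if filt
            else cmb.default_sp_filter(width),
            polarity=p.get("polarity", "max"),
            min_amplitude=p.get("min_amplitude", 0),
            refractory_ticks=p.get("refractory_ticks", 0),
        )
        return SPDetectUnit(_per_channel(n, factory))
    if kind == "sorter":
        banks = [
            cmb.SortBank(
                criterion=b["criterion"],
                threshold=b.get("threshold", 0),
                event_type=b.get("event_type"),
            )
            for b in p.get("banks", [])
        ]
        core = cmb.ChannelSorter(
            n,
            banks,
            p.get("logic", "b1 or b2 or b3 or b4"),
            epoch_ticks=p.get("epoch_ticks", int(rate)),
        )
        return SorterUnit(
            core,
            event_types=p.get("event_types", []),
            has_raw=p.get("has_raw", False),
            has_sync=p.get("has_sync", False),
        )
    if kind == "router":
        routes = p.get("routes")
        if routes is None:
            routes = {src: [i] for i, src in enumerate(desc.inputs)}
        core = TriggerRouter(
            m_outputs=p.get("m_outputs", max(
                (max(v) if not isinstance(v, int) else v) for v in routes.values()
            ) + 1),
            routes=routes,
            pulse_ticks=p.get("pulse_ticks", 1),
        )
        missing = set(core.routes) - set(desc.inputs)
        if missing:
            raise ConfigurationError(f"router routes reference unknown taps: {missing}")
        return RouterUnit(core, desc.inputs)
    if kind == "blanker":
        core = Blanker(
            window_ms=p.get("window_ms", 0.0),
            channel_mask=p.get("channel_mask", [True] * n),
            rate_hz=rate,
        )
        unit = BlankerUnit(core)
        unit._rate_hz = rate
        return unit
    raise ConfigurationError(f"unknown unit kind {kind!r}")


# --------------------------------------------------------------------------
# Chain


class Chain:
    """Executable, sample-synchronous processing chain."""

    def __init__(self, config: ChainConfig, width: int = DEFAULT_WIDTH):
        if config.n_channels < 1:
            raise ConfigurationError("chain needs at least one channel")
        ids = [u.unit_id for u in config.units]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate unit ids in chain config")
        self.config = config
        self.width = width
        self.units: dict[str, ChainUnit] = {}
        for desc in config.units:
            self.units[desc.unit_id] = _build_unit(desc, config, width)
        # validate wiring and topologically order
        graph: dict[str, set[str]] = {}
        for desc in config.units:
            deps = set()
            for ref in desc.inputs:
                src = ref.split(".", 1)[0]
                if src == INPUT_TAG:
                    continue
                if src not in self.units:
                    raise ConfigurationError(
                        f"unit {desc.unit_id!r} references missing unit {src!r}"
                    )
                port = ref.split(".", 1)[1] if "." in ref else self.units[src].ports[0]
                if port not in self.units[src].ports:
                    raise ConfigurationError(
                        f"unit {src!r} has no output port {port!r}"
                    )
                deps.add(src)
            graph[desc.unit_id] = deps
        try:
            self.order = list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            raise ConfigurationError(f"cycle in chain wiring: {exc.args[1]}") from exc
        for tap in config.taps:
            src = tap.split(".", 1)[0]
            if src not in self.units:
                raise ConfigurationError(f"tap references missing unit {src!r}")
            port = tap.split(".", 1)[1] if "." in tap else self.units[src].ports[0]
            if port not in self.units[src].ports:
                raise ConfigurationError(f"tap {tap!r}: no such port")
        self._inputs = {u.unit_id: list(u.inputs) for u in config.units}
        self.tick = 0
        self._pending: list[tuple[str, str, Any]] = []
        #: applied updates as (tick, unit_id, name, value) records
        self.param_log: list[tuple[int, str, str, Any]] = []

    # -- parameters

    def update_param(self, unit_id: str, name: str, value: Any) -> Any:
        """Queue a dynamic-parameter update for the next tick boundary.

        Validates immediately (static parameters and out-of-range values are
        rejected with :class:`ParameterError`); returns the value as it will
        be applied (quantized/clamped).
        """
        unit = self.units.get(unit_id)
        if unit is None:
            raise ParameterError(f"no unit {unit_id!r} in chain")
        q = unit.check_param(name, value)
        self._pending.append((unit_id, name, q))
        return q

    def _apply_pending(self) -> None:
        for unit_id, name, value in self._pending:
            self.units[unit_id].apply_param(name, value)
            self.param_log.append((self.tick, unit_id, name, value))
        self._pending.clear()

    # -- execution

    def step(self, values: Sequence[int] | SampleFrame) -> dict[str, Any]:
        """Advance every unit one tick; returns the tapped output streams.

        Keys are ``"unit.port"``.  With no taps configured, every port of
        every unit is returned.
        """
        if isinstance(values, SampleFrame):
            values = values.values
        if len(values) != self.config.n_channels:
            raise DataError(
                f"frame has {len(values)} channels, chain expects "
                f"{self.config.n_channels}"
            )
        self._apply_pending()
        # coerce to Python ints: fixed-width numpy scalars would silently
        # wrap in the guard-bit shift arithmetic
        outputs: dict[str, dict[str, list]] = {
            INPUT_TAG: {"out": [int(v) for v in values]}
        }
        for unit_id in self.order:
            unit = self.units[unit_id]
            ins = []
            for ref in self._inputs[unit_id]:
                if "." in ref:
                    src, port = ref.split(".", 1)
                else:
                    src = ref
                    port = "out" if src == INPUT_TAG else self.units[src].ports[0]
                ins.append(outputs[src][port])
            outputs[unit_id] = unit.step(self.tick, ins)
        self.tick += 1
        if self.config.taps:
            result = {}
            for tap in self.config.taps:
                if "." in tap:
                    src, port = tap.split(".", 1)
                else:
                    src, port = tap, self.units[tap].ports[0]
                result[f"{src}.{port}"] = outputs[src][port]
            return result
        return {
            f"{uid}.{port}": vals
            for uid in self.order
            for port, vals in outputs[uid].items()
        }

    def run(self, frames) -> list[dict[str, Any]]:
        """Run a whole stream; returns the per-tick tap outputs."""
        return [self.step(f) for f in frames]


def build_chain(config: ChainConfig, width: int = DEFAULT_WIDTH) -> Chain:
    """Build an executable chain from a validated configuration."""
    return Chain(config, width)
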