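"""Combined detection functions assembled from the elementary units.

Each class composes filters and elementary decision units into one of the
standard building blocks of an extracellular processing chain:

* :class:`APDetector` / :class:`LFPDetector` -- band-pass (linear or wavelet)
  isolation of the waveform of interest, a closed-loop sigma estimator, and a
  comparator at a multiple of the estimated noise amplitude.
* :class:`BurstDetector` -- spike cleaning (refractory), a free-running leaky
  event counter, and a hysteresis comparator whose set/clear thresholds give
  different time sensitivities for burst start and end.
* :class:`SyncDetector` -- events from several channels mixed into one leaky
  counter; firing flags the channels that contributed.
* :class:`EventFrequencyMeter` / :class:`PlateauFraction` -- low-pass
  averaging of the event indicator (events/s) or of the burst envelope
  (fraction of time in plateau).
* :class:`SlowPotentialDetector` -- 0.2-2 Hz band-pass, alternating extrema
  detection with amplitude gate, and a refractory period.
* :class:`ChannelSorter` -- four criterion banks over per-epoch channel
  statistics combined by a user boolean expression, latched at epoch ends.

Per-channel detectors are scalar (one instance per channel); the chain layer
replicates them across channels.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .detectors import (
    ExtremaDetector,
    HysteresisComparator,
    LeakyCounter,
    SigmaEstimator,
)
from .errors import ConfigurationError
from .filters import FilterUnit, StationaryWaveletTransform
from .frames import DEFAULT_WIDTH

#: Fraction bits used to quantize threshold multipliers.
MULTIPLIER_BITS = 8

#: Full-scale value an event indicator is mapped to before low-pass
#: averaging, so the smoothed mean stays resolvable above integer
#: quantization (2^14 fits a 16-bit signed sample).
EVENT_SCALE = 1 << 14


def quantize_multiplier(multiplier: float) -> int:
    """Quantize a threshold multiplier to its fixed-point grid."""
    if multiplier <= 0:
        raise ConfigurationError("multiplier must be positive")
    q = round(multiplier * (1 << MULTIPLIER_BITS))
    return max(q, 1)


class APDetector:
    """Adaptive action-potential detector for one channel.

    Variants
    --------
    ``linear``
        Band-pass :class:`FilterUnit` isolates the spike band; a
        :class:`SigmaEstimator` tracks the filtered noise amplitude; an event
        fires on each rising crossing of ``multiplier * sigma``.
    ``wavelet``
        A stationary wavelet transform replaces the linear filter: detection
        compares ``|d[j_det]|`` against ``multiplier * sigma`` where sigma is
        estimated on level ``j_thr``.  The threshold level defaults to the
        detection level so the multiplier is scale-consistent; estimating it
        on a different level (e.g. the first) remains configurable.
    ``fixed_threshold``
        Plain comparator at a fixed level on the (optionally filtered)
        signal.

    One event is emitted per threshold crossing (rising edge of the
    comparison), so a multi-sample supra-threshold waveform yields a single
    event tick.  An optional ``refractory_ticks`` cleaning period suppresses
    further events after each accepted one, discarding the secondary
    crossings a single multiphasic waveform can produce.
    """

    def __init__(
        self,
        variant: str = "linear",
        *,
        filter_unit: FilterUnit | None = None,
        swt: StationaryWaveletTransform | None = None,
        j_det: int | None = None,
        j_thr: int | None = None,
        sigma: SigmaEstimator | None = None,
        multiplier: float = 4.0,
        fixed_threshold: int = 0,
        band: str = "bp",
        refractory_ticks: int = 0,
    ):
        if variant not in ("linear", "wavelet", "fixed_threshold"):
            raise ConfigurationError(f"unknown AP detector variant {variant!r}")
        if refractory_ticks < 0:
            raise ConfigurationError("refractory_ticks must be >= 0")
        self.variant = variant
        if variant == "wavelet":
            self.swt = swt or StationaryWaveletTransform(levels=2)
            self.j_det = j_det if j_det is not None else self.swt.levels
            self.j_thr = j_thr if j_thr is not None else self.j_det
            if not 1 <= self.j_det <= self.swt.levels:
                raise ConfigurationError("j_det must be within configured levels")
            if not 1 <= self.j_thr <= self.swt.levels:
                raise ConfigurationError("j_thr must be within configured levels")
            self.filter_unit = None
        else:
            self.filter_unit = filter_unit
            self.swt = None
        if band not in ("lp", "hp", "bp"):
            raise ConfigurationError("band must be one of lp/hp/bp")
        self.band = band
        self.sigma = sigma or SigmaEstimator()
        self.multiplier_q = quantize_multiplier(multiplier)
        self.fixed_threshold = int(fixed_threshold)
        self.refractory_ticks = int(refractory_ticks)
        self._refract = 0
        self._level = False

    def set_multiplier(self, multiplier: float) -> None:
        self.multiplier_q = quantize_multiplier(multiplier)

    def _filtered(self, x: int) -> int:
        if self.filter_unit is None:
            return x
        lp, hp, bp = self.filter_unit.step(x)
        return {"lp": lp, "hp": hp, "bp": bp}[self.band]

    def step(self, x: int) -> bool:
        """Advance one tick; returns True on a detection event."""
        if self.variant == "wavelet":
            details, _ = self.swt.step(x)
            det = details[self.j_det - 1]
            self.sigma.step(details[self.j_thr - 1])
            value = det if det >= 0 else -det
            threshold = self.sigma.threshold(self.multiplier_q, MULTIPLIER_BITS)
        elif self.variant == "linear":
            value = self._filtered(x)
            self.sigma.step(value)
            threshold = self.sigma.threshold(self.multiplier_q, MULTIPLIER_BITS)
        else:
            value = self._filtered(x)
            threshold = self.fixed_threshold
        prev = self._level
        # threshold <= 0 (e.g. sigma estimate still at its power-on zero)
        # requires a strictly positive excursion, so silence never fires
        self._level = value >= threshold if threshold > 0 else value > threshold
        event = self._level and not prev
        if self._refract > 0:
            self._refract -= 1
            return False
        if event:
            self._refract = self.refractory_ticks
        return event

    def process(self, xs: Sequence[int]) -> list[int]:
        """Block form; returns the tick indices of detection events."""
        return [t for t, x in enumerate(xs) if self.step(x)]


def default_ap_filter(width: int = DEFAULT_WIDTH) -> FilterUnit:
    """Spike band-pass ~106-530 Hz at 10 kHz sampling (k=[2, 4]).

    With first-order band edges this acts as a crude matched filter for
    millisecond biphasic spike waveforms: the low-pass edge averages the
    2-3 samples of the depolarization lobe (raising peak-to-noise), while
    the high-pass edge removes LFP-band content below ~100 Hz.
    """
    return FilterUnit(k_list=[2, 4], lp_tap=1, hp_tap=2, width=width)


def default_lfp_filter(width: int = DEFAULT_WIDTH) -> FilterUnit:
    """LFP band-pass ~1.6-106 Hz at 10 kHz sampling (k=[4, 4, 10]).

    The upper edge is second order (two k=4 sections) so that
    millisecond-scale spike transients two decades above the band are
    attenuated by ~40 dB and cannot masquerade as field potentials.
    """
    return FilterUnit(k_list=[4, 4, 10], hp_tap=3, lp_tap=2, width=width)


class LFPDetector(APDetector):
    """Local-field-potential detector: linear band two orders of magnitude
    below the spike band.  Wavelet filtering is not offered -- LFP amplitude
    alone discriminates well.

    The sigma estimate gets a small default floor (4 LSB): white front-end
    noise shrinks to a couple of LSB inside the narrow LFP band, and without
    a floor the adaptive threshold would collapse onto the quantization grid
    and chatter on rounding noise."""

    def __init__(
        self,
        *,
        filter_unit: FilterUnit | None = None,
        sigma: SigmaEstimator | None = None,
        multiplier: float = 4.0,
        band: str = "bp",
        refractory_ticks: int = 0,
    ):
        super().__init__(
            "linear",
            filter_unit=filter_unit or default_lfp_filter(),
            sigma=sigma or SigmaEstimator(floor=4),
            multiplier=multiplier,
            band=band,
            refractory_ticks=refractory_ticks,
        )


class BurstDetector:
    """Burst envelope with spike cleaning, for one channel.

    Incoming AP events first pass a refractory gate: each accepted event
    blanks the following ``clean_window`` ticks, discarding noise-induced
    double detections.  Cleaned events feed a free-running leaky counter, and
    a hysteresis comparator on the count marks the burst envelope --
    ``t_set`` controls sensitivity to burst onset, ``t_clear`` to burst end.

    The default counter steps (s_u=500, s_d=1) put the reference firing rate
    at 20 Hz for 10 kHz sampling: the count grows during >20 Hz intraburst
    firing and drains during silence; with ``t_set=1500`` a burst is declared
    after roughly three rapid spikes.
    """

    def __init__(
        self,
        counter: LeakyCounter | None = None,
        hysteresis: HysteresisComparator | None = None,
        clean_window: int = 0,
    ):
        if clean_window < 0:
            raise ConfigurationError("clean_window must be >= 0")
        self.counter = counter or LeakyCounter(
            s_u=500, s_d=1, q=1 << 30, reset_on_fire=False
        )
        self.hysteresis = hysteresis or HysteresisComparator(t_set=1500, t_clear=750)
        self.clean_window = int(clean_window)
        self._refract = 0

    def step(self, ap_event: int) -> tuple[bool, bool, bool, bool]:
        """Advance one tick.

        Returns ``(burst_level, cleaned_event, burst_start, burst_end)``.
        """
        if self._refract > 0:
            self._refract -= 1
            cleaned = False
        elif ap_event:
            cleaned = True
            self._refract = self.clean_window
        else:
            cleaned = False
        count, _ = self.counter.step(1 if cleaned else 0)
        prev = self.hysteresis.level
        level, start = self.hysteresis.step(count)
        end = prev and not level
        return level, cleaned, start, end


class SyncDetector:
    """Cross-channel synchronization detector.

    Per tick the number of events on the selected channels increments a
    leaky counter (reset-on-fire mode); when the count reaches ``q`` a
    synchronization event fires and the channels that contributed events
    since the counter was last empty are flagged.

    The factory :meth:`window_rule` maps the natural phrasing "more than
    ``min_events`` events within ``window_ticks``" onto counter steps: each
    event adds ``window_ticks // 2``, the leak drains one event's worth over
    exactly ``window_ticks`` ticks, and the counter fires as soon as the
    remembered count exceeds ``min_events`` events.  The leak makes this a
    sliding-window approximation: events are gradually forgotten over the
    window rather than expiring all at once.
    """

    def __init__(
        self,
        channel_mask: Sequence[bool],
        counter: LeakyCounter | None = None,
    ):
        self.channel_mask = tuple(bool(m) for m in channel_mask)
        if not any(self.channel_mask):
            raise ConfigurationError("channel_mask must select >= 1 channel")
        self.counter = counter or LeakyCounter(s_u=1, s_d=0, q=2)
        self._contrib: set[int] = set()
        self.last_contributors: tuple[int, ...] = ()

    @classmethod
    def window_rule(
        cls,
        channel_mask: Sequence[bool],
        min_events: int,
        window_ticks: int,
    ) -> "SyncDetector":
        """Fire when more than ``min_events`` events arrive in ``window_ticks``."""
        if min_events < 1 or window_ticks < 2:
            raise ConfigurationError("need min_events >= 1 and window_ticks >= 2")
        s_u = window_ticks // 2
        s_d = max(min_events * s_u // window_ticks, 1)
        counter = LeakyCounter(
            s_u=s_u, s_d=s_d, q=min_events * s_u + 1, reset_on_fire=True
        )
        return cls(channel_mask, counter)

    def step(self, flags: Sequence[bool]) -> bool:
        """Advance one tick with this tick's event flags; True on sync."""
        n = 0
        for ch, (m, f) in enumerate(zip(self.channel_mask, flags)):
            if m and f:
                n += 1
                self._contrib.add(ch)
        _, fired = self.counter.step(n)
        if fired:
            self.last_contributors = tuple(sorted(self._contrib))
            self._contrib.clear()
        elif self.counter.count == 0:
            self._contrib.clear()
        return fired


class _EventAverager:
    """Shared machinery: low-pass of a scaled 0/1 indicator."""

    def __init__(self, k: int, order: int = 1):
        if order not in (1, 2):
            raise ConfigurationError("order must be 1 or 2")
        from .filters import FirstOrderLowpass

        self.stages = [FirstOrderLowpass(k) for _ in range(order)]

    def smoothed(self, indicator: int) -> int:
        y = EVENT_SCALE if indicator else 0
        for stage in self.stages:
            y = stage.step(y)
        return y


class EventFrequencyMeter(_EventAverager):
    """Smoothed event rate in events/s for one channel.

    The 0/1 event indicator, scaled to full range, runs through a first- or
    second-order unit-DC-gain low-pass with time constant set by ``k``
    (``tau ~ (2^k - 1) Ts``); the smoothed mean is the event probability per
    tick, rescaled to Hz by the sampling rate.
    """

    def __init__(self, rate_hz: float, k: int = 13, order: int = 1):
        super().__init__(k, order)
        self.rate_hz = float(rate_hz)

    def step(self, event: int) -> float:
        """Advance one tick; returns the current frequency estimate (Hz)."""
        return self.smoothed(event) * self.rate_hz / EVENT_SCALE


class PlateauFraction(_EventAverager):
    """Fraction of time the burst/plateau envelope is active (FOPP), the
    low-passed burst indicator on one channel; output in [0, 1]."""

    def __init__(self, k: int = 13, order: int = 1):
        super().__init__(k, order)

    def step(self, burst_level: int) -> float:
        return self.smoothed(burst_level) / EVENT_SCALE


def default_sp_filter(width: int = DEFAULT_WIDTH) -> FilterUnit:
    """Slow-potential band-pass ~0.19-1.56 Hz at 10 kHz sampling."""
    return FilterUnit(k_list=[10, 13], hp_tap=2, lp_tap=1, width=width)


class SlowPotentialDetector:
    """Slow-potential (sub-Hz oscillation) detector for one channel.

    The signal is band-passed to the 0.2-2 Hz detection band, then an
    alternating extrema detector with amplitude threshold ``delta`` finds
    oscillation peaks.  An event is emitted at each extremum of the
    configured polarity (default: maximum), optionally gated by a minimum
    peak-to-peak amplitude and a refractory period enforced by an event
    counter.
    """

    def __init__(
        self,
        delta: int,
        filter_unit: FilterUnit | None = None,
        polarity: str = "max",
        min_amplitude: int = 0,
        refractory_ticks: int = 0,
    ):
        if polarity not in ("max", "min"):
            raise ConfigurationError("polarity must be 'max' or 'min'")
        self.filter_unit = filter_unit or default_sp_filter()
        self.extrema = ExtremaDetector(delta)
        self.polarity = polarity
        self.min_amplitude = int(min_amplitude)
        self.refractory_ticks = int(refractory_ticks)
        self._refract = 0

    def step(self, x: int) -> bool:
        """Advance one tick; returns True on a slow-potential event."""
        _, _, bp = self.filter_unit.step(x)
        max_ev, min_ev = self.extrema.step(bp)
        event = max_ev if self.polarity == "max" else min_ev
        if self._refract > 0:
            self._refract -= 1
            return False
        if event and self.extrema.last_amplitude >= self.min_amplitude:
            self._refract = self.refractory_ticks
            return True
        return False


# --------------------------------------------------------------------------
# Channel sorting


@dataclass
class SortBank:
    """One sorting criterion applied channel-wise to epoch statistics."""

    criterion: str  # amplitude_exceeds | event_count_exceeds | synchronization_flagged
    threshold: int = 0
    event_type: str | None = None

    def __post_init__(self) -> None:
        if self.criterion not in (
            "amplitude_exceeds",
            "event_count_exceeds",
            "synchronization_flagged",
        ):
            raise ConfigurationError(f"unknown sort criterion {self.criterion!r}")
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if self.criterion == "event_count_exceeds" and not self.event_type:
            raise ConfigurationError("event_count_exceeds needs an event_type")

    def evaluate(self, stats: "EpochStats") -> list[bool]:
        if self.criterion == "amplitude_exceeds":
            return [a > self.threshold for a in stats.max_abs]
        if self.criterion == "event_count_exceeds":
            counts = stats.event_counts.get(self.event_type, [0] * stats.n_channels)
            return [c > self.threshold for c in counts]
        return list(stats.sync_flagged)


@dataclass
class EpochStats:
    """Per-channel statistics accumulated over one measurement period."""

    n_channels: int
    max_abs: list[int] = field(default_factory=list)
    event_counts: dict[str, list[int]] = field(default_factory=dict)
    sync_flagged: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.max_abs:
            self.max_abs = [0] * self.n_channels
        if not self.sync_flagged:
            self.sync_flagged = [False] * self.n_channels


_ALLOWED_BANKS = ("b1", "b2", "b3", "b4")


def _eval_logic(node: ast.AST, banks: Mapping[str, Sequence[bool]], n: int) -> list[bool]:
    if isinstance(node, ast.Expression):
        return _eval_logic(node.body, banks, n)
    if isinstance(node, ast.BoolOp):
        parts = [_eval_logic(v, banks, n) for v in node.values]
        if isinstance(node.op, ast.And):
            return [all(p[i] for p in parts) for i in range(n)]
        return [any(p[i] for p in parts) for i in range(n)]
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
        inner = _eval_logic(node.operand, banks, n)
        return [not v for v in inner]
    if isinstance(node, ast.Name):
        name = node.id.lower()
        if name not in _ALLOWED_BANKS:
            raise ConfigurationError(f"unknown bank identifier {node.id!r}")
        return list(banks[name])
    raise ConfigurationError("logic expression may only use b1..b4, and/or/not")


def combine_banks(
    logic_expr: str, bank_results: Sequence[Sequence[bool]]
) -> list[bool]:
    """Channel-wise boolean combination of the four bank vectors.

    ``logic_expr`` uses identifiers ``b1..b4`` with ``and``/``or``/``not``
    and parentheses (e.g. ``"(b1 or b2) and not b3"``).
    """
    n = len(bank_results[0])
    banks = {f"b{i + 1}": bank_results[i] for i in range(len(bank_results))}
    try:
        tree = ast.parse(logic_expr, mode="eval")
    except SyntaxError as exc:
        raise ConfigurationError(f"malformed logic expression: {exc}") from exc
    return _eval_logic(tree, banks, n)


@dataclass
class SortResult:
    """Outcome of one measurement period of channel sorting."""

    banks: list[list[bool]]
    final: list[bool]
    epoch: int


def sort_channels(
    banks: Sequence[SortBank], logic_expr: str, stats: EpochStats, epoch: int = 0
) -> SortResult:
    """Evaluate the four criterion banks on one epoch's statistics."""
    if len(banks) != 4:
        raise ConfigurationError("exactly four sorting banks are required")
    results = [b.evaluate(stats) for b in banks]
    return SortResult(results, combine_banks(logic_expr, results), epoch)


class ChannelSorter:
    """Streaming channel sorter over measurement periods.

    Statistics (peak absolute raw amplitude, event counts per type,
    synchronization contribution) accumulate within an epoch of
    ``epoch_ticks`` ticks; at the epoch boundary -- or on an explicit
    :meth:`close_epoch` request -- the four banks are evaluated and the final
    selection re-latched.  Between boundaries :attr:`result` is stable no
    matter what the within-epoch statistics do.
    """

    def __init__(
        self,
        n_channels: int,
        banks: Sequence[SortBank],
        logic_expr: str,
        epoch_ticks: int = 10_000,
    ):
        if epoch_ticks < 1:
            raise ConfigurationError("epoch_ticks must be >= 1")
        if len(banks) != 4:
            raise ConfigurationError("exactly four sorting banks are required")
        # validate the expression up-front against dummy banks
        combine_banks(logic_expr, [[False] * n_channels] * 4)
        self.n_channels = int(n_channels)
        self.banks = list(banks)
        self.logic_expr = logic_expr
        self.epoch_ticks = int(epoch_ticks)
        self.stats = EpochStats(n_channels)
        self.epoch = 0
        self._tick_in_epoch = 0
        self.result = SortResult(
            [[False] * n_channels] * 4, [False] * n_channels, -1
        )

    def observe(
        self,
        raw_values: Sequence[int] | None = None,
        events: Mapping[str, Sequence[bool]] | None = None,
        sync_contributors: Sequence[int] | None = None,
    ) -> SortResult:
        """Feed one tick of observations; returns the latched result."""
        if raw_values is not None:
            for ch, v in enumerate(raw_values):
                a = v if v >= 0 else -v
                if a > self.stats.max_abs[ch]:
                    self.stats.max_abs[ch] = a
        if events:
            for etype, flags in events.items():
                counts = self.stats.event_counts.setdefault(
                    etype, [0] * self.n_channels
                )
                for ch, f in enumerate(flags):
                    if f:
                        counts[ch] += 1
        if sync_contributors:
            for ch in sync_contributors:
                self.stats.sync_flagged[ch] = True
        self._tick_in_epoch += 1
        if self._tick_in_epoch >= self.epoch_ticks:
            self.close_epoch()
        return self.result

    def close_epoch(self) -> SortResult:
        """End the measurement period now and re-latch the sorting result."""
        self.result = sort_channels(
            self.banks, self.logic_expr, self.stats, self.epoch
        )
        self.epoch += 1
        self.stats = EpochStats(self.n_channels)
        self._tick_in_epoch = 0
        return self.result
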