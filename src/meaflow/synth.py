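"""Seeded synthetic multichannel MEA recordings with exact ground truth.

The generator emulates the three signal classes a multi-electrode-array
platform must handle, as phenomenological stand-ins with controlled
statistics (no biophysical simulation):

* **Action potentials** -- biphasic ~1 ms templates (difference of
  Gaussians, spectral energy above ~200 Hz) inserted at known ticks, either
  at a homogeneous rate or grouped into bursts with an intraburst rate above
  10 Hz separated by silent periods.
* **Local field potentials** -- damped oscillations below 100 Hz.
* **Slow potentials** -- sub-Hz oscillations in the 0.2-2 Hz detection band
  with an asymmetric waveform (fast rise, slow decay, so the downward phase
  is well defined); an optional stepwise protocol reschedules frequency and
  amplitude mid-recording, emulating glucose steps.

Background noise is white Gaussian (matching the sigma estimator's working
hypothesis).  Every inserted component is logged tick-exactly in a
:class:`GroundTruthLog`, and the same seed always reproduces the same
recording bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .io import EventRecord, RawRecordingHeader


@dataclass
class BurstModel:
    """Bursting AP schedule: bursts of fast firing separated by silence."""

    burst_rate_hz: float = 0.2
    intraburst_hz: float = 50.0
    burst_len_s: float = 1.0

    def __post_init__(self) -> None:
        if self.intraburst_hz <= 10.0:
            raise ConfigurationError("intraburst rate must exceed 10 Hz")


@dataclass
class LFPModel:
    """Damped-oscillation LFP events (< 100 Hz)."""

    event_rate_hz: float = 0.5
    freq_hz: float = 10.0
    amplitude: float = 400.0
    cycles: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.freq_hz < 100.0:
            raise ConfigurationError("LFP frequency must be below 100 Hz")


@dataclass
class SPSegment:
    """One protocol segment of slow-potential activity."""

    duration_s: float
    freq_hz: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 0.2 <= self.freq_hz <= 2.0:
            raise ConfigurationError("SP frequency must lie in 0.2-2 Hz")


@dataclass
class SynthSpec:
    """Full description of a synthetic recording."""

    n_channels: int = 4
    rate_hz: float = 10_000.0
    duration_s: float = 10.0
    noise_sigma: float = 20.0
    ap_amplitude: float = 120.0
    ap_rate_hz: float = 0.0
    burst: BurstModel | None = None
    lfp: LFPModel | None = None
    sp_segments: list[SPSegment] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.duration_s <= 0 or self.rate_hz <= 0:
            raise ConfigurationError("invalid synthesis dimensions")
        if self.noise_sigma < 0 or self.ap_rate_hz < 0 or self.ap_amplitude < 0:
            raise ConfigurationError("rates and amplitudes must be >= 0")


def neural_preset(
    n_channels: int = 60, duration_s: float = 30.0, seed: int = 0
) -> SynthSpec:
    """Patterned neural culture: bursting APs on background noise."""
    return SynthSpec(
        n_channels=n_channels,
        duration_s=duration_s,
        noise_sigma=20.0,
        ap_amplitude=120.0,
        burst=BurstModel(),
        lfp=LFPModel(),
        seed=seed,
    )


def islet_preset(
    n_channels: int = 8,
    duration_s: float = 60.0,
    seed: int = 0,
    glucose_protocol: Sequence[SPSegment] | None = None,
) -> SynthSpec:
    """Pancreatic islet: slow potentials (optionally stepped) plus sparse APs."""
    if glucose_protocol is None:
        glucose_protocol = [SPSegment(duration_s, 0.5, 2000.0)]
    return SynthSpec(
        n_channels=n_channels,
        duration_s=duration_s,
        noise_sigma=20.0,
        ap_amplitude=120.0,
        ap_rate_hz=1.0,
        sp_segments=list(glucose_protocol),
        seed=seed,
    )


@dataclass
class GroundTruthLog:
    """Tick-exact list of inserted components, sorted by tick."""

    events: list[EventRecord] = field(default_factory=list)

    def add(self, tick: int, channel: int, etype: str, value: float = 0.0) -> None:
        self.events.append(EventRecord(int(tick), int(channel), etype, value))

    def of_type(self, etype: str, channel: int | None = None) -> list[EventRecord]:
        return [
            e
            for e in self.events
            if e.type == etype and (channel is None or e.channel == channel)
        ]

    def ticks(self, etype: str, channel: int | None = None) -> np.ndarray:
        return np.array([e.tick for e in self.of_type(etype, channel)], dtype=np.int64)

    def sort(self) -> None:
        self.events.sort(key=lambda e: (e.tick, e.channel, e.type))


def ap_template(rate_hz: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Biphasic ~1 ms spike template; returns (waveform, peak offset).

    A difference of two Gaussians: a sharp positive lobe followed by a
    shallower negative lobe, mean-free to within the lobe balance, peak
    normalized to ``amplitude``.
    """
    span = int(round(1.0e-3 * rate_hz))  # 1 ms worth of samples
    if span < 4:
        raise ConfigurationError("sampling rate too low for a 1 ms AP template")
    t = (np.arange(span) - round(span * 0.3)) / rate_hz
    w = np.exp(-0.5 * (t / 1.2e-4) ** 2) - 0.6 * np.exp(
        -0.5 * ((t - 3.0e-4) / 2.0e-4) ** 2
    )
    w = w / np.max(w) * amplitude
    return w, int(np.argmax(w))


def sp_waveform(phase: np.ndarray) -> np.ndarray:
    """Asymmetric slow-potential cycle on phase in [0, 1).

    Half-cosine rise over the first 30 % of the cycle (-1 to +1, maximum at
    phase 0.3) and half-cosine decay over the remaining 70 % -- continuous
    first derivative, so almost all spectral energy sits at the fundamental.
    """
    u = np.mod(phase, 1.0)
    rising = u < 0.3
    out = np.empty_like(u)
    out[rising] = -np.cos(np.pi * u[rising] / 0.3)
    out[~rising] = np.cos(np.pi * (u[~rising] - 0.3) / 0.7)
    return out


def _poisson_ticks(
    rng: np.random.Generator, rate_hz: float, t0: int, t1: int, rate_ticks: float
) -> np.ndarray:
    """Homogeneous Poisson event ticks in [t0, t1)."""
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0, dtype=np.int64)
    p = rate_hz / rate_ticks
    n_exp = (t1 - t0) * p
    n = rng.poisson(n_exp)
    return np.sort(rng.integers(t0, t1, size=n)).astype(np.int64)


def generate(spec: SynthSpec) -> tuple[RawRecordingHeader, np.ndarray, GroundTruthLog]:
    """Synthesize a recording.

    Returns the header, an int16 array of shape (n_ticks, n_channels), and
    the ground-truth log.  Deterministic for a given spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate_hz
    n_ticks = int(round(spec.duration_s * rate))
    n_ch = spec.n_channels
    truth = GroundTruthLog()

    if spec.noise_sigma > 0:
        signal = rng.normal(0.0, spec.noise_sigma, size=(n_ticks, n_ch))
    else:
        signal = np.zeros((n_ticks, n_ch))

    # -- action potentials
    if spec.ap_rate_hz > 0 or spec.burst is not None:
        template, peak_off = ap_template(rate, spec.ap_amplitude)
        if len(template) > n_ticks:
            raise ConfigurationError("AP template longer than the recording")
        for ch in range(n_ch):
            starts: list[int] = []
            if spec.burst is not None:
                b = spec.burst
                burst_len = int(round(b.burst_len_s * rate))
                period = int(round(rate / b.burst_rate_hz))
                first = int(rng.integers(0, max(period // 2, 1)))
                for b0 in range(first, n_ticks - burst_len, period):
                    truth.add(b0, ch, "BURST_START")
                    truth.add(b0 + burst_len, ch, "BURST_END")
                    starts.extend(
                        _poisson_ticks(rng, b.intraburst_hz, b0, b0 + burst_len, rate)
                    )
            if spec.ap_rate_hz > 0:
                starts.extend(
                    _poisson_ticks(rng, spec.ap_rate_hz, 0, n_ticks - len(template), rate)
                )
            for t0 in sorted(starts):
                if t0 + len(template) > n_ticks:
                    continue
                signal[t0 : t0 + len(template), ch] += template
                truth.add(t0 + peak_off, ch, "AP", spec.ap_amplitude)

    # -- local field potentials
    if spec.lfp is not None:
        m = spec.lfp
        dur = int(round(m.cycles / m.freq_hz * rate))
        t = np.arange(dur) / rate
        wave = m.amplitude * np.exp(-t * m.freq_hz / m.cycles * 3.0) * np.sin(
            2 * np.pi * m.freq_hz * t
        )
        for ch in range(n_ch):
            for t0 in _poisson_ticks(rng, m.event_rate_hz, 0, n_ticks - dur, rate):
                signal[t0 : t0 + dur, ch] += wave
                truth.add(t0, ch, "LFP", m.amplitude)

    # -- slow potentials (shared phase across channels: syncytial behaviour)
    if spec.sp_segments:
        tick0 = 0
        for seg in spec.sp_segments:
            seg_ticks = min(int(round(seg.duration_s * rate)), n_ticks - tick0)
            if seg_ticks <= 0:
                break
            phase = np.arange(seg_ticks) * seg.freq_hz / rate
            wave = seg.amplitude * sp_waveform(phase)
            signal[tick0 : tick0 + seg_ticks, :] += wave[:, None]
            n_cycles = int(np.floor(phase[-1]))
            period_ticks = rate / seg.freq_hz
            for c in range(n_cycles + 1):
                max_tick = tick0 + int(round((c + 0.3) * period_ticks))
                min_tick = tick0 + int(round((c + 1.0) * period_ticks))
                if max_tick < tick0 + seg_ticks:
                    for ch in range(n_ch):
                        truth.add(max_tick, ch, "SP_MAX", seg.amplitude)
                if min_tick < tick0 + seg_ticks:
                    for ch in range(n_ch):
                        truth.add(min_tick, ch, "SP_MIN", seg.amplitude)
            tick0 += seg_ticks

    truth.sort()
    frames = np.clip(np.rint(signal), -32768, 32767).astype(np.int16)
    header = RawRecordingHeader(
        n_channels=n_ch,
        sample_rate_hz=rate,
        bit_depth=16,
        gain_code=1,
        n_frames=n_ticks,
    )
    return header, frames, truth
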