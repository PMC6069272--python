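"""Stimulation trigger routing and post-stimulus detection blanking.

A :class:`TriggerRouter` maps any set of event sources onto ``M`` trigger
lines (any-to-any OR) and stretches each assertion into a pulse of
configurable width; re-triggering extends the pulse.  Assertion happens on
the same tick as the source event (zero routing latency in ticks).

A :class:`Blanker` suppresses detection events on selected channels for a
configurable window after any trigger, rejecting stimulation artifacts that
would otherwise register as cell activity.  Blanking gates event detection
only -- the raw sample stream is untouched, so acquisition and recording
continue through the artifact.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .errors import ConfigurationError

BLANKING_STEP_MS = 0.1
BLANKING_MAX_MS = 25.0


class TriggerRouter:
    """Route event sources to ``m_outputs`` trigger lines with pulse stretch.

    Parameters
    ----------
    m_outputs
        Number of trigger lines.
    routes
        Mapping source name -> line index (or list of line indices).
    pulse_ticks
        Pulse width per line: a routed event holds the line high for this
        many ticks; an event arriving while the line is high restarts the
        countdown (OR + retrigger semantics).
    """

    def __init__(
        self,
        m_outputs: int,
        routes: Mapping[str, int | Sequence[int]],
        pulse_ticks: int = 1,
    ):
        if m_outputs < 1:
            raise ConfigurationError("need at least one trigger line")
        if pulse_ticks < 1:
            raise ConfigurationError("pulse_ticks must be >= 1")
        self.m_outputs = int(m_outputs)
        self.pulse_ticks = int(pulse_ticks)
        self.routes: dict[str, tuple[int, ...]] = {}
        for src, lines in routes.items():
            if isinstance(lines, int):
                lines = (lines,)
            lines = tuple(int(l) for l in lines)
            for line in lines:
                if not 0 <= line < m_outputs:
                    raise ConfigurationError(
                        f"route {src!r} -> line {line} outside 0..{m_outputs - 1}"
                    )
            self.routes[src] = lines
        self._remaining = [0] * self.m_outputs
        self.log: list[tuple[int, int, str]] = []  # (tick, line, rise|fall)

    def step(self, tick: int, source_events: Mapping[str, bool]) -> list[bool]:
        """Advance one tick; returns the M-line trigger frame."""
        for src in source_events:
            if src not in self.routes:
                raise ConfigurationError(f"event source {src!r} has no route")
        fire = [False] * self.m_outputs
        for src, lines in self.routes.items():
            if source_events.get(src):
                for line in lines:
                    fire[line] = True
        frame = []
        for line in range(self.m_outputs):
            was_high = self._remaining[line] > 0
            if fire[line]:
                self._remaining[line] = self.pulse_ticks
            elif was_high:
                self._remaining[line] -= 1
            high = self._remaining[line] > 0
            if high and not was_high:
                self.log.append((tick, line, "rise"))
            elif was_high and not high:
                self.log.append((tick, line, "fall"))
            frame.append(high)
        return frame


def blanking_ticks(window_ms: float, rate_hz: float) -> int:
    """Blanking window length in ticks; the window is quantized to 0.1 ms."""
    if not 0.0 <= window_ms <= BLANKING_MAX_MS:
        raise ConfigurationError(
            f"blanking window must be within 0..{BLANKING_MAX_MS} ms"
        )
    steps = round(window_ms / BLANKING_STEP_MS)
    if abs(steps * BLANKING_STEP_MS - window_ms) > 1e-9:
        raise ConfigurationError(
            f"blanking window must be a multiple of {BLANKING_STEP_MS} ms"
        )
    return round(steps * BLANKING_STEP_MS * rate_hz / 1000.0)


class Blanker:
    """Post-trigger suppression of detection events on masked channels.

    After any tick on which a trigger line is asserted, events on the masked
    channels are dropped for ``window_ms`` (0-25 ms, 0.1 ms steps).  The gate
    opens on the trigger tick itself and a retrigger restarts the window.
    Unmasked channels, and the raw sample stream, are never affected.
    """

    def __init__(
        self,
        window_ms: float,
        channel_mask: Sequence[bool],
        rate_hz: float,
    ):
        self.window_ticks = blanking_ticks(window_ms, rate_hz)
        self.window_ms = float(window_ms)
        self.channel_mask = tuple(bool(m) for m in channel_mask)
        self._remaining = 0
        self.dropped_count = 0

    def step(
        self, trigger_frame: Sequence[bool], event_flags: Sequence[bool]
    ) -> list[bool]:
        """Advance one tick; returns the gated event flags."""
        if any(trigger_frame):
            self._remaining = self.window_ticks
        gated = []
        active = self._remaining > 0
        for ch, flag in enumerate(event_flags):
            if active and flag and ch < len(self.channel_mask) and self.channel_mask[ch]:
                gated.append(False)
                self.dropped_count += 1
            else:
                gated.append(bool(flag))
        if self._remaining > 0:
            self._remaining -= 1
        return gated
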