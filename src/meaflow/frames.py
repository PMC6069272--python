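"""Frame containers exchanged between processing units.

A *tick* is one sample period: every unit in a chain advances exactly once
per tick.  Samples are signed fixed-point integers of width ``W`` bits
(default 16, the ADC width), carried as plain Python ints so that all
arithmetic is exact and shifts are true two's-complement arithmetic shifts.
Event streams carry one boolean per channel per tick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

DEFAULT_WIDTH = 16


def sample_range(width: int = DEFAULT_WIDTH) -> tuple[int, int]:
    """Inclusive (lo, hi) range of a signed ``width``-bit sample."""
    return -(1 << (width - 1)), (1 << (width - 1)) - 1


def clamp(value: int, width: int = DEFAULT_WIDTH) -> int:
    """Saturate ``value`` to the signed ``width``-bit range."""
    lo, hi = sample_range(width)
    if value < lo:
        return lo
    if value > hi:
        return hi
    return value


@dataclass(frozen=True)
class SampleFrame:
    """One tick's vector of per-channel signed samples.

    Parameters
    ----------
    tick
        Sample index, ``>= 0``.
    values
        One signed integer per channel, inside the ``width``-bit range.
    """

    tick: int
    values: tuple[int, ...]
    width: int = DEFAULT_WIDTH

    def __post_init__(self) -> None:
        if self.tick < 0:
            raise ValueError(f"tick must be >= 0, got {self.tick}")
        object.__setattr__(self, "values", tuple(int(v) for v in self.values))
        lo, hi = sample_range(self.width)
        for v in self.values:
            if not lo <= v <= hi:
                raise ValueError(
                    f"sample {v} outside signed {self.width}-bit range [{lo}, {hi}]"
                )

    @property
    def n_channels(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EventFrame:
    """One tick's vector of per-channel event flags (one bit per channel).

    An event occupies exactly one tick; sustained conditions are encoded by
    level outputs, not by event frames.
    """

    tick: int
    flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.tick < 0:
            raise ValueError(f"tick must be >= 0, got {self.tick}")
        object.__setattr__(self, "flags", tuple(bool(f) for f in self.flags))

    @property
    def n_channels(self) -> int:
        return len(self.flags)


def frames_from_array(array: Sequence[Sequence[int]], width: int = DEFAULT_WIDTH):
    """Yield :class:`SampleFrame` objects from a (n_ticks, n_channels) array."""
    for t, row in enumerate(array):
        yield SampleFrame(t, tuple(int(v) for v in row), width)
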