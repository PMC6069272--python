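"""Elementary decision units.

These are the scalar building blocks every detection pipeline is assembled
from: a closed-loop noise-amplitude (sigma) estimator, a two-threshold
hysteresis comparator, a leaky event counter, an alternating local-extrema
detector, and a shift-add spatial averager.  All state is integer; a run is
bit-reproducible.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError


class SigmaEstimator:
    """Closed-loop estimator of the noise standard deviation.

    Rather than computing moments, the estimator regulates its output so that
    a fixed fraction of input samples exceeds it.  Per tick::

        if x > est:  est += s_up
        else:        est = max(est - s_dn, floor)

    At equilibrium the exceedance fraction is ``s_dn / (s_up + s_dn)``.  The
    defaults ``s_up = 841``, ``s_dn = 159`` pin it at 15.9 %, the one-sided
    probability that a zero-mean Gaussian sample exceeds +1 sigma, so the
    converged estimate tracks the noise standard deviation of a Gaussian
    channel while remaining largely insensitive to sparse spiking activity.

    The estimate carries ``fraction_bits`` fixed-point fraction bits: the
    update steps are expressed in estimate LSBs of ``2**-fraction_bits``
    sample LSBs.  The equilibrium ripple of the regulator scales with the
    square root of the step size, so the default resolution (14 fraction
    bits) keeps the ripple below a few percent of typical noise amplitudes
    while still converging from a cold start within a few thousand ticks.

    Parameters
    ----------
    s_up, s_dn
        Increment / decrement in estimate LSBs.
    floor
        Minimum estimate, in sample LSBs.
    fraction_bits
        Fixed-point resolution of the estimate (default 14).
    """

    def __init__(
        self,
        s_up: int = 841,
        s_dn: int = 159,
        floor: int = 0,
        fraction_bits: int = 14,
    ):
        if s_up <= 0 or s_dn <= 0:
            raise ConfigurationError("s_up and s_dn must be positive")
        if floor < 0:
            raise ConfigurationError("floor must be >= 0")
        self.s_up = int(s_up)
        self.s_dn = int(s_dn)
        self.fraction_bits = int(fraction_bits)
        self.floor_raw = int(floor) << self.fraction_bits
        self.est_raw = self.floor_raw

    @property
    def estimate(self) -> float:
        """Current estimate in sample LSBs."""
        return self.est_raw / (1 << self.fraction_bits)

    def exceeded(self, x: int) -> bool:
        """Whether ``x`` lies strictly above the current estimate."""
        return (int(x) << self.fraction_bits) > self.est_raw

    def threshold(self, multiplier_q: int, multiplier_bits: int = 8) -> int:
        """Integer threshold ``multiplier * estimate`` in sample LSBs.

        ``multiplier_q`` is the multiplier quantized to ``multiplier_bits``
        fraction bits; the product is truncated to sample LSBs.
        """
        return (multiplier_q * self.est_raw) >> (
            self.fraction_bits + multiplier_bits
        )

    def step(self, x: int) -> int:
        """Advance one tick; returns the raw (fixed-point) estimate."""
        if (int(x) << self.fraction_bits) > self.est_raw:
            self.est_raw += self.s_up
        else:
            est = self.est_raw - self.s_dn
            self.est_raw = est if est > self.floor_raw else self.floor_raw
        return self.est_raw

    def process(self, xs: Iterable[int]) -> int:
        """Run a block; returns the final raw estimate (tight loop)."""
        est = self.est_raw
        s_up, s_dn, floor, fb = self.s_up, self.s_dn, self.floor_raw, self.fraction_bits
        for x in xs:
            if (int(x) << fb) > est:
                est += s_up
            else:
                est -= s_dn
                if est < floor:
                    est = floor
        self.est_raw = est
        return est


class HysteresisComparator:
    """Two-threshold asymmetrical comparator.

    The output asserts when the input reaches ``t_set`` and deasserts when it
    drops below ``t_clear``; between the thresholds it holds its level, which
    suppresses chatter on noisy inputs.  Equal thresholds degenerate to a
    plain comparator ``x >= t``.
    """

    def __init__(self, t_set: int, t_clear: int | None = None):
        if t_clear is None:
            t_clear = t_set
        if t_set < t_clear:
            raise ConfigurationError(
                f"t_set ({t_set}) must be >= t_clear ({t_clear})"
            )
        self.t_set = int(t_set)
        self.t_clear = int(t_clear)
        self.level = False

    def step(self, x: int) -> tuple[bool, bool]:
        """Advance one tick; returns ``(level, rising_edge)``."""
        prev = self.level
        if x >= self.t_set:
            self.level = True
        elif x < self.t_clear:
            self.level = False
        return self.level, self.level and not prev


class LeakyCounter:
    """Event integrator with constant leak and firing threshold.

    Per tick, with input event (or event count) ``x``::

        v = count + x * s_u
        fires (y = 1) iff v >= q
        count <- 0 if fired and reset_on_fire else max(v - s_d, 0)

    The count measures recent activity against a reference rate ``s_d/s_u``
    events per tick.  ``reset_on_fire`` selects between one-shot firing
    (reset to zero, used for synchronization detection) and a free-running
    count (used for burst envelopes, where a hysteresis comparator reads the
    count).
    """

    def __init__(
        self,
        s_u: int = 1,
        s_d: int = 0,
        q: int = 1,
        reset_on_fire: bool = True,
    ):
        if q <= 0:
            raise ConfigurationError("q must be positive")
        if s_u <= 0 or s_d < 0:
            raise ConfigurationError("s_u must be > 0 and s_d >= 0")
        self.s_u = int(s_u)
        self.s_d = int(s_d)
        self.q = int(q)
        self.reset_on_fire = bool(reset_on_fire)
        self.count = 0

    def step(self, x: int) -> tuple[int, bool]:
        """Advance one tick; returns ``(count, fired)``."""
        v = self.count + x * self.s_u
        fired = v >= self.q
        if fired and self.reset_on_fire:
            self.count = 0
        else:
            v -= self.s_d
            self.count = v if v > 0 else 0
        return self.count, fired


class ExtremaDetector:
    """Alternating local maximum / minimum detector with amplitude gate.

    While seeking a maximum, the running maximum ``m_hi`` tracks the input;
    a maximum event is emitted when the signal has dropped at least ``delta``
    below ``m_hi``, at which point the unit re-arms for a minimum (seeded at
    the current sample).  Minimum seeking mirrors this.  Events therefore
    strictly alternate, and ripples smaller than ``delta`` peak-to-peak are
    ignored.

    The running extrema are seeded from the first sample (not zero), so a
    signal with nonzero baseline does not fabricate an initial event.
    ``last_amplitude`` holds the peak-to-peak excursion between the two most
    recent extrema at every event tick, available for amplitude gating.
    """

    def __init__(self, delta: int, seek_max_first: bool = True):
        if delta <= 0:
            raise ConfigurationError("delta must be positive")
        self.delta = int(delta)
        self.seeking_max = bool(seek_max_first)
        self.m_hi = 0
        self.m_lo = 0
        self.last_amplitude = 0
        self._primed = False

    def step(self, x: int) -> tuple[bool, bool]:
        """Advance one tick; returns ``(max_event, min_event)``."""
        if not self._primed:
            self.m_hi = self.m_lo = x
            self._primed = True
            return False, False
        if self.seeking_max:
            if x > self.m_hi:
                self.m_hi = x
            elif x <= self.m_hi - self.delta:
                self.last_amplitude = self.m_hi - self.m_lo
                self.m_lo = x
                self.seeking_max = False
                return True, False
        else:
            if x < self.m_lo:
                self.m_lo = x
            elif x >= self.m_lo + self.delta:
                self.last_amplitude = self.m_hi - self.m_lo
                self.m_hi = x
                self.seeking_max = True
                return False, True
        return False, False


class AvgPlan:
    """Precomputed shift-add plan for averaging ``n_sel`` channels.

    The reciprocal is computed once as a Euclidean division
    ``A = floor(2^W / n_sel)``; the average of a channel sum ``S`` is then the
    shift-add evaluation over the set bits ``a_i`` of ``A``::

        Y = sum_{i : a_i = 1} (S >> (W - i))

    (one arithmetic shift and add per set bit, no divider).  Each term is
    truncated, so the result sits within ``popcount(A)`` LSBs below the exact
    ``A*S/2^W``, which itself is within ``n_sel * max|X| / 2^W`` of the true
    mean.  ``n_sel = 1`` gives ``A = 2^W`` and an exact pass-through.
    """

    def __init__(self, n_sel: int, width: int = 16):
        if n_sel < 1:
            raise ConfigurationError("need at least one selected channel")
        self.n_sel = int(n_sel)
        self.width = int(width)
        self.a = (1 << width) // n_sel
        self.bits = tuple(i for i in range(width + 1) if (self.a >> i) & 1)

    def average(self, total: int) -> int:
        """Shift-add average of the pre-summed selection total."""
        w = self.width
        return sum(total >> (w - i) for i in self.bits)


def spatial_average(
    values: Sequence[int], selection: Sequence[int], width: int = 16
) -> int:
    """Average the selected channels of one frame by shift-add.

    Convenience wrapper constructing the :class:`AvgPlan` for
    ``len(selection)`` channels and applying it to ``sum(values[c])``.
    """
    if len(selection) == 0:
        raise ConfigurationError("selection must not be empty")
    plan = AvgPlan(len(selection), width)
    return plan.average(sum(int(values[c]) for c in selection))


def spatial_average_block(
    frames: np.ndarray, selection: Sequence[int], width: int = 16
) -> np.ndarray:
    """Vectorized shift-add average over a (n_ticks, n_channels) block.

    Matches :func:`spatial_average` bit-for-bit (numpy's right shift on
    signed integers is arithmetic, like Python's).
    """
    sel = list(selection)
    if not sel:
        raise ConfigurationError("selection must not be empty")
    plan = AvgPlan(len(sel), width)
    totals = frames[:, sel].astype(np.int64).sum(axis=1)
    out = np.zeros_like(totals)
    for i in plan.bits:
        out += totals >> (width - i)
    return out
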