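"""Fixed-point streaming filters.

Two filter families cover all frequency shaping in a processing chain:

* A cascade of first-order low-pass sections whose only coefficient is a
  power of two, ``y_n = y_{n-1} (1 - 2^-k) + x_n 2^-k``.  Each section is a
  single shift-and-add per tick; the cutoff is ``Fc = 1 / ((2^k - 1) 2 pi Ts)``
  for shift exponent ``k``.  High-pass output is formed by subtracting a tap
  of the low-pass chain from the input, and band-pass by differencing two
  taps of the chain.
* A stationary (undecimated, "a trous") wavelet transform computing detail
  and approximation coefficients with integer kernels dilated by powers of
  two, used to sharpen spike waveforms against noise before thresholding.

All arithmetic is exact integer arithmetic with arithmetic (floor) shifts, so
a run is bit-reproducible.  Accumulators carry ``GUARD_BITS`` fraction bits
to avoid the dead zone a bare 16-bit implementation of the recurrence would
exhibit at large ``k``; overflow saturates (and is counted) rather than
wrapping.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

from .errors import ConfigurationError

#: Fraction bits kept in every first-order accumulator.  The largest shift
#: exponent is 17, and two extra bits keep the per-tick truncation error
#: below one output LSB without accumulating.
GUARD_BITS = 19

K_MIN, K_MAX = 0, 17
MAX_STAGES = 8


class FirstOrderLowpass:
    """One first-order low-pass section with power-of-two coefficient.

    The recurrence ``y_n = y_{n-1} (1 - 2^-k) + x_n 2^-k`` is evaluated on an
    accumulator holding ``guard_bits`` fraction bits::

        acc <- acc - (acc >> k) + (x << (guard_bits - k));   y = acc >> guard_bits

    ``k = 0`` degenerates to a pass-through (the recurrence keeps no memory).
    DC gain is exactly 1: a constant input converges to itself within 1 LSB.

    Parameters
    ----------
    k
        Shift exponent in ``{0..17}``; larger ``k`` means lower cutoff.
    width
        Sample width in bits; the accumulator saturates at the equivalent
        full-scale value (saturations are counted in ``saturation_count``).
    """

    def __init__(self, k: int, width: int = 16, guard_bits: int = GUARD_BITS):
        if not K_MIN <= k <= K_MAX:
            raise ConfigurationError(f"k must be in {{{K_MIN}..{K_MAX}}}, got {k}")
        if guard_bits < k:
            raise ConfigurationError("guard_bits must be >= k")
        self.k = int(k)
        self.width = int(width)
        self.guard_bits = int(guard_bits)
        self.acc = 0
        self.saturation_count = 0
        self._acc_hi = ((1 << (width - 1)) - 1) << guard_bits
        self._acc_lo = -(1 << (width - 1)) << guard_bits

    def step(self, x: int) -> int:
        x = int(x)  # fixed-width numpy scalars would wrap in the shift
        acc = self.acc
        acc = acc - (acc >> self.k) + (x << (self.guard_bits - self.k))
        if acc > self._acc_hi:
            acc = self._acc_hi
            self.saturation_count += 1
        elif acc < self._acc_lo:
            acc = self._acc_lo
            self.saturation_count += 1
        self.acc = acc
        return acc >> self.guard_bits

    def process(self, xs: Sequence[int]) -> list[int]:
        """Run a whole block through the section (tight scalar loop)."""
        out = []
        append = out.append
        k, g = self.k, self.guard_bits
        acc = self.acc
        hi, lo = self._acc_hi, self._acc_lo
        sat = self.saturation_count
        for x in xs:
            acc = acc - (acc >> k) + (int(x) << (g - k))
            if acc > hi:
                acc = hi
                sat += 1
            elif acc < lo:
                acc = lo
                sat += 1
            append(acc >> g)
        self.acc = acc
        self.saturation_count = sat
        return out

    @property
    def value(self) -> int:
        """Current output (accumulator truncated to sample LSBs)."""
        return self.acc >> self.guard_bits


def cutoff_from_k(k: int, ts: float) -> float:
    """Approximate -3 dB cutoff (Hz) of a section with shift exponent ``k``.

    ``Fc = 1 / ((2^k - 1) 2 pi Ts)``.  ``k = 0`` performs no filtering and has
    no cutoff.
    """
    if k == 0:
        raise ConfigurationError("k=0 is a pass-through; cutoff undefined")
    if not K_MIN < k <= K_MAX:
        raise ConfigurationError(f"k must be in {{1..{K_MAX}}}, got {k}")
    if ts <= 0:
        raise ConfigurationError("sample period must be positive")
    return 1.0 / (((1 << k) - 1) * 2.0 * math.pi * ts)


def k_from_cutoff(fc_target: float, ts: float) -> int:
    """Shift exponent whose cutoff is nearest ``fc_target`` on a log scale.

    Ties resolve to the smaller ``k``; targets outside the achievable range
    return the nearest endpoint with a warning.
    """
    if fc_target <= 0:
        raise ConfigurationError("target cutoff must be positive")
    best_k, best_err = None, None
    for k in range(1, K_MAX + 1):
        err = abs(math.log(cutoff_from_k(k, ts)) - math.log(fc_target))
        if best_err is None or err < best_err - 1e-12:
            best_k, best_err = k, err
    lo = cutoff_from_k(K_MAX, ts)
    hi = cutoff_from_k(1, ts)
    if not lo <= fc_target <= hi:
        warnings.warn(
            f"target cutoff {fc_target:g} Hz outside achievable range "
            f"[{lo:.3g}, {hi:.3g}] Hz; using nearest endpoint k={best_k}",
            stacklevel=2,
        )
    return best_k


class FilterUnit:
    """Series chain of up to 8 first-order sections with LP/HP/BP taps.

    Let ``y[0] = x`` and ``y[j]`` be the cascade output after section ``j``.
    Per tick the unit produces:

    * ``lp = y[lp_tap]`` -- low-pass (``lp_tap = 0`` passes the input),
    * ``hp = x - y[hp_tap]`` -- high-pass (``hp_tap = 0`` disables the
      subtraction and passes the input),
    * ``bp = y[lp_tap] - y[hp_tap]`` -- band-pass when both taps are active;
      ``hp_tap`` must then sit deeper in the chain than ``lp_tap`` so its
      cumulative cutoff forms the low edge of the band.

    HP and BP outputs saturate to the sample width (differences can
    transiently exceed full scale by one bit).
    """

    PORTS = ("lp", "hp", "bp")

    def __init__(
        self,
        k_list: Sequence[int],
        hp_tap: int = 0,
        lp_tap: int = 0,
        width: int = 16,
    ):
        if not 1 <= len(k_list) <= MAX_STAGES:
            raise ConfigurationError(
                f"filter unit takes 1..{MAX_STAGES} sections, got {len(k_list)}"
            )
        n = len(k_list)
        if not (0 <= hp_tap <= n and 0 <= lp_tap <= n):
            raise ConfigurationError(
                f"taps must be in 0..{n} (number of sections), got "
                f"hp_tap={hp_tap}, lp_tap={lp_tap}"
            )
        if hp_tap == 0 and lp_tap == 0:
            raise ConfigurationError("at least one of hp_tap/lp_tap must be active")
        if hp_tap and lp_tap and hp_tap <= lp_tap:
            raise ConfigurationError(
                "band-pass needs hp_tap deeper in the chain than lp_tap"
            )
        self.stages = [FirstOrderLowpass(k, width=width) for k in k_list]
        self.hp_tap = int(hp_tap)
        self.lp_tap = int(lp_tap)
        self.width = int(width)
        self._hi = (1 << (width - 1)) - 1
        self._lo = -(1 << (width - 1))
        self.saturation_count = 0

    def _sat(self, v: int) -> int:
        if v > self._hi:
            self.saturation_count += 1
            return self._hi
        if v < self._lo:
            self.saturation_count += 1
            return self._lo
        return v

    def set_stage_k(self, index: int, k: int) -> None:
        """Retarget one section's cutoff; its accumulator is preserved."""
        if not K_MIN <= k <= K_MAX:
            raise ConfigurationError(f"k must be in {{{K_MIN}..{K_MAX}}}, got {k}")
        self.stages[index].k = int(k)

    def step(self, x: int) -> tuple[int, int, int]:
        y = x
        taps = [x]
        for stage in self.stages:
            y = stage.step(y)
            taps.append(y)
        lp = taps[self.lp_tap]
        hp = self._sat(x - taps[self.hp_tap]) if self.hp_tap else x
        if self.hp_tap:
            bp = self._sat(taps[self.lp_tap] - taps[self.hp_tap])
        else:
            bp = lp
        return lp, hp, bp

    def process(self, xs: Sequence[int]) -> tuple[list[int], list[int], list[int]]:
        lps, hps, bps = [], [], []
        for x in xs:
            lp, hp, bp = self.step(x)
            lps.append(lp)
            hps.append(hp)
            bps.append(bp)
        return lps, hps, bps


HAAR_G = (1, -1)
HAAR_H = (1, 1)


class StationaryWaveletTransform:
    """Causal streaming stationary (a trous) wavelet transform.

    At level ``j`` (1-based) the detail and approximation coefficients are
    integer convolutions of the previous level's approximation sequence with
    kernels ``g`` / ``h`` dilated by a power of two::

        d[j]_n = (sum_k g[k] * a[j-1]_{n - D_j k}) >> log2(coeff_scale)
        a[j]_n = (sum_k h[k] * a[j-1]_{n - D_j k}) >> log2(coeff_scale)

    with ``a[0]_n = x_n``.  Two dilation conventions are supported:
    ``"paper"`` uses ``D_j = 2^j`` and ``"textbook"`` the classical
    ``D_j = 2^(j-1)``; they differ only in how fast the kernels stretch with
    level.  Delay lines start zero-filled (power-on reset).

    The default mother wavelet is Haar with integer kernels ``g = (1, -1)``,
    ``h = (1, 1)`` and ``coeff_scale = 2``.
    """

    def __init__(
        self,
        levels: int,
        g: Sequence[int] = HAAR_G,
        h: Sequence[int] = HAAR_H,
        coeff_scale: int = 2,
        dilation_convention: str = "paper",
    ):
        if levels < 1:
            raise ConfigurationError("levels must be >= 1")
        if len(g) != len(h):
            raise ConfigurationError("g and h must have the same length")
        if len(g) < 2:
            raise ConfigurationError("kernels need at least 2 coefficients")
        if coeff_scale < 1 or coeff_scale & (coeff_scale - 1):
            raise ConfigurationError("coeff_scale must be a power of two")
        if dilation_convention not in ("paper", "textbook"):
            raise ConfigurationError(
                "dilation_convention must be 'paper' or 'textbook'"
            )
        self.levels = int(levels)
        self.g = tuple(int(c) for c in g)
        self.h = tuple(int(c) for c in h)
        self.coeff_scale = int(coeff_scale)
        self._shift = coeff_scale.bit_length() - 1
        self.dilation_convention = dilation_convention
        self._taps = len(self.g) - 1  # L: highest kernel index
        self._dil = [
            (1 << j) if dilation_convention == "paper" else (1 << (j - 1))
            for j in range(1, levels + 1)
        ]
        # ring buffer per level over the previous level's approximations
        self._buflen = [d * self._taps + 1 for d in self._dil]
        self._buf = [[0] * n for n in self._buflen]
        self._pos = [0] * levels

    def step(self, x: int) -> tuple[list[int], int]:
        """Advance one tick; returns (details d[1..J], approximation a[J])."""
        a_prev = x
        details = []
        shift = self._shift
        for j in range(self.levels):
            buf = self._buf[j]
            n = self._buflen[j]
            pos = self._pos[j]
            buf[pos] = a_prev
            d_acc = 0
            a_acc = 0
            dil = self._dil[j]
            for k in range(self._taps + 1):
                v = buf[(pos - dil * k) % n]
                d_acc += self.g[k] * v
                a_acc += self.h[k] * v
            self._pos[j] = (pos + 1) % n
            details.append(d_acc >> shift)
            a_prev = a_acc >> shift
        return details, a_prev

    def process(self, xs: Sequence[int]) -> tuple[list[list[int]], list[int]]:
        """Block form: returns (details per level [J][n], approximations [n])."""
        d_out: list[list[int]] = [[] for _ in range(self.levels)]
        a_out: list[int] = []
        for x in xs:
            d, a = self.step(x)
            for j in range(self.levels):
                d_out[j].append(d[j])
            a_out.append(a)
        return d_out, a_out
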