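"""Latency and memory cost model of the processing units.

The hardware realization of each unit has a fixed, input-independent cost:
processing latency in clock cycles (affine in the channel count ``N``) and,
for the combined functions, a memory footprint in bits.  This module
evaluates those documented affine formulas; it does not measure anything.

Elementary units
----------------
========================  =======================
kind                      cycles
========================  =======================
filter_unit / lowpass     ``2 N k + 2`` (k sections)
swt                       ``7 N`` .. ``65 N`` (mother-wavelet dependent)
sigma                     ``9 N + 4``
hysteresis                ``4 N``
leaky_counter             ``N``
extrema                   ``6 N + 1``
spatial_avg               ``N + W + 1``
========================  =======================

Combined units carry both cycles and memory bits; ranged rows (the wavelet
variants) take a ``bound`` parameter selecting the ``"min"`` or ``"max"``
end of the documented range (default ``"max"``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnsupportedCostError


@dataclass(frozen=True)
class CostEstimate:
    """Clock-cycle latency and memory footprint of one unit.

    ``cycles`` is ``None`` for units whose latency depends on external
    equipment (stimulation control); ``note`` carries caveats.
    """

    cycles: int | None
    memory_bits: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.cycles is not None and self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.memory_bits is not None and self.memory_bits < 0:
            raise ValueError("memory_bits must be >= 0")


def _bound(params: dict, lo: int, hi: int) -> int:
    which = (params or {}).get("bound", "max")
    if which not in ("min", "max"):
        raise UnsupportedCostError("bound must be 'min' or 'max'")
    return lo if which == "min" else hi


def estimate_cost(kind: str, n_channels: int, params: dict | None = None) -> CostEstimate:
    """Evaluate the documented latency/memory formula for a unit kind.

    Parameters
    ----------
    kind
        A chain unit kind (``sigma``, ``leaky_counter``, ``ap_detect``, ...).
    n_channels
        Channel count ``N`` (>= 1).
    params
        Kind-specific extras: ``k`` section count for filters, ``width`` for
        the averager, ``variant`` for AP detection, ``bound`` for ranged
        rows, ``s`` stimulation-channel count for the trigger router.
    """
    if n_channels < 1:
        raise UnsupportedCostError("n_channels must be >= 1")
    n = int(n_channels)
    p = params or {}

    if kind in ("filter_unit", "lowpass_chain"):
        k = int(p.get("k", 1))
        return CostEstimate(2 * n * k + 2)
    if kind == "swt":
        return CostEstimate(
            _bound(p, 7 * n, 65 * n), note="mother-wavelet dependent range"
        )
    if kind == "sigma":
        return CostEstimate(9 * n + 4)
    if kind == "hysteresis":
        return CostEstimate(4 * n)
    if kind == "leaky_counter":
        return CostEstimate(n)
    if kind == "extrema":
        return CostEstimate(6 * n + 1)
    if kind == "spatial_avg":
        w = int(p.get("width", 16))
        return CostEstimate(n + w + 1)

    if kind in ("ap_detect", "lfp_detect"):
        variant = p.get("variant", "linear")
        if variant == "wavelet":
            return CostEstimate(
                _bound(p, 16 * n + 4, 74 * n + 4),
                _bound(p, 256 * n, 16_512 * n),
                note="mother-wavelet dependent range",
            )
        return CostEstimate(16 * n + 6, 512 * n)
    if kind == "burst_detect":
        return CostEstimate(
            4 * n,
            128 * n * 216,
            note="memory figure documented as '128N x 216'; transcribed verbatim, "
            "possibly 128N x 2^16",
        )
    if kind == "sync_detect":
        return CostEstimate(4 * n + 1, 8 * n)
    if kind in ("event_freq", "fopp"):
        return CostEstimate(9, 72 * n)
    if kind == "sp_detect":
        return CostEstimate(7 * n + 1, 48 * n)
    if kind == "sorter":
        return CostEstimate(9 * n + 3, 152 * n)
    if kind == "router":
        s = int(p.get("s", 1))
        return CostEstimate(
            None, 14 + 4 * s, note="latency is stimulation-equipment dependent"
        )
    raise UnsupportedCostError(f"no documented cost formula for kind {kind!r}")


def chain_cost(chain) -> dict[str, CostEstimate]:
    """Per-unit cost report for a built chain (best-effort parameters)."""
    report = {}
    for desc in chain.config.units:
        params = dict(desc.params)
        if desc.kind in ("filter_unit", "lowpass_chain") and "k_list" in params:
            params["k"] = len(params["k_list"])
        try:
            report[desc.unit_id] = estimate_cost(
                desc.kind, chain.config.n_channels, params
            )
        except UnsupportedCostError:
            report[desc.unit_id] = CostEstimate(None, None, note="no documented formula")
    return report
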