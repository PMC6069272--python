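"""Stream a recording through a chain and collect event/trigger logs."""

from __future__ import annotations

from typing import Iterable, Sequence

from .chain import Chain
from .io import EventRecord

#: Mapping (unit kind, port) -> event-log type for the standard detectors.
EVENT_PORT_TYPES = {
    ("ap_detect", "event"): "AP",
    ("lfp_detect", "event"): "LFP",
    ("sp_detect", "event"): "SP",
    ("burst_detect", "start"): "BURST_START",
    ("burst_detect", "end"): "BURST_END",
    ("sync_detect", "event"): "SYNC",
}

#: Channel index used for network-wide (cross-channel) events.
NETWORK_CHANNEL = -1


def stream_events(
    chain: Chain, frames: Iterable[Sequence[int]]
) -> list[EventRecord]:
    """Run ``frames`` through ``chain`` and return the event log.

    Tapped boolean streams from the standard detector kinds are logged under
    their conventional type names (AP, LFP, SP, BURST_START/END, SYNC);
    other tapped boolean streams are logged under ``"unit.port"``.
    Cross-channel events (synchronization) use channel ``-1``.
    """
    records: list[EventRecord] = []
    kind_of = {uid: unit.kind for uid, unit in chain.units.items()}
    for values in frames:
        tick = chain.tick
        outputs = chain.step(values)
        for key, vec in outputs.items():
            uid, port = key.split(".", 1)
            etype = EVENT_PORT_TYPES.get((kind_of[uid], port))
            if etype is None:
                if not (
                    isinstance(vec, list) and vec and isinstance(vec[0], bool)
                ):
                    continue
                etype = key
            if len(vec) == 1 and kind_of[uid] == "sync_detect":
                if vec[0]:
                    records.append(EventRecord(tick, NETWORK_CHANNEL, etype))
                continue
            for ch, flag in enumerate(vec):
                if flag:
                    records.append(EventRecord(tick, ch, etype))
    return records
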