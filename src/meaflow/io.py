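"""Readers and writers for raw recordings, event logs, and chain configs,
plus the recording data-rate/capacity calculator.

Raw recordings are interleaved little-endian signed 16-bit samples,
channel-major within each frame (the layout an acquisition front-end streams
to storage), with a JSON sidecar describing channel count, sampling rate and
amplifier gain.  Event and trigger logs are plain CSV.  All round trips are
lossless at the integer level.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from .chain import ChainConfig
from .errors import ConfigurationError, DataError

GAIN_CODES = (0, 1, 2, 5, 10, 20, 50, 100)

EVENT_TYPES = ("AP", "LFP", "SP", "SP_MAX", "SP_MIN", "BURST_START", "BURST_END", "SYNC")


@dataclass
class RawRecordingHeader:
    """Sidecar metadata of a raw recording."""

    n_channels: int
    sample_rate_hz: float
    bit_depth: int = 16
    gain_code: int = 1
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth != 16:
            raise ConfigurationError("bit_depth is fixed at 16")
        if self.gain_code not in GAIN_CODES:
            raise ConfigurationError(
                f"gain_code must be one of {GAIN_CODES}, got {self.gain_code}"
            )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raw(path, header: RawRecordingHeader, frames) -> RawRecordingHeader:
    """Write frames as interleaved int16; returns the header with the
    actual frame count filled in.

    ``frames`` may be an iterable of per-tick channel vectors or a
    ``(n_ticks, n_channels)`` array.
    """
    path = Path(path)
    arr = np.asarray(list(frames) if not isinstance(frames, np.ndarray) else frames)
    if arr.size and arr.ndim != 2:
        raise DataError("frames must be 2-D (ticks x channels)")
    if arr.size and arr.shape[1] != header.n_channels:
        raise DataError(
            f"frames have {arr.shape[1]} channels, header says {header.n_channels}"
        )
    arr = arr.astype("<i2") if arr.size else np.empty((0, header.n_channels), "<i2")
    arr.tofile(path)
    header = RawRecordingHeader(**{**asdict(header), "n_frames": arr.shape[0]})
    _sidecar(path).write_text(json.dumps(asdict(header), indent=1))
    return header


def read_raw(path) -> tuple[RawRecordingHeader, Iterator[np.ndarray]]:
    """Read a raw recording; returns (header, frame iterator).

    A file whose byte length is not a whole number of frames raises
    :class:`DataError` reporting the number of complete frames present.
    """
    path = Path(path)
    header = RawRecordingHeader(**json.loads(_sidecar(path).read_text()))
    data = np.fromfile(path, dtype="<i2")
    frame_len = header.n_channels
    n_complete, remainder = divmod(data.size, frame_len)
    if remainder:
        raise DataError(
            f"truncated raw file: {n_complete} complete frames, "
            f"{remainder} trailing samples"
        )
    if n_complete != header.n_frames:
        raise DataError(
            f"header says {header.n_frames} frames, file holds {n_complete}"
        )
    frames = data.reshape(n_complete, frame_len)
    return header, iter(frames)


def read_raw_array(path) -> tuple[RawRecordingHeader, np.ndarray]:
    """Read a whole raw recording into a (n_ticks, n_channels) array."""
    header, frames = read_raw(path)
    return header, np.array(list(frames), dtype=np.int16).reshape(
        header.n_frames, header.n_channels
    )


@dataclass(frozen=True)
class EventRecord:
    """One detected event: (tick, channel, type, value)."""

    tick: int
    channel: int
    type: str
    value: float = 0.0


def write_events(path, records: Iterable[EventRecord]) -> int:
    """Write an event log as CSV with header; returns the record count."""
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tick", "channel", "type", "value"])
        for rec in records:
            writer.writerow([rec.tick, rec.channel, rec.type, rec.value])
            n += 1
    return n


def read_events(path) -> list[EventRecord]:
    """Read an event log; malformed rows raise :class:`DataError` with the
    line number, non-monotone ticks emit a warning."""
    records: list[EventRecord] = []
    last_tick = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["tick", "channel", "type", "value"]:
            raise DataError(f"unexpected event-log header: {header}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = EventRecord(int(row[0]), int(row[1]), row[2], float(row[3]))
            except (IndexError, ValueError) as exc:
                raise DataError(f"malformed event row at line {lineno}: {row}") from exc
            if last_tick is not None and rec.tick < last_tick:
                warnings.warn(
                    f"non-monotone tick at line {lineno}: {rec.tick} < {last_tick}",
                    stacklevel=2,
                )
            last_tick = rec.tick
            records.append(rec)
    return records


def write_param_log(path, param_log) -> int:
    """Write a chain's applied-parameter-update records as CSV.

    Each record is (tick, unit_id, name, value): the tick is the first one
    at which the new value was in effect.
    """
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tick", "unit", "param", "value"])
        for tick, unit, name, value in param_log:
            writer.writerow([tick, unit, name, value])
            n += 1
    return n


# --------------------------------------------------------------------------
# Chain config files


def load_chain_config(path) -> ChainConfig:
    """Load a chain configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not hold a mapping")
    return ChainConfig.from_dict(data)


def save_chain_config(config: ChainConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# --------------------------------------------------------------------------
# Recording budget

MIB = float(1 << 20)


def recording_budget(
    n_channels: int,
    rate_hz: float,
    bit_depth: int = 16,
    card_bytes: int | None = None,
) -> tuple[float, float | None]:
    """Raw data rate and recording capacity.

    Returns ``(rate_mb_per_min, max_minutes)`` where the rate is in binary
    megabytes (2^20 bytes) per minute -- 64 channels at 10 kHz, 16 bit give
    73.24 MB/min -- and ``max_minutes`` is how long ``card_bytes`` of storage
    sustains that rate (``None`` if no card size is given).
    """
    if n_channels <= 0 or rate_hz <= 0 or bit_depth <= 0:
        raise ConfigurationError("budget arguments must be positive")
    bytes_per_s = n_channels * rate_hz * bit_depth / 8.0
    rate_mb_per_min = bytes_per_s * 60.0 / MIB
    max_minutes = None
    if card_bytes is not None:
        if card_bytes <= 0:
            raise ConfigurationError("card_bytes must be positive")
        max_minutes = card_bytes / bytes_per_s / 60.0
    return rate_mb_per_min, max_minutes
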