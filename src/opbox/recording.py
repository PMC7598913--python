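"""On-disk recording format.

Each subject's recording is three sibling files:

* ``<name>.obx``  -- raw payload: little-endian float32, interleaved frames
  (one frame = one sample of every channel), append-friendly;
* ``<name>.json`` -- sidecar header: format version, subject metadata,
  sampling rate, channel names and units, device-clock start time;
* ``<name>_events.csv`` -- events as ``time_s,channel,label`` rows.

The payload carries no length field; the sample count is the file size
divided by the frame size, and a file whose size is not a whole number of
frames is reported as corrupt with the byte offset of the first incomplete
frame rather than silently truncated.  This layout is this package's own; it
is not claimed compatible with any other acquisition system's files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CorruptRecordingError, StateError, ValidationError

FORMAT_VERSION = 1
_DTYPE = np.dtype("<f4")

EVENT_COLUMNS = ["time_s", "channel", "label"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events.csv")


class RecordingWriter:
    """Incremental writer: open, append sample blocks and events, close.

    ``metadata`` must contain ``channel_names`` (list of str) and ``fs``; any
    other JSON-serializable keys (subject id, box id, units, device-clock
    start time...) are stored verbatim in the sidecar.
    """

    def __init__(self, path, metadata: dict):
        if "channel_names" not in metadata or "fs" not in metadata:
            raise ValidationError("metadata requires 'channel_names' and 'fs'")
        self.path = Path(path)
        self.metadata = dict(metadata)
        self.metadata.setdefault("format_version", FORMAT_VERSION)
        self.n_channels = len(self.metadata["channel_names"])
        if self.n_channels == 0:
            raise ValidationError("need at least one channel")
        self.n_samples = 0
        self._events = []
        self.path.parent.mkdir(parents=True, exist_ok=True)
        _sidecar_path(self.path).write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True) + "\n")
        self._fh = open(self.path, "wb")

    def write_block(self, samples: np.ndarray) -> None:
        if self._fh is None:
            raise StateError("writer already closed")
        block = np.atleast_2d(np.asarray(samples))
        if block.shape[1] != self.n_channels:
            raise ValidationError(
                f"block has {block.shape[1]} channels, header says {self.n_channels}")
        self._fh.write(np.ascontiguousarray(block, dtype=_DTYPE).tobytes())
        self.n_samples += block.shape[0]

    def add_event(self, time_s: float, channel: str, label: str) -> None:
        self._events.append({"time_s": float(time_s), "channel": str(channel),
                             "label": str(label)})

    def close(self) -> Path:
        if self._fh is not None:
            self._fh.close()
            self._fh = None
            pd.DataFrame(self._events, columns=EVENT_COLUMNS).to_csv(
                _events_path(self.path), index=False)
        return self.path

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


@dataclass
class Recording:
    """An in-memory recording: sidecar metadata, samples, events."""

    metadata: dict
    samples: np.ndarray          # (n_samples, n_channels) float32
    events: pd.DataFrame

    @property
    def fs(self) -> float:
        return float(self.metadata["fs"])

    @property
    def channel_names(self) -> list:
        return list(self.metadata["channel_names"])

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.fs


def write_recording(path, metadata: dict, samples: np.ndarray,
                    events: Optional[Sequence] = None) -> Path:
    """One-shot write of a complete recording (see :class:`RecordingWriter`).

    ``events`` is an iterable of ``(time_s, channel, label)`` tuples.
    """
    with RecordingWriter(path, metadata) as w:
        w.write_block(samples)
        for t, ch, label in (events or []):
            w.add_event(t, ch, label)
    return Path(path)


def read_recording(path) -> Recording:
    """Read a recording back; the inverse of :func:`write_recording`.

    Raises :class:`CorruptRecordingError` (with the byte offset of the first
    incomplete frame) if the payload is not frame-aligned.
    """
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    n_ch = len(meta["channel_names"])
    frame_bytes = n_ch * _DTYPE.itemsize
    size = os.path.getsize(path)
    rem = size % frame_bytes
    if rem:
        raise CorruptRecordingError(
            f"{path}: payload size {size} is not a whole number of "
            f"{frame_bytes}-byte frames", byte_offset=size - rem)
    samples = np.fromfile(path, dtype=_DTYPE).reshape(-1, n_ch)
    ev_path = _events_path(path)
    if ev_path.exists():
        events = pd.read_csv(ev_path, dtype={"channel": str, "label": str})
        if events.empty:
            events = pd.DataFrame(columns=EVENT_COLUMNS)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return Recording(metadata=meta, samples=samples, events=events)
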