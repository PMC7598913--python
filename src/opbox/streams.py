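"""Chunked stream processing: dispatch, events, ERP, spectra, encoder, video.

The acquisition backend (simulated here, hardware behind the same interface
elsewhere) delivers :class:`DeviceChunk` objects -- contiguous blocks of all
channels of one device at the update cadence (default 10 Hz).
:func:`dispatch_chunk` slices each chunk sample-exactly into per-subject
blocks according to the routing plan; the streaming accumulators (ERP
averaging, real-time spectra) are written so that streaming over chunks gives
bit-identical results to batch computation on the whole record.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .errors import StreamIntegrityError, ValidationError
from .routing import RoutingPlan
from .trace import DigitalTrace, SignalTrace


# ---------------------------------------------------------------------------
# device chunks and dispatch
# ---------------------------------------------------------------------------

@dataclass
class DeviceChunk:
    """One contiguous block of every channel of one device.

    ``start_index`` is the 0-based sample index of the first frame on the
    device clock; consecutive chunks must be contiguous (no gaps, no overlap).
    """

    device_id: str
    start_index: int
    analog: np.ndarray    # (n_samples, n_device_analog_channels)
    digital: np.ndarray   # (n_samples, n_device_digital_channels) bool
    fs: float

    def __post_init__(self):
        self.analog = np.atleast_2d(np.asarray(self.analog))
        self.digital = np.atleast_2d(np.asarray(self.digital, dtype=bool))
        if self.analog.shape[0] != self.digital.shape[0] and self.digital.size:
            raise ValidationError("analog/digital blocks differ in length")

    @property
    def n_samples(self) -> int:
        return self.analog.shape[0]


@dataclass
class SubjectBlock:
    """The slice of one chunk belonging to one subject."""

    subject_id: str
    sample_index: int        # index of first sample on the subject's own clock
    analog: np.ndarray       # (n_samples, n_subject_analog_channels)
    digital: np.ndarray      # (n_samples, n_subject_digital_channels) bool
    fs: float


def dispatch_chunk(plan: RoutingPlan, chunk: DeviceChunk) -> dict:
    """Slice a device chunk into per-subject blocks, sample-exactly.

    Only subjects that have been started receive data, and only the samples
    inside their [start, stop) interval; sample 0 on the subject clock is the
    first sample at or after the subject's start time.  Concatenating the
    blocks a subject receives reconstructs its stream bit-exactly.
    """
    if plan.devices is not None and chunk.device_id not in plan.devices:
        raise ValidationError(f"chunk from unknown device {chunk.device_id!r}")
    out = {}
    c0 = chunk.start_index
    c1 = c0 + chunk.n_samples
    for sub in plan.subjects_on_device(chunk.device_id):
        s0 = sub.start_sample(chunk.fs)
        if s0 is None:
            continue
        s1 = sub.stop_sample(chunk.fs)
        a = max(c0, s0)
        b = c1 if s1 is None else min(c1, s1)
        if a >= b:
            continue
        box = plan.boxes[sub.box_id]
        analog = chunk.analog[a - c0:b - c0][:, list(box.analog_channels)]
        dig_cols = list(box.digital_channels)
        if dig_cols and chunk.digital.size:
            digital = chunk.digital[a - c0:b - c0][:, dig_cols]
        else:
            digital = np.empty((b - a, 0), dtype=bool)
        out[sub.subject_id] = SubjectBlock(
            subject_id=sub.subject_id, sample_index=a - s0,
            analog=analog, digital=digital, fs=chunk.fs)
    return out


class DeviceStreamTracker:
    """Checks chunk contiguity per device; a gap marks the stream discontinuous."""

    def __init__(self):
        self.next_index = {}
        self.discontinuous = set()

    def check(self, chunk: DeviceChunk) -> None:
        expected = self.next_index.get(chunk.device_id)
        if expected is not None and chunk.start_index != expected:
            self.discontinuous.add(chunk.device_id)
            self.next_index[chunk.device_id] = chunk.start_index + chunk.n_samples
            raise StreamIntegrityError(
                f"device {chunk.device_id!r}: expected sample {expected}, "
                f"got {chunk.start_index}")
        self.next_index[chunk.device_id] = chunk.start_index + chunk.n_samples


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_onsets(trace: SignalTrace, threshold: Optional[float] = None,
                  refractory_s: float = 0.0) -> np.ndarray:
    """Rising-threshold crossings of an analog event stream.

    The default threshold is 1.5x the median sample value.  An optional
    refractory period suppresses re-triggering; half the minimum expected
    off-time is a sensible choice when the schedule is known.  Returns onset
    times in seconds on the trace's clock; a constant trace has no events.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size == 0:
        raise ValidationError("empty trace")
    thr = 1.5 * float(np.median(x)) if threshold is None else threshold
    above = x > thr
    rising = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if refractory_s > 0 and rising.size:
        keep = [int(rising[0])]
        min_gap = refractory_s * trace.fs
        for i in rising[1:]:
            if i - keep[-1] >= min_gap:
                keep.append(int(i))
        rising = np.array(keep)
    return trace.t0 + rising / trace.fs


# ---------------------------------------------------------------------------
# event-related potential accumulation
# ---------------------------------------------------------------------------

class ERPAccumulator:
    """Running sum of event-locked windows, per channel.

    The window is ``pre_samples`` before the event plus ``post_samples`` at
    and after it (default 0.1 s + 0.9 s at 1 kHz = a 1-s total window with the
    event at sample ``pre_samples``).  ``mean()`` is sum/count; events whose
    window falls outside the available data are skipped and counted.
    """

    def __init__(self, n_channels: int, pre_samples: int, post_samples: int):
        if n_channels <= 0 or pre_samples < 0 or post_samples <= 0:
            raise ValidationError("need n_channels>0, pre>=0, post>0")
        self.n_channels = n_channels
        self.pre_samples = int(pre_samples)
        self.post_samples = int(post_samples)
        self.sum = np.zeros((n_channels, self.window_samples))
        self.count = 0
        self.skipped = 0

    @property
    def window_samples(self) -> int:
        return self.pre_samples + self.post_samples

    def add_window(self, window: np.ndarray) -> None:
        window = np.asarray(window)
        if window.shape != (self.n_channels, self.window_samples):
            raise ValidationError(
                f"window shape {window.shape} != "
                f"({self.n_channels}, {self.window_samples})")
        self.sum += window
        self.count += 1

    def mean(self) -> Optional[np.ndarray]:
        if self.count == 0:
            return None
        return self.sum / self.count

    def update(self, samples: np.ndarray, fs: float, t0: float,
               event_times: Sequence[float]) -> "ERPAccumulator":
        """Batch update: accumulate every event whose window lies fully inside
        ``samples`` (shape (n_channels, n)); others are skipped and counted."""
        samples = np.atleast_2d(samples)
        n = samples.shape[1]
        for ev in np.sort(np.asarray(event_times, dtype=float)):
            i = int(round((ev - t0) * fs))
            w0, w1 = i - self.pre_samples, i + self.post_samples
            if w0 < 0 or w1 > n:
                self.skipped += 1
            else:
                self.add_window(samples[:, w0:w1])
        return self


class StreamingERP:
    """Feed an :class:`ERPAccumulator` from a chunked stream.

    Blocks arrive in order via :meth:`push`; event times (seconds on the same
    clock as the stream, which starts at sample 0 = time ``t0``) may arrive at
    any point before or while their window's data arrives.  A tail of
    window-length - 1 samples is retained so windows spanning chunk
    boundaries come out bit-identical to a batch computation.  Call
    :meth:`finalize` at end of stream to count events with incomplete windows
    as skipped.
    """

    def __init__(self, acc: ERPAccumulator, fs: float, t0: float = 0.0):
        self.acc = acc
        self.fs = fs
        self.t0 = t0
        self._tail = np.zeros((acc.n_channels, 0))
        self._tail_start = 0          # absolute index of first retained sample
        self._next_index = 0          # absolute index of next sample to arrive
        self._pending = deque()

    def add_events(self, event_times: Sequence[float]) -> None:
        for ev in np.asarray(event_times, dtype=float):
            self._pending.append(int(round((ev - self.t0) * self.fs)))

    def push(self, block: np.ndarray) -> None:
        block = np.atleast_2d(block)
        data = np.concatenate([self._tail, block], axis=1)
        data_start = self._tail_start
        end = self._next_index + block.shape[1]
        while self._pending:
            i = self._pending[0]
            w0, w1 = i - self.acc.pre_samples, i + self.acc.post_samples
            if w1 > end:
                break
            self._pending.popleft()
            if w0 < 0 or w0 < data_start:
                self.acc.skipped += 1
            else:
                self.acc.add_window(data[:, w0 - data_start:w1 - data_start])
        keep = min(self.acc.window_samples - 1, data.shape[1])
        self._tail = data[:, data.shape[1] - keep:]
        self._tail_start = end - keep
        self._next_index = end

    def finalize(self) -> ERPAccumulator:
        self.acc.skipped += len(self._pending)
        self._pending.clear()
        return self.acc


# ---------------------------------------------------------------------------
# real-time spectra
# ---------------------------------------------------------------------------

class RingBuffer:
    """Fixed-capacity sample buffer holding the most recent samples."""

    def __init__(self, capacity: int):
        if capacity <= 0:
            raise ValidationError("capacity must be positive")
        self.capacity = int(capacity)
        self._chunks = deque()
        self._n = 0

    def push(self, samples: np.ndarray) -> None:
        samples = np.asarray(samples, dtype=float).ravel()
        self._chunks.append(samples)
        self._n += samples.size
        while self._n - self._chunks[0].size >= self.capacity:
            self._n -= self._chunks.popleft().size

    @property
    def n(self) -> int:
        return min(self._n, self.capacity)

    @property
    def is_full(self) -> bool:
        return self._n >= self.capacity

    def data(self) -> np.ndarray:
        if not self._chunks:
            return np.empty(0)
        joined = np.concatenate(list(self._chunks))
        return joined[-self.capacity:] if joined.size > self.capacity else joined


@dataclass
class SpectrumEstimate:
    """0-100 Hz (by default) log-power spectrum of the most recent window."""

    freqs_hz: np.ndarray
    log10_power: np.ndarray
    window_s: float


def realtime_spectrum(buffer, fs: float, band_hz=(0.0, 100.0),
                      window_s: float = 5.0) -> Optional[SpectrumEstimate]:
    """Hann-windowed power spectrum of the last ``window_s`` seconds,
    restricted to ``band_hz``, as log10 power.

    ``buffer`` is a :class:`RingBuffer` or a plain sample array.  Returns
    ``None`` (not ready) until a full analysis window is available.
    """
    x = buffer.data() if isinstance(buffer, RingBuffer) else np.asarray(buffer, float)
    nwin = int(round(window_s * fs))
    if x.size < nwin:
        return None
    f, p = sps.periodogram(x[-nwin:], fs, window="hann")
    mask = (f >= band_hz[0]) & (f <= band_hz[1])
    return SpectrumEstimate(freqs_hz=f[mask],
                            log10_power=np.log10(p[mask] + np.finfo(float).tiny),
                            window_s=window_s)


# ---------------------------------------------------------------------------
# quadrature decoding
# ---------------------------------------------------------------------------

_QUAD_INDEX = {(0, 0): 0, (1, 0): 1, (1, 1): 2, (0, 1): 3}  # forward order


@dataclass
class QuadratureDecode:
    """Cumulative x4 position counts plus a tally of invalid transitions."""

    counts: np.ndarray
    invalid_transitions: int
    fs: float
    t0: float = 0.0


def decode_quadrature(a: DigitalTrace, b: DigitalTrace) -> QuadratureDecode:
    """x4 state-machine decode of a quadrature pair.

    Each valid transition moves the count by +-1; a double step (both lines
    flipping between samples) is ambiguous, contributes nothing, and is
    counted in ``invalid_transitions``.  Swapping A and B negates the counts.
    """
    if a.fs != b.fs or a.n != b.n:
        raise ValidationError("A and B must share fs and length")
    av = np.asarray(a.samples, dtype=np.int8)
    bv = np.asarray(b.samples, dtype=np.int8)
    # forward cycle (0,0)->(1,0)->(1,1)->(0,1), indexed by 2*A + B
    idx = np.array([0, 3, 1, 2], dtype=np.int8)[2 * av + bv]
    d = np.mod(np.diff(idx), 4)
    step = np.where(d == 1, 1, np.where(d == 3, -1, 0))
    invalid = int(np.count_nonzero(d == 2))
    counts = np.concatenate([[0], np.cumsum(step)]).astype(np.int64)
    return QuadratureDecode(counts=counts, invalid_transitions=invalid,
                            fs=a.fs, t0=a.t0)


# ---------------------------------------------------------------------------
# video synchronization
# ---------------------------------------------------------------------------

class VideoSyncRecord:
    """(device-clock time, frame index) pairs registered at each data update.

    Times must be strictly increasing and frame indices non-decreasing; the
    per-frame timestamps are recovered afterwards by piecewise-linear
    interpolation between registrations.
    """

    def __init__(self):
        self.times = []
        self.frames = []

    def register(self, daq_time_s: float, frame_index: int) -> "VideoSyncRecord":
        if self.times and daq_time_s <= self.times[-1]:
            raise StreamIntegrityError("registration times must strictly increase")
        if self.frames and frame_index < self.frames[-1]:
            raise StreamIntegrityError("frame indices must be non-decreasing")
        self.times.append(float(daq_time_s))
        self.frames.append(int(frame_index))
        return self


def interpolate_frame_times(sync: VideoSyncRecord):
    """Per-frame timestamps between the first and last registered frames.

    Returns ``(frame_indices, times_s)``.  For each registered frame index the
    earliest registration time is used (the moment the frame was first seen);
    intermediate frames get linearly interpolated times.  Frames outside the
    registered range are not extrapolated.
    """
    if len(sync.times) < 2:
        raise ValidationError("need at least two registrations to interpolate")
    frames = np.asarray(sync.frames, dtype=float)
    times = np.asarray(sync.times, dtype=float)
    _, first_idx = np.unique(frames, return_index=True)
    fk, tk = frames[first_idx], times[first_idx]
    if fk.size < 2:
        raise ValidationError("all registrations report the same frame")
    out_frames = np.arange(int(fk[0]), int(fk[-1]) + 1)
    out_times = np.interp(out_frames, fk, tk)
    return out_frames, out_times
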