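"""Uniformly sampled signal containers.

:class:`SignalTrace` carries analog samples in volts; :class:`DigitalTrace`
carries boolean (TTL) samples.  Both are plain value objects: a 1-D sample
array, a sampling rate ``fs`` in Hz, and a start time ``t0`` on whichever
clock the caller is using (device clock or per-subject session clock).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError


@dataclass
class SignalTrace:
    """A uniformly sampled analog signal in volts."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValidationError("SignalTrace samples must be 1-D")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds on the trace's own clock."""
        return self.t0 + np.arange(self.n) / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples, dtype=float))))

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        return replace(self, samples=samples)


@dataclass
class DigitalTrace:
    """A uniformly sampled boolean (TTL) signal."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=bool)
        if self.samples.ndim != 1:
            raise ValidationError("DigitalTrace samples must be 1-D")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


def require_compatible(a, b, what: str = "traces") -> None:
    """Raise unless two traces share sampling rate and length."""
    if a.fs != b.fs:
        raise ValidationError(f"{what} have different sampling rates: {a.fs} vs {b.fs}")
    if a.n != b.n:
        raise ValidationError(f"{what} have different lengths: {a.n} vs {b.n}")
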