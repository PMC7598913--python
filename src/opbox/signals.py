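"""Seeded generators for bench waveforms and synthetic rodent EEG/EMG sessions.

Two families live here:

* deterministic test-bench waveforms (sine, triangle, unipolar rectangular,
  step, impulse) as a signal generator plus precision voltage divider would
  produce them, and
* seeded synthetic physiology: multichannel EEG with a 1/f^alpha background,
  optional narrowband oscillations and an evoked response embedded at known
  event times; EMG as envelope-modulated broadband noise; TTL stimulus
  markers; quadrature rotary-encoder traces; and a commutator rotation sweep.

Every generator is deterministic given its parameters and seed, and synthetic
sessions return a ground-truth record sufficient to reconstruct every
embedded event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .errors import AliasingError, ValidationError
from .trace import DigitalTrace, SignalTrace

_WAVEFORM_KINDS = ("sine", "triangle", "unipolar-rect", "impulse", "step")


# ---------------------------------------------------------------------------
# bench waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformParams:
    """Parameters of one test-bench waveform.

    ``amplitude_v`` is the peak amplitude for sine/triangle and the high level
    for unipolar kinds.  ``phase`` is the starting point expressed as a
    fraction of a cycle in [0, 1).  ``duty`` (unipolar-rect only) is the
    fraction of each cycle spent high.  ``width_s`` is the pulse width for
    ``impulse``; ``onset_s`` the turn-on time for ``step`` and ``impulse``.
    """

    kind: str
    amplitude_v: float
    fs: float
    duration_s: float
    freq_hz: Optional[float] = None
    phase: float = 0.0
    duty: float = 0.5
    width_s: Optional[float] = None
    onset_s: float = 0.0

    def __post_init__(self):
        if self.kind not in _WAVEFORM_KINDS:
            raise ValidationError(f"unknown waveform kind {self.kind!r}")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if self.duration_s < 0:
            raise ValidationError("duration_s must be non-negative")
        if self.kind in ("sine", "triangle", "unipolar-rect"):
            if self.freq_hz is None or not self.freq_hz > 0:
                raise ValidationError(f"{self.kind} requires freq_hz > 0")
        if not 0.0 <= self.phase < 1.0:
            raise ValidationError("phase must lie in [0, 1)")
        if not 0.0 < self.duty < 1.0:
            raise ValidationError("duty must lie in (0, 1)")


def make_waveform(params: WaveformParams) -> SignalTrace:
    """Render a waveform onto the sampling grid.

    Phase convention: sample 0 sits at the stated phase of the cycle.  A
    triangle at phase 0 starts at 0 V rising and peaks a quarter period later,
    so at integer samples-per-quarter-period the samples land exactly on the
    peaks (this is what makes a 10-Hz triangle at 1 kHz read 288.79 uV RMS for
    a 500-uV amplitude instead of the continuous-time 288.68 uV).
    """
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    A = params.amplitude_v

    if params.kind == "sine":
        x = A * np.sin(2 * np.pi * (params.freq_hz * t + params.phase))
    elif params.kind == "triangle":
        theta = 2 * np.pi * (params.freq_hz * t + params.phase) + np.pi / 2
        x = A * sps.sawtooth(theta, width=0.5)
    elif params.kind == "unipolar-rect":
        theta = 2 * np.pi * (params.freq_hz * t + params.phase)
        x = A * (sps.square(theta, duty=params.duty) + 1.0) / 2.0
    elif params.kind == "step":
        x = np.where(t >= params.onset_s, A, 0.0)
    else:  # impulse
        width = params.width_s if params.width_s is not None else 1e-3
        n_pulse = int(round(width * params.fs))
        if n_pulse < 1:
            warnings.warn(
                f"impulse width {width} s is shorter than one sample period; "
                "emitting a single-sample pulse", stacklevel=2)
            n_pulse = 1
        i0 = int(round(params.onset_s * params.fs))
        x = np.zeros(n)
        x[i0:i0 + n_pulse] = A

    return SignalTrace(samples=x, fs=params.fs)


def voltage_divider(trace: SignalTrace, ratio: float) -> SignalTrace:
    """Precision voltage divider: scale samples by ``ratio`` (0 < ratio <= 1)."""
    if not 0.0 < ratio <= 1.0:
        raise ValidationError(f"divider ratio must lie in (0, 1], got {ratio}")
    return trace.with_samples(trace.samples * ratio)


# ---------------------------------------------------------------------------
# synthetic physiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EphysProfile:
    """What one synthetic subject's physiology looks like.

    Amplitudes are in microvolts at the electrode (pre-amplifier).  ``bands``
    is a sequence of ``(center_hz, bandwidth_hz, rms_uv)`` narrowband
    oscillations added to every EEG channel.  The evoked response is a damped
    sinusoid of ``evoked_duration_s`` added at each event time; events repeat
    every ``event_period_s`` starting at ``event_start_s`` and drive a TTL
    line high for ``stim_duration_s``.  ``event_period_s = None`` disables
    events entirely (a spontaneous-behavior subject).
    """

    n_eeg_channels: int = 2
    n_emg_channels: int = 1
    one_over_f_exponent: float = 1.0
    background_rms_uv: float = 80.0
    bands: tuple = ((6.0, 2.0, 30.0),)
    emg_rms_uv: float = 60.0
    emg_band_hz: tuple = (20.0, 300.0)
    emg_burst_rate_hz: float = 0.5
    evoked_amplitude_uv: float = 40.0
    evoked_freq_hz: float = 8.0
    evoked_duration_s: float = 0.3
    evoked_decay_s: float = 0.08
    event_period_s: Optional[float] = 3.0
    event_start_s: float = 2.0
    stim_duration_s: float = 1.0

    def __post_init__(self):
        if self.n_eeg_channels < 0 or self.n_emg_channels < 0:
            raise ValidationError("channel counts must be non-negative")
        for name in ("background_rms_uv", "emg_rms_uv", "evoked_amplitude_uv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for c, bw, p in self.bands:
            if p < 0 or bw <= 0 or c <= 0:
                raise ValidationError("band peaks need center>0, bandwidth>0, rms>=0")
        if self.event_period_s is not None and self.event_period_s <= 0:
            raise ValidationError("event_period_s must be positive or None")


def evoked_template(profile: EphysProfile, fs: float) -> np.ndarray:
    """The damped-sinusoid evoked response, in volts, on the sampling grid."""
    t = np.arange(int(round(profile.evoked_duration_s * fs))) / fs
    return (profile.evoked_amplitude_uv * 1e-6
            * np.exp(-t / profile.evoked_decay_s)
            * np.sin(2 * np.pi * profile.evoked_freq_hz * t))


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  psd_shape, target_rms: float) -> np.ndarray:
    """White noise spectrally shaped by ``sqrt(psd_shape(f))`` and rescaled to
    an exact target RMS.  Uses a single FFT of length n (the whole trace), so
    repeat runs with the same seed are byte-identical."""
    if target_rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.sqrt(psd_shape(f))
    amp[0] = 0.0  # no DC
    x = np.fft.irfft(spec * amp, n)
    rms = np.sqrt(np.mean(x * x))
    if rms == 0:
        return np.zeros(n)
    return x * (target_rms / rms)


def _one_over_f_psd(alpha: float, f_floor_hz: float = 0.5):
    def shape(f):
        ff = np.maximum(f, f_floor_hz)
        return ff ** (-alpha)
    return shape


def _gaussian_band_psd(center: float, bandwidth: float):
    sigma = bandwidth / 2.355  # FWHM -> sigma
    def shape(f):
        return np.exp(-0.5 * ((f - center) / sigma) ** 2)
    return shape


def event_schedule(profile: EphysProfile, duration_s: float) -> np.ndarray:
    """Event onset times (s) for one session: periodic, template must fit."""
    if profile.event_period_s is None or profile.evoked_amplitude_uv <= 0:
        return np.array([])
    if profile.evoked_duration_s > profile.event_period_s:
        raise ValidationError("evoked template longer than the inter-event interval")
    last = duration_s - profile.evoked_duration_s
    if last < profile.event_start_s:
        return np.array([])
    k = np.arange(int(np.floor((last - profile.event_start_s) / profile.event_period_s)) + 1)
    return profile.event_start_s + k * profile.event_period_s


def synth_session(profile: EphysProfile, fs: float, duration_s: float,
                  rng_seed) -> tuple:
    """Generate one subject's session.

    Returns ``(analog, digital, truth)`` where ``analog`` is a list of
    :class:`SignalTrace` (EEG channels first, then EMG), ``digital`` a list
    with one TTL :class:`DigitalTrace` marking stimuli, and ``truth`` a dict
    holding the exact event times, the evoked template, and the seed --
    everything needed to reconstruct the embedded structure.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    n = int(round(duration_s * fs))
    events = event_schedule(profile, duration_s)
    template = evoked_template(profile, fs)

    analog = []
    for _ in range(profile.n_eeg_channels):
        x = _shaped_noise(rng, n, fs,
                          _one_over_f_psd(profile.one_over_f_exponent),
                          profile.background_rms_uv * 1e-6)
        for center, bw, rms_uv in profile.bands:
            x = x + _shaped_noise(rng, n, fs, _gaussian_band_psd(center, bw),
                                  rms_uv * 1e-6)
        for ev in events:
            i = int(round(ev * fs))
            x[i:i + template.size] += template[:max(0, n - i)]
        analog.append(SignalTrace(x, fs))

    for _ in range(profile.n_emg_channels):
        lo, hi = profile.emg_band_hz
        hi = min(hi, 0.45 * fs)
        def emg_psd(f, lo=lo, hi=hi):
            return ((f >= lo) & (f <= hi)).astype(float)
        broad = _shaped_noise(rng, n, fs, emg_psd, 1.0)
        env_raw = _shaped_noise(
            rng, n, fs,
            lambda f: np.exp(-(f / max(profile.emg_burst_rate_hz, 1e-6)) ** 2), 1.0)
        env = np.clip(1.0 + 0.5 * env_raw, 0.05, None)
        x = broad * env
        rms = np.sqrt(np.mean(x * x)) if n else 0.0
        if rms > 0 and profile.emg_rms_uv > 0:
            x = x * (profile.emg_rms_uv * 1e-6 / rms)
        else:
            x = np.zeros(n)
        analog.append(SignalTrace(x, fs))

    ttl = np.zeros(n, dtype=bool)
    for ev in events:
        i = int(round(ev * fs))
        j = int(round((ev + profile.stim_duration_s) * fs))
        ttl[i:min(j, n)] = True
    digital = [DigitalTrace(ttl, fs)]

    truth = {
        "event_times_s": events,
        "template": template,
        "fs": fs,
        "duration_s": duration_s,
        "profile": profile,
    }
    return analog, digital, truth


# ---------------------------------------------------------------------------
# rotary encoder and commutator
# ---------------------------------------------------------------------------

_QUAD_STATES = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=bool)  # forward cycle


def quadrature_from_angle(angle: SignalTrace, counts_per_rev: int):
    """Encode an angle trace (radians) as x4 quadrature channels A/B.

    ``counts_per_rev`` is the x4-decoded resolution: one full forward
    revolution produces exactly ``counts_per_rev`` net counts.  Raises
    :class:`AliasingError` if the angle moves more than one quarter-count per
    sample (the decoder could not follow).
    """
    if counts_per_rev < 4:
        raise ValidationError("counts_per_rev must be >= 4")
    theta = np.asarray(angle.samples, dtype=float)
    state = np.floor(theta / (2 * np.pi) * counts_per_rev).astype(np.int64)
    if state.size and np.abs(np.diff(state)).max(initial=0) > 1:
        raise AliasingError(
            "angle advances more than one quadrature count per sample; "
            "increase fs or lower counts_per_rev")
    q = np.mod(state, 4)
    a = _QUAD_STATES[q, 0]
    b = _QUAD_STATES[q, 1]
    return (DigitalTrace(a, angle.fs, angle.t0),
            DigitalTrace(b, angle.fs, angle.t0))


def commutator_rotation_profile(fs: float, n: int, rotation_hz: float = 0.2,
                                pattern: Sequence[float] = (2.0, -2.0, 2.0)) -> np.ndarray:
    """Angular position (radians) for a hand-spun commutator sweep.

    ``pattern`` lists signed revolution counts per segment; each segment runs
    at ``rotation_hz`` revolutions per second.  The default (+2, -2, +2) spans
    [0, 4*pi], returns through 0, and climbs back to 4*pi.
    """
    omega = np.zeros(n)
    i = 0
    for revs in pattern:
        seg = int(round(abs(revs) / rotation_hz * fs))
        omega[i:i + seg] = np.sign(revs) * 2 * np.pi * rotation_hz
        i += seg
        if i >= n:
            break
    return np.cumsum(omega) / fs


def commutator_sweep(trace: SignalTrace,
                     position_rad: Optional[np.ndarray] = None,
                     artifact_amplitude_v: float = 0.0,
                     rotation_hz: float = 0.2):
    """Pass a signal through a (virtual) rotating commutator.

    Returns ``(out, position)``: the trace with an optional rotation-locked
    artifact ``a * sin(position)`` added (default amplitude 0 -- an ideal
    commutator leaves the signal untouched) and the rotational-position trace
    for plotting.
    """
    pos = (commutator_rotation_profile(trace.fs, trace.n, rotation_hz=rotation_hz)
           if position_rad is None else np.asarray(position_rad, dtype=float))
    if pos.shape[0] != trace.n:
        raise ValidationError("rotation profile must cover the whole trace")
    out = trace.samples + artifact_amplitude_v * np.sin(pos)
    return (trace.with_samples(out), SignalTrace(pos, trace.fs, trace.t0))
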