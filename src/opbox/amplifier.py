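"""Virtual analog EEG/EMG front end.

The model is a battery-powered differential amplifier as used for tethered
rodent EEG/EMG: an instrumentation stage with a fixed gain of 10x feeding a
cascade of second-order active filters in Sallen-Key configuration, each with
its own corner frequency, quality factor Q and per-stage gain.  The default
instrument has one two-pole high-pass section (0.28 Hz, Q = 0.71, 10x) and one
two-pole low-pass section (200 Hz, Q = 0.71, 10x), for a nominal total gain of
1000x over the EEG band.

Non-idealities are modeled explicitly:

* finite common-mode rejection, as a single frequency-independent
  common-to-differential leak of ``10**(-cmrr_db/20)`` applied at the input;
* finite input impedance, as a resistive divider against the source impedance
  (:func:`input_loading`);
* input-referred noise, as seeded white Gaussian noise whose in-band RMS
  equals ``noise_rms_uv`` once the amplifier's own transfer function has
  band-limited it;
* saturation, as hard clipping at the battery rails ``+-rail_v``.

Sampled-signal simulation discretizes each second-order section with the
bilinear transform, prewarped at that section's corner so the -3 dB points
land exactly where the continuous-time design puts them even at modest
sampling rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .errors import UndefinedRiseTimeError, ValidationError
from .trace import SignalTrace, require_compatible

HIGH_PASS = "high-pass"
LOW_PASS = "low-pass"
_KINDS = (HIGH_PASS, LOW_PASS)

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# filter stages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterStage:
    """One second-order (two-pole) active filter section.

    The continuous-time transfer function is

    * high-pass:  ``G * s**2 / (s**2 + (w0/Q) s + w0**2)``
    * low-pass:   ``G * w0**2 / (s**2 + (w0/Q) s + w0**2)``

    with ``w0 = 2*pi*corner_hz``.  The magnitude at the corner frequency is
    ``Q * G`` for either kind, a second-order property used by the tests.
    """

    kind: str
    corner_hz: float
    q_factor: float
    stage_gain: float = 1.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValidationError(f"stage kind must be one of {_KINDS}, got {self.kind!r}")
        for name in ("corner_hz", "q_factor", "stage_gain"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")

    def analog_ba(self, corner_rad_s: Optional[float] = None):
        """Continuous-time (b, a) polynomial coefficients in descending powers of s.

        ``corner_rad_s`` overrides the design corner; used internally for
        bilinear prewarping.
        """
        w0 = TWO_PI * self.corner_hz if corner_rad_s is None else corner_rad_s
        a = np.array([1.0, w0 / self.q_factor, w0 * w0])
        if self.kind == HIGH_PASS:
            b = np.array([self.stage_gain, 0.0, 0.0])
        else:
            b = np.array([0.0, 0.0, self.stage_gain * w0 * w0])
        return b, a

    def response(self, freqs_hz) -> np.ndarray:
        """Complex continuous-time response at the given frequencies (Hz)."""
        f = np.asarray(freqs_hz, dtype=float)
        s = 1j * TWO_PI * f
        b, a = self.analog_ba()
        return np.polyval(b, s) / np.polyval(a, s)


def design_stage(kind: str, corner_hz: float, q_factor: float,
                 stage_gain: float = 1.0) -> FilterStage:
    """Design a second-order Sallen-Key style section (validates parameters)."""
    return FilterStage(kind=kind, corner_hz=float(corner_hz),
                       q_factor=float(q_factor), stage_gain=float(stage_gain))


# ---------------------------------------------------------------------------
# amplifier specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplifierSpec:
    """Complete description of one virtual amplifier channel."""

    stages: tuple
    front_gain: float = 10.0
    cmrr_db: float = 115.0
    input_impedance_ohm: float = 0.87e9
    noise_rms_uv: float = 1.3
    rail_v: float = 3.0
    label: str = "amp"

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.front_gain > 0:
            raise ValidationError("front_gain must be positive")
        if self.cmrr_db < 0:
            raise ValidationError("cmrr_db must be non-negative")
        if not self.input_impedance_ohm > 0:
            raise ValidationError("input_impedance_ohm must be positive")
        if self.noise_rms_uv < 0:
            raise ValidationError("noise_rms_uv must be non-negative")
        if not self.rail_v > 0:
            raise ValidationError("rail_v must be positive")

    @property
    def nominal_gain(self) -> float:
        """Front gain times the product of all stage gains (1000 for the default)."""
        g = self.front_gain
        for st in self.stages:
            g *= st.stage_gain
        return g

    @property
    def highest_lowpass_corner_hz(self) -> Optional[float]:
        corners = [st.corner_hz for st in self.stages if st.kind == LOW_PASS]
        return max(corners) if corners else None

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "front_gain": self.front_gain,
            "stages": [
                {"kind": st.kind, "corner_hz": st.corner_hz,
                 "q_factor": st.q_factor, "stage_gain": st.stage_gain}
                for st in self.stages
            ],
            "cmrr_db": self.cmrr_db,
            "input_impedance_ohm": self.input_impedance_ohm,
            "noise_rms_uv": self.noise_rms_uv,
            "rail_v": self.rail_v,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "AmplifierSpec":
        stages = tuple(
            FilterStage(kind=s["kind"], corner_hz=s["corner_hz"],
                        q_factor=s["q_factor"], stage_gain=s.get("stage_gain", 1.0))
            for s in d.get("stages", [])
        )
        return cls(stages=stages,
                   front_gain=d.get("front_gain", 10.0),
                   cmrr_db=d.get("cmrr_db", 115.0),
                   input_impedance_ohm=d.get("input_impedance_ohm", 0.87e9),
                   noise_rms_uv=d.get("noise_rms_uv", 1.3),
                   rail_v=d.get("rail_v", 3.0),
                   label=d.get("label", "amp"))

    @classmethod
    def from_file(cls, path) -> "AmplifierSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def default(cls) -> "AmplifierSpec":
        """The default instrument: 10x front stage, 2-pole HP (0.28 Hz) and
        2-pole LP (200 Hz) sections at Q = 0.71 with 10x gain each."""
        return cls(
            stages=(
                design_stage(HIGH_PASS, 0.28, 0.71, 10.0),
                design_stage(LOW_PASS, 200.0, 0.71, 10.0),
            ),
            front_gain=10.0,
            cmrr_db=115.0,
            input_impedance_ohm=0.87e9,
            noise_rms_uv=1.3,
            rail_v=3.0,
            label="opbox-default",
        )


def packaged_spec_path(name: str = "opbox_default") -> Path:
    """Path to one of the amplifier parameter files shipped with the package."""
    return Path(resources.files("opbox").joinpath(f"specs/{name}.json"))


# ---------------------------------------------------------------------------
# frequency-domain analysis
# ---------------------------------------------------------------------------

def frequency_response(spec: AmplifierSpec, freqs_hz) -> np.ndarray:
    """Complex analytic (continuous-time) gain at each frequency.

    The product of the front gain and every stage response.  An empty
    frequency list yields an empty result.
    """
    f = np.asarray(freqs_hz, dtype=float)
    h = np.full(f.shape, complex(spec.front_gain))
    for st in spec.stages:
        h = h * st.response(f)
    return h


def _magnitude(spec: AmplifierSpec, f: float) -> float:
    return float(np.abs(frequency_response(spec, np.array([f]))[0]))


def find_minus3db_corners(spec: AmplifierSpec,
                          f_min: float = 1e-4,
                          f_max: float = 1e5,
                          n_grid: int = 4096,
                          rtol: float = 1e-6):
    """Locate the -3 dB points of the analytic magnitude response.

    Scans a logarithmic grid for the peak, then bisects (in log frequency)
    toward ``peak/sqrt(2)`` on each side to relative tolerance ``rtol``.
    A side with no crossing inside ``[f_min, f_max]`` (monotone response,
    e.g. a missing stage) is reported as ``None`` rather than a number.

    Returns
    -------
    (f_low, f_high) : tuple of float or None
    """
    grid = np.logspace(np.log10(f_min), np.log10(f_max), n_grid)
    mag = np.abs(frequency_response(spec, grid))
    ipk = int(np.argmax(mag))
    peak = mag[ipk]
    if peak <= 0:
        return (None, None)
    target = peak / np.sqrt(2.0)

    def bisect(lo_f, hi_f, rising: bool) -> float:
        # rising=True: magnitude increases from lo_f to hi_f through the target
        lo, hi = np.log10(lo_f), np.log10(hi_f)
        while (10 ** hi) / (10 ** lo) - 1.0 > rtol:
            mid = 0.5 * (lo + hi)
            above = _magnitude(spec, 10 ** mid) > target
            if above == rising:
                hi = mid
            else:
                lo = mid
        return float(10 ** (0.5 * (lo + hi)))

    f_low = None
    below = np.nonzero(mag[:ipk] < target)[0]
    if below.size:
        i = below[-1]
        f_low = bisect(grid[i], grid[i + 1], rising=True)

    f_high = None
    above_idx = np.nonzero(mag[ipk:] < target)[0]
    if above_idx.size:
        i = ipk + above_idx[0]
        f_high = bisect(grid[i - 1], grid[i], rising=False)

    return (f_low, f_high)


# ---------------------------------------------------------------------------
# discretization and time-domain simulation
# ---------------------------------------------------------------------------

def discretize(spec: AmplifierSpec, fs: float):
    """Discretize the stage cascade at sampling rate ``fs``.

    Each second-order section is converted with the bilinear transform after
    prewarping its corner frequency, so the discrete response is exact at
    every section corner.  Returns ``(sos, k)`` where ``sos`` is an
    ``(n_stages, 6)`` array for :func:`scipy.signal.sosfilt` (empty when the
    spec has no stages) and ``k`` is the front gain scalar.
    """
    if not fs > 0:
        raise ValidationError("fs must be positive")
    rows = []
    for st in spec.stages:
        w0 = TWO_PI * st.corner_hz
        if st.corner_hz >= fs / 2:
            raise ValidationError(
                f"stage corner {st.corner_hz} Hz is at or above Nyquist ({fs/2} Hz)")
        w_warp = 2.0 * fs * np.tan(w0 / (2.0 * fs))
        b, a = st.analog_ba(corner_rad_s=w_warp)
        bz, az = sps.bilinear(b, a, fs)
        rows.append(np.concatenate([bz, az]))
    sos = np.array(rows) if rows else np.empty((0, 6))
    return sos, float(spec.front_gain)


def digital_response(spec: AmplifierSpec, freqs_hz, fs: float) -> np.ndarray:
    """Complex response of the discretized cascade at the given frequencies."""
    sos, k = discretize(spec, fs)
    f = np.asarray(freqs_hz, dtype=float)
    if sos.shape[0] == 0:
        return np.full(f.shape, complex(k))
    _, h = sps.sosfreqz(sos, worN=f, fs=fs)
    return k * h


def equivalent_noise_bandwidth(spec: AmplifierSpec, fs: float, n: int = 8192) -> float:
    """Noise-equivalent bandwidth (Hz) of the normalized magnitude response
    over [0, fs/2]; fs/2 for a flat (stage-less) amplifier."""
    f = np.linspace(0.0, fs / 2.0, n)
    mag = np.abs(frequency_response(spec, f))
    peak = mag.max()
    if peak == 0:
        return fs / 2.0
    h = mag / peak
    return float(np.trapezoid(h * h, f))


def noise_sigma_per_sample(spec: AmplifierSpec, fs: float) -> float:
    """Per-sample std-dev (volts) of the input white noise such that the
    amplifier's own band-limiting leaves ``noise_rms_uv`` RMS in band."""
    if spec.noise_rms_uv == 0:
        return 0.0
    enbw = equivalent_noise_bandwidth(spec, fs)
    return spec.noise_rms_uv * 1e-6 * np.sqrt((fs / 2.0) / enbw)


def simulate_channel(spec: AmplifierSpec,
                     v_diff: SignalTrace,
                     v_common: Optional[SignalTrace] = None,
                     rng_seed=None) -> SignalTrace:
    """Pass a differential (and optionally common-mode) input through the
    virtual amplifier.

    The input-referred signal is ``v_diff + 10**(-cmrr_db/20) * v_common``
    plus seeded white Gaussian noise; the cascade (front gain and discretized
    stages) amplifies it, and the output is hard-clipped at the rails.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``; it is
    mandatory whenever ``noise_rms_uv > 0`` so that every noisy simulation is
    reproducible.
    """
    if v_common is not None:
        require_compatible(v_diff, v_common, "v_diff/v_common")
    fs = v_diff.fs
    f_hi = spec.highest_lowpass_corner_hz
    if f_hi is not None and fs < 4.0 * f_hi:
        warnings.warn(
            f"fs = {fs} Hz is below 4x the highest low-pass corner ({f_hi} Hz); "
            "the discretized model will deviate from the analog response",
            stacklevel=2)

    x = np.asarray(v_diff.samples, dtype=float)
    if v_common is not None:
        x = x + 10.0 ** (-spec.cmrr_db / 20.0) * np.asarray(v_common.samples, dtype=float)

    if spec.noise_rms_uv > 0:
        if rng_seed is None:
            raise ValidationError("rng_seed is required when noise_rms_uv > 0")
        rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
            else np.random.default_rng(rng_seed)
        x = x + rng.normal(0.0, noise_sigma_per_sample(spec, fs), size=x.shape)

    sos, k = discretize(spec, fs)
    y = k * (sps.sosfilt(sos, x) if sos.shape[0] else x)
    np.clip(y, -spec.rail_v, spec.rail_v, out=y)
    return SignalTrace(samples=y, fs=fs, t0=v_diff.t0)


def step_response(spec: AmplifierSpec, fs: float, duration_s: float,
                  amplitude_v: float = 500e-6,
                  onset_s: Optional[float] = None) -> SignalTrace:
    """Simulate the output for an input step of ``amplitude_v`` (noise off).

    The step turns on at ``onset_s`` (default: 10% into the trace).
    """
    n = int(round(duration_s * fs))
    onset = duration_s * 0.1 if onset_s is None else onset_s
    x = np.zeros(n)
    x[int(round(onset * fs)):] = amplitude_v
    quiet = AmplifierSpec(stages=spec.stages, front_gain=spec.front_gain,
                          cmrr_db=spec.cmrr_db,
                          input_impedance_ohm=spec.input_impedance_ohm,
                          noise_rms_uv=0.0, rail_v=spec.rail_v, label=spec.label)
    return simulate_channel(quiet, SignalTrace(x, fs))


def rise_time_10_90(trace: SignalTrace) -> float:
    """10-90% rise time (seconds) of a step response.

    Crossings of 10% and 90% of the post-step maximum are located by linear
    interpolation between the straddling samples.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size == 0:
        raise UndefinedRiseTimeError("empty trace")
    m = float(x.max())
    if m <= 0:
        raise UndefinedRiseTimeError("trace never rises above zero")

    def crossing(level: float, start: int) -> float:
        idx = np.nonzero(x[start:] >= level)[0]
        if idx.size == 0:
            raise UndefinedRiseTimeError(f"trace never reaches {level:.3g} V")
        i = start + int(idx[0])
        if i == 0:
            return 0.0
        frac = (level - x[i - 1]) / (x[i] - x[i - 1])
        return (i - 1 + frac) / trace.fs

    t10 = crossing(0.1 * m, 0)
    i10 = int(np.floor(t10 * trace.fs))
    t90 = crossing(0.9 * m, max(i10, 0))
    return t90 - t10


def input_loading(input_impedance_ohm: float, source_resistance_ohm: float) -> float:
    """Voltage-divider attenuation ``Zin / (Zin + Rs)`` applied at the input."""
    if not input_impedance_ohm > 0:
        raise ValidationError("input_impedance_ohm must be positive")
    if source_resistance_ohm < 0:
        raise ValidationError("source_resistance_ohm must be non-negative")
    return input_impedance_ohm / (input_impedance_ohm + source_resistance_ohm)
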