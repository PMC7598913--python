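"""Amplifier-characterization metrics.

Windowed statistics for the standard bench conditions -- noise floor, CMRR,
SNR, crosstalk, phase distortion, effective gain, input impedance -- plus a
spectrogram helper and a classical one-way ANOVA with Bonferroni-corrected
pairwise follow-ups.  Each metric tiles the recording into non-overlapping
windows, reports per-window values, and summarizes them as mean and SEM
(sd/sqrt(n_windows)), the way amplifier comparisons are usually tabulated.

Conventions worth knowing:

* CMRR is reported *input-referred*: the output RMS is divided by the nominal
  gain before comparison with the ideal input, so a perfect amplifier scores
  0 dB and a 100-dB rejection scores -100 dB.
* The SNR estimator is a documented periodogram method (Hann window; signal =
  fundamental +- a few bins; noise = everything except DC, the signal and
  harmonics 2..6), capped at +150 dB, with a time-domain sine-fit oracle used
  by the tests as an independent cross-check.
* The ANOVA statistic is computed from sums of squares directly rather than
  delegated, so the statistic itself is part of the tested surface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .errors import (NonMeasurableImpedanceError, UndefinedMetricError,
                     ValidationError)
from .trace import SignalTrace, require_compatible

SNR_CAP_DB = 150.0


@dataclass
class WindowedStat:
    """Per-window values of one metric plus their mean and SEM."""

    metric: str
    window_s: float
    values: np.ndarray
    mean: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(np.mean(self.values)) if self.values.size else float("nan")
        if self.values.size > 1:
            self.sem = float(np.std(self.values, ddof=1) / np.sqrt(self.values.size))
        else:
            self.sem = 0.0

    @property
    def n_windows(self) -> int:
        return int(self.values.size)

    def to_dict(self) -> dict:
        return {"metric": self.metric, "window_s": self.window_s,
                "n_windows": self.n_windows, "mean": self.mean, "sem": self.sem,
                "values": self.values.tolist()}


def _windows(trace: SignalTrace, window_s: float) -> np.ndarray:
    """Tile the trace into non-overlapping windows; the remainder is discarded."""
    nw = int(round(window_s * trace.fs))
    if nw <= 0:
        raise ValidationError("window_s must span at least one sample")
    k = trace.n // nw
    if k == 0:
        raise ValidationError(
            f"trace ({trace.duration_s:.3g} s) is shorter than one window ({window_s} s)")
    return np.asarray(trace.samples[: k * nw], dtype=float).reshape(k, nw)


def windowed_rms(trace: SignalTrace, window_s: float,
                 metric: str = "rms") -> WindowedStat:
    """Per-window root-mean-square value."""
    w = _windows(trace, window_s)
    return WindowedStat(metric, window_s, np.sqrt(np.mean(w * w, axis=1)))


def cmrr_db(output: SignalTrace, ideal_input: SignalTrace, nominal_gain: float,
            window_s: float = 30.0) -> WindowedStat:
    """Common-mode rejection, input-referred, in dB per window:
    ``20*log10((rms_out / nominal_gain) / rms_in)``."""
    require_compatible(output, ideal_input, "output/ideal input")
    if not nominal_gain > 0:
        raise ValidationError("nominal_gain must be positive")
    out = _windows(output, window_s)
    ref = _windows(ideal_input, window_s)
    rms_out = np.sqrt(np.mean(out * out, axis=1))
    rms_in = np.sqrt(np.mean(ref * ref, axis=1))
    if np.any(rms_in == 0):
        raise UndefinedMetricError("ideal input has a zero-RMS window")
    return WindowedStat("cmrr_db", window_s,
                        20.0 * np.log10((rms_out / nominal_gain) / rms_in))


def snr_db(trace: SignalTrace, fundamental_hz: float, window_s: float = 15.0,
           n_harmonics: int = 6, guard_bins: int = 3,
           cap_db: float = SNR_CAP_DB) -> WindowedStat:
    """Periodogram SNR of a sine recording, per non-overlapping window.

    Each window gets a Hann-windowed periodogram.  Signal power is the sum
    over the fundamental bin +- ``guard_bins`` (the leakage half-width); noise
    power is the total minus DC, the signal region and harmonics 2..n; the
    ratio is reported in dB and capped at ``cap_db`` (a noiseless recording
    would otherwise be infinite).
    """
    if fundamental_hz >= trace.fs / 2:
        raise ValidationError("fundamental is at or above Nyquist")
    if window_s * fundamental_hz < 10:
        warnings.warn("window holds fewer than 10 cycles of the fundamental",
                      stacklevel=2)
    w = _windows(trace, window_s)
    vals = []
    for row in w:
        f, p = sps.periodogram(row, trace.fs, window="hann")
        df = f[1] - f[0]
        power = p * df
        half = guard_bins * df
        keep = np.ones(f.size, dtype=bool)
        keep[f <= half] = False  # DC region
        sig = 0.0
        for h in range(1, n_harmonics + 1):
            fc = h * fundamental_hz
            if fc >= trace.fs / 2:
                break
            band = np.abs(f - fc) <= half
            if h == 1:
                sig = float(power[band].sum())
            keep &= ~band
        noise = float(power[keep].sum())
        if noise <= 0 or sig / noise > 10 ** (cap_db / 10):
            vals.append(cap_db)
        else:
            vals.append(min(10.0 * np.log10(sig / noise), cap_db))
    return WindowedStat("snr_db", window_s, np.array(vals))


def phase_discrepancy(test: SignalTrace, reference: SignalTrace):
    """Instantaneous phase difference between two narrowband recordings.

    Both traces are Hilbert transformed; the per-sample phase difference is
    taken from the analytic signals, one cycle is trimmed from each edge, and
    the circular mean and SEM are returned (radians).
    """
    require_compatible(test, reference, "test/reference")
    ref = np.asarray(reference.samples, dtype=float)
    f, p = sps.periodogram(ref, reference.fs)
    i = int(np.argmax(p[1:])) + 1
    if p[1:].sum() > 0 and p[i] / p[1:].sum() < 0.5:
        warnings.warn("reference looks broadband; instantaneous phase is "
                      "ill-defined", stacklevel=2)
    f0 = max(f[i], 1.0 / reference.duration_s)
    trim = int(round(reference.fs / f0))
    za = sps.hilbert(np.asarray(test.samples, dtype=float))
    zb = sps.hilbert(ref)
    dphi = np.angle(za * np.conj(zb))
    if 2 * trim >= dphi.size:
        raise ValidationError("trace too short to trim one cycle per edge")
    dphi = dphi[trim:-trim]
    z = np.exp(1j * dphi)
    r = np.mean(z)
    mean = float(np.angle(r))
    rho = min(np.abs(r), 1.0)
    circ_sd = np.sqrt(max(-2.0 * np.log(rho), 0.0)) if rho > 0 else np.pi
    sem = float(circ_sd / np.sqrt(dphi.size))
    return mean, sem


def effective_gain(output: SignalTrace, inp: SignalTrace,
                   window_s: float = 1.0) -> WindowedStat:
    """Per-window RMS ratio of amplifier output to input."""
    require_compatible(output, inp, "output/input")
    out = _windows(output, window_s)
    ref = _windows(inp, window_s)
    rms_out = np.sqrt(np.mean(out * out, axis=1))
    rms_in = np.sqrt(np.mean(ref * ref, axis=1))
    if np.any(rms_in == 0):
        raise UndefinedMetricError("input has a zero-RMS window")
    return WindowedStat("effective_gain", window_s, rms_out / rms_in)


@dataclass
class ImpedanceEstimate:
    """Per-window input impedances summarized as median and interquartile range."""

    values_ohm: np.ndarray
    median_ohm: float = field(init=False)
    iqr_ohm: tuple = field(init=False)

    def __post_init__(self):
        self.values_ohm = np.asarray(self.values_ohm, dtype=float)
        self.median_ohm = float(np.median(self.values_ohm))
        self.iqr_ohm = (float(np.percentile(self.values_ohm, 25)),
                        float(np.percentile(self.values_ohm, 75)))


def input_impedance_estimate(rms_direct, rms_through_10M,
                             series_ohm: float = 10e6) -> ImpedanceEstimate:
    """Input impedance from paired windowed RMS values:
    ``Zin = R_series * RMS_through / (RMS_direct - RMS_through)`` per window.

    Raises :class:`NonMeasurableImpedanceError` if any pair has the
    through-resistor RMS at or above the direct RMS (the divider formula would
    return a non-physical impedance), rather than reporting a negative number.
    """
    r0 = np.asarray(rms_direct, dtype=float)
    r1 = np.asarray(rms_through_10M, dtype=float)
    if r0.shape != r1.shape:
        raise ValidationError("rms arrays must be paired (same shape)")
    if np.any(r1 <= 0):
        raise ValidationError("rms_through must be positive")
    if np.any(r1 >= r0):
        raise NonMeasurableImpedanceError(
            "RMS through the series resistor is not below the direct RMS; "
            "input impedance is non-measurable at this precision")
    return ImpedanceEstimate(series_ohm * r1 / (r0 - r1))


def crosstalk_table(active: SignalTrace, unused: Sequence[SignalTrace],
                    window_s: float = 30.0) -> dict:
    """Windowed RMS of the driven channel and each unused channel, plus the
    ratio of every unused channel's mean RMS to the active channel's."""
    for u in unused:
        require_compatible(active, u, "active/unused")
    out = {"active": windowed_rms(active, window_s, metric="active_rms")}
    active_mean = out["active"].mean
    for i, u in enumerate(unused):
        stat = windowed_rms(u, window_s, metric=f"unused{i}_rms")
        out[f"unused{i}"] = stat
        out[f"unused{i}_ratio"] = (stat.mean / active_mean) if active_mean > 0 else 0.0
    return out


def spectrogram(trace: SignalTrace, window_s: float = 2.0,
                overlap_frac: float = 0.8):
    """Magnitude-squared short-time spectrum (Hann window).

    Returns ``(freqs, frame_times, Sxx)``.  Hop = window * (1 - overlap), so a
    30-s trace at the defaults yields 71 frames.
    """
    if overlap_frac >= 1.0 or overlap_frac < 0.0:
        raise ValidationError("overlap_frac must lie in [0, 1)")
    nperseg = int(round(window_s * trace.fs))
    if trace.n < nperseg:
        raise ValidationError("trace shorter than one spectrogram window")
    noverlap = int(round(nperseg * overlap_frac))
    f, t, sxx = sps.spectrogram(np.asarray(trace.samples, dtype=float), trace.fs,
                                window="hann", nperseg=nperseg, noverlap=noverlap)
    return f, t + trace.t0, sxx


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def oneway_anova(groups: Sequence[Sequence[float]]):
    """Classical one-way fixed-effects ANOVA from sums of squares.

    Returns ``(F, p)``.  Identical groups with zero within-group variance are
    reported as ``F = 0, p = 1`` rather than 0/0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValidationError("need at least 2 groups with at least 2 values each")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = all_vals.size - len(gs)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(spstats.f.sf(f_stat, df_b, df_w))
    return float(f_stat), p


def bonferroni_pairwise(groups: Sequence[Sequence[float]]) -> np.ndarray:
    """Pairwise two-sample t tests with Bonferroni-adjusted p values.

    Returns a symmetric matrix of adjusted p values (diagonal NaN); each raw p
    is multiplied by the number of comparisons and capped at 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    m = k * (k - 1) // 2
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            _, p = spstats.ttest_ind(gs[i], gs[j])
            out[i, j] = out[j, i] = min(float(p) * m, 1.0)
    return out


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class BenchReport:
    """Structured result of a bench run: label, per-metric stats, comparisons."""

    label: str
    stats: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, WindowedStat):
                return v.to_dict()
            if isinstance(v, ImpedanceEstimate):
                return {"median_ohm": v.median_ohm, "iqr_ohm": list(v.iqr_ohm),
                        "values_ohm": v.values_ohm.tolist()}
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        return {"label": self.label, "stats": conv(self.stats),
                "comparisons": conv(self.comparisons), "notes": conv(self.notes)}

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def summary_rows(self) -> list:
        """Flat (metric, mean, sem, n) rows for table rendering."""
        rows = []
        def walk(prefix, obj):
            if isinstance(obj, WindowedStat):
                rows.append({"metric": f"{prefix}", "mean": obj.mean,
                             "sem": obj.sem, "n_windows": obj.n_windows})
            elif isinstance(obj, ImpedanceEstimate):
                rows.append({"metric": f"{prefix}", "mean": obj.median_ohm,
                             "sem": float("nan"), "n_windows": obj.values_ohm.size})
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (int, float, np.floating)):
                rows.append({"metric": prefix, "mean": float(obj),
                             "sem": float("nan"), "n_windows": 1})
        walk("", self.stats)
        return rows
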