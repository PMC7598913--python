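"""Session orchestration: simulated multi-subject runs and the bench protocol.

:func:`run_simulated_session` wires the whole acquisition path together:
seeded synthetic physiology per subject -> optional virtual amplifier ->
simulated DAQ (float32 quantization, chunked delivery at the update cadence)
-> CSV-driven dispatch -> per-subject recording files, streaming ERP means
and first-hour mean power spectra, plus a manifest that pins inputs, seed and
version so a rerun reproduces every output byte-for-byte.

:func:`run_bench_protocol` runs the amplifier-characterization conditions
(noise floor under several source impedances, CMRR, SNR, crosstalk,
high-sample-rate phase/gain/step/impulse, input-impedance sweep) against a
virtual amplifier and emits a structured :class:`~opbox.bench.BenchReport`.
Bench recordings default to desk-scale durations (60 s with proportionally
shortened windows instead of 5-min takes); ``full_length=True`` restores the
long protocol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import __version__
from .amplifier import (AmplifierSpec, find_minus3db_corners, frequency_response,
                        input_loading, rise_time_10_90, simulate_channel,
                        step_response)
from .bench import (BenchReport, cmrr_db, crosstalk_table, effective_gain,
                    input_impedance_estimate, oneway_anova, phase_discrepancy,
                    snr_db, windowed_rms)
from .errors import ValidationError
from .recording import RecordingWriter, read_recording
from .routing import RoutingPlan, load_routing, start_subject, stop_subject
from .signals import (EphysProfile, WaveformParams, make_waveform, synth_session,
                      voltage_divider)
from .streams import (DeviceChunk, DeviceStreamTracker, ERPAccumulator,
                      RingBuffer, StreamingERP, dispatch_chunk,
                      realtime_spectrum)
from .trace import SignalTrace

PROTOCOLS = ("noise", "cmrr", "snr", "crosstalk", "highrate", "impedance",
             "gain", "corners")


# ---------------------------------------------------------------------------
# simulated sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Everything needed to reproduce one simulated multi-subject session."""

    subjects_csv: str
    boxes_csv: str
    out_dir: str
    seed: int
    duration_s: float = 60.0
    fs: float = 1000.0
    chunk_hz: float = 10.0
    amplifier_spec: Optional[str] = None   # path to a spec JSON; None = bypass
    profiles: dict = field(default_factory=dict)       # subject_id -> EphysProfile
    start_times: dict = field(default_factory=dict)    # subject_id -> seconds
    stop_times: dict = field(default_factory=dict)
    erp_pre_s: float = 0.1
    erp_post_s: float = 0.9
    spectrum_window_s: float = 5.0
    psd_hours_s: float = 3600.0

    @classmethod
    def from_json(cls, path) -> "SessionConfig":
        raw = json.loads(Path(path).read_text())
        profiles = {sid: EphysProfile(**p)
                    for sid, p in raw.pop("profiles", {}).items()}
        return cls(profiles=profiles, **raw)

    def describe(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "profiles"}
        d["profiles"] = {sid: asdict(p) if isinstance(p, EphysProfile) else p
                         for sid, p in self.profiles.items()}
        return d


def _subject_seeds(seed: int, subject_ids) -> dict:
    """Stable per-subject seeds: independent of which other subjects run when."""
    out = {}
    for sid in sorted(subject_ids):
        h = hashlib.sha256(f"{seed}:{sid}".encode()).digest()
        out[sid] = int.from_bytes(h[:4], "little") % (2 ** 31)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_simulated_session(config: SessionConfig) -> dict:
    """Run one simulated session end to end; deterministic given the seed.

    Returns a dict keyed by subject id with the recording path, trial counts,
    the ERP mean (or ``None`` for subjects without events -- spontaneous
    recordings are valid, not an error), and the mean power spectral density
    over the first hour (or the whole recording if shorter).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = load_routing(config.subjects_csv, config.boxes_csv)
    fs = config.fs
    n_total = int(round(config.duration_s * fs))
    chunk_len = int(round(fs / config.chunk_hz))
    seeds = _subject_seeds(config.seed, plan.subjects)

    amp = (AmplifierSpec.from_file(config.amplifier_spec)
           if config.amplifier_spec else None)

    # --- generate per-subject physiology and assemble device matrices -------
    device_ids = sorted({b.device_id for b in plan.boxes.values()})
    n_analog = {d: 0 for d in device_ids}
    n_digital = {d: 0 for d in device_ids}
    for box in plan.boxes.values():
        n_analog[box.device_id] = max(
            n_analog[box.device_id], max(box.analog_channels, default=-1) + 1)
        dig = box.digital_channels + (box.encoder_channels or ())
        n_digital[box.device_id] = max(
            n_digital[box.device_id], max(dig, default=-1) + 1)

    analog_mat = {d: np.zeros((n_total, n_analog[d]), dtype=np.float32)
                  for d in device_ids}
    digital_mat = {d: np.zeros((n_total, max(n_digital[d], 1)), dtype=bool)
                   for d in device_ids}

    truths = {}
    for sid in sorted(plan.subjects):
        sub = plan.subjects[sid]
        box = plan.boxes[sub.box_id]
        profile = config.profiles.get(sid, EphysProfile())
        rng = np.random.default_rng(seeds[sid])
        analog, digital, truth = synth_session(profile, fs, config.duration_s, rng)
        truths[sid] = truth
        for k, tr in enumerate(analog[:len(box.analog_channels)]):
            if amp is not None:
                tr = simulate_channel(amp, tr, rng_seed=rng)
            analog_mat[box.device_id][:, box.analog_channels[k]] = \
                tr.samples.astype(np.float32)
        for k, dtr in enumerate(digital[:len(box.digital_channels)]):
            digital_mat[box.device_id][:, box.digital_channels[k]] = dtr.samples

    # --- run the acquisition loop ------------------------------------------
    session = AcquisitionSession(
        plan, fs, out_dir,
        erp_pre_s=config.erp_pre_s, erp_post_s=config.erp_post_s,
        spectrum_window_s=config.spectrum_window_s)

    events = []
    for sid in plan.subjects:
        events.append((config.start_times.get(sid, 0.0), "start", sid))
        events.append((config.stop_times.get(sid, config.duration_s), "stop", sid))
    events.sort(key=lambda e: (e[0], e[1] == "start", e[2]))

    for i0 in range(0, n_total, chunk_len):
        i1 = min(i0 + chunk_len, n_total)
        chunk_end_t = i1 / fs
        while events and events[0][0] < chunk_end_t - 1e-12:
            t, what, sid = events.pop(0)
            if what == "start":
                session.start_subject(sid, t)
            else:
                session.stop_subject(sid, t)
        for d in device_ids:
            session.process_chunk(DeviceChunk(
                device_id=d, start_index=i0,
                analog=analog_mat[d][i0:i1],
                digital=digital_mat[d][i0:i1], fs=fs))
    while events:
        t, what, sid = events.pop(0)
        if what == "stop":
            session.stop_subject(sid, t)

    results = session.close(psd_seconds=config.psd_hours_s)

    manifest = {
        "config": config.describe(),
        "seed": config.seed,
        "opbox_version": __version__,
        "outputs": {},
    }
    for sid, res in results.items():
        for key in ("recording", "erp_csv", "psd_csv"):
            p = res.get(key)
            if p is not None:
                manifest["outputs"][str(Path(p).name)] = _sha256(Path(p))
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return results


class AcquisitionSession:
    """Streaming engine state for one session: writers, ERPs, ring buffers."""

    def __init__(self, plan: RoutingPlan, fs: float, out_dir,
                 erp_pre_s: float = 0.1, erp_post_s: float = 0.9,
                 spectrum_window_s: float = 5.0):
        self.plan = plan
        self.fs = fs
        self.out_dir = Path(out_dir)
        self.erp_pre = int(round(erp_pre_s * fs))
        self.erp_post = int(round(erp_post_s * fs))
        self.spectrum_window_s = spectrum_window_s
        self.tracker = DeviceStreamTracker()
        self._state = {}

    def start_subject(self, sid: str, t: float) -> None:
        start_subject(self.plan, sid, t)
        box = self.plan.boxes[self.plan.subjects[sid].box_id]
        n_ch = len(box.analog_channels)
        meta = {
            "subject_id": sid,
            "box_id": box.box_id,
            "device_id": box.device_id,
            "protocol": self.plan.subjects[sid].protocol,
            "fs": self.fs,
            "channel_names": [f"a{c}" for c in box.analog_channels],
            "units": "V",
            "device_start_time_s": t,
        }
        acc = ERPAccumulator(n_ch, self.erp_pre, self.erp_post)
        self._state[sid] = {
            "writer": RecordingWriter(self.out_dir / f"{sid}.obx", meta),
            "erp": StreamingERP(acc, self.fs),
            "ring": RingBuffer(int(round(self.spectrum_window_s * self.fs))),
            "ttl_level": False,
            "n_events": 0,
        }

    def stop_subject(self, sid: str, t: float) -> None:
        stop_subject(self.plan, sid, t)

    def process_chunk(self, chunk: DeviceChunk) -> None:
        self.tracker.check(chunk)
        for sid, block in dispatch_chunk(self.plan, chunk).items():
            st = self._state[sid]
            st["writer"].write_block(block.analog)
            if block.digital.shape[1]:
                ttl = block.digital[:, 0]
                prev = np.concatenate([[st["ttl_level"]], ttl[:-1]])
                onsets = np.nonzero(ttl & ~prev)[0]
                st["ttl_level"] = bool(ttl[-1]) if ttl.size else st["ttl_level"]
                if onsets.size:
                    times = (block.sample_index + onsets) / self.fs
                    st["erp"].add_events(times)
                    st["n_events"] += onsets.size
                    for tt in times:
                        st["writer"].add_event(tt, "d0", "ttl_onset")
            st["erp"].push(block.analog.T)
            st["ring"].push(block.analog[:, 0])

    def close(self, psd_seconds: float = 3600.0) -> dict:
        results = {}
        for sid, st in self._state.items():
            path = st["writer"].close()
            acc = st["erp"].finalize()
            res = {
                "recording": path,
                "n_events": st["n_events"],
                "erp_trials": acc.count,
                "erp_skipped": acc.skipped,
                "erp_mean": acc.mean(),
                "erp_csv": None,
                "psd_csv": None,
            }
            if acc.count > 0:
                t_axis = (np.arange(acc.window_samples) - acc.pre_samples) / self.fs
                df = pd.DataFrame(acc.mean().T,
                                  columns=[f"ch{k}" for k in range(acc.n_channels)])
                df.insert(0, "time_s", t_axis)
                p = self.out_dir / f"{sid}_erp.csv"
                df.to_csv(p, index=False, float_format="%.9g")
                res["erp_csv"] = p
            rec = read_recording(path)
            n_psd = min(rec.samples.shape[0], int(round(psd_seconds * self.fs)))
            if n_psd >= int(self.spectrum_window_s * self.fs):
                f, pxx = sps.welch(rec.samples[:n_psd, 0].astype(float), self.fs,
                                   nperseg=int(self.spectrum_window_s * self.fs))
                mask = f <= 100.0
                df = pd.DataFrame({"freq_hz": f[mask],
                                   "log10_power": np.log10(pxx[mask]
                                                           + np.finfo(float).tiny)})
                p = self.out_dir / f"{sid}_psd.csv"
                df.to_csv(p, index=False, float_format="%.9g")
                res["psd_csv"] = p
            results[sid] = res
        return results


# ---------------------------------------------------------------------------
# bench protocol
# ---------------------------------------------------------------------------

def _quiet(spec: AmplifierSpec) -> AmplifierSpec:
    return AmplifierSpec(stages=spec.stages, front_gain=spec.front_gain,
                         cmrr_db=spec.cmrr_db,
                         input_impedance_ohm=spec.input_impedance_ohm,
                         noise_rms_uv=0.0, rail_v=spec.rail_v, label=spec.label)


def run_bench_protocol(spec: AmplifierSpec, protocols="all", seed: int = 0,
                       full_length: bool = False,
                       crosstalk_leak: float = 0.0,
                       out_dir=None) -> BenchReport:
    """Run the selected characterization conditions against a virtual amplifier.

    ``protocols`` is ``"all"`` or an iterable drawn from
    ``noise, cmrr, snr, crosstalk, highrate, impedance, gain, corners``.
    Desk-scale durations are the default (noted in the report); pass
    ``full_length=True`` for the 5-minute takes with 30-s/15-s windows.
    """
    if protocols == "all":
        selected = list(PROTOCOLS)
    else:
        selected = list(protocols)
        unknown = [p for p in selected if p not in PROTOCOLS]
        if unknown:
            raise ValidationError(
                f"unknown protocol(s) {unknown}; valid names: {list(PROTOCOLS)}")

    rng = np.random.default_rng(seed)
    gain = spec.nominal_gain
    report = BenchReport(label=spec.label)
    report.notes["scaled"] = not full_length
    report.notes["seed"] = seed

    if full_length:
        rms_dur, rms_win = 300.0, 30.0          # 10 windows
        snr_dur, snr_win = 300.0, 15.0          # 20 windows
        hr_dur = 10.0
        imp_dur, imp_win = 180.0, 9.0           # 20 windows
    else:
        rms_dur, rms_win = 60.0, 6.0
        snr_dur, snr_win = 60.0, 3.0
        hr_dur = 4.0
        imp_dur, imp_win = 20.0, 1.0
    fs = 1000.0
    fs_hr = 100e3

    def zeros(duration):
        return SignalTrace(np.zeros(int(round(duration * fs))), fs)

    if "noise" in selected:
        conditions = {"shorted": 0.0, "r1k": 1e3, "r10k": 1e4,
                      "r10k_cable": 1e4, "open": None}
        stats = {}
        values = []
        for name, r_src in conditions.items():
            out = simulate_channel(spec, zeros(rms_dur), rng_seed=rng)
            stat = windowed_rms(out.with_samples(out.samples / gain * 1e6),
                                rms_win, metric=f"noise_{name}_uvrms")
            stats[name] = stat
            values.append(stat.values)
        f_stat, p = oneway_anova(values)
        report.stats["noise_floor_uvrms_input_referred"] = stats
        report.comparisons["noise_anova"] = {"F": f_stat, "p": p}

    if "cmrr" in selected:
        common = make_waveform(WaveformParams(
            kind="sine", freq_hz=60.0, amplitude_v=0.5, fs=fs, duration_s=rms_dur))
        out = simulate_channel(spec, zeros(rms_dur), v_common=common, rng_seed=rng)
        report.stats["cmrr_db"] = cmrr_db(out, common, gain, window_s=rms_win)

    if "snr" in selected:
        source = make_waveform(WaveformParams(
            kind="sine", freq_hz=10.0, amplitude_v=0.05, fs=fs, duration_s=snr_dur))
        test_in = voltage_divider(source, 1e-3)          # 100 uV peak-to-peak
        out = simulate_channel(spec, test_in, rng_seed=rng)
        report.stats["snr_db"] = snr_db(out, 10.0, window_s=snr_win)

    if "crosstalk" in selected:
        tri_src = make_waveform(WaveformParams(
            kind="triangle", freq_hz=10.0, amplitude_v=0.5, fs=fs,
            duration_s=rms_dur))
        tri = voltage_divider(tri_src, 1e-3)             # 1 mV peak-to-peak
        active = simulate_channel(spec, tri, rng_seed=rng)
        unused = [simulate_channel(
            spec, tri.with_samples(tri.samples * crosstalk_leak), rng_seed=rng)
            for _ in range(2)]
        table = crosstalk_table(
            active.with_samples(active.samples / gain * 1e6),
            [u.with_samples(u.samples / gain * 1e6) for u in unused],
            window_s=rms_win)
        report.stats["crosstalk_uvrms_input_referred"] = table

    if "highrate" in selected:
        phase_stats, gain_stats = {}, {}
        settle = int(round(hr_dur / 2 * fs_hr))   # discard the start-up transient
        for f0 in (5.0, 10.0, 25.0, 50.0, 100.0):
            direct = make_waveform(WaveformParams(
                kind="sine", freq_hz=f0, amplitude_v=0.5, fs=fs_hr,
                duration_s=hr_dur))
            test_in = voltage_divider(direct, 1e-3)
            out = simulate_channel(_quiet(spec), test_in)
            out = out.with_samples(out.samples[settle:])
            ref = test_in.with_samples(test_in.samples[settle:])
            mean, sem = phase_discrepancy(out, ref)
            phase_stats[f"{f0:g}Hz"] = {"mean_rad": mean, "sem_rad": sem}
            # 1-s windows hold an integer number of cycles at every test frequency
            gain_stats[f"{f0:g}Hz"] = effective_gain(out, ref, window_s=1.0)
        report.stats["phase_discrepancy_rad"] = phase_stats
        report.stats["effective_gain"] = gain_stats

        step = step_response(spec, fs_hr, duration_s=0.2, amplitude_v=500e-6)
        report.stats["step_rise_time_ms"] = rise_time_10_90(step) * 1e3

        imp_in = make_waveform(WaveformParams(
            kind="impulse", amplitude_v=500e-6, fs=fs_hr, duration_s=0.05,
            width_s=1e-3, onset_s=0.01))
        imp_out = simulate_channel(_quiet(spec), imp_in)
        report.stats["impulse_peak_v"] = float(np.max(np.abs(imp_out.samples)))

    if "impedance" in selected:
        imp = {}
        amplitude = 2e-3   # large input without saturating: ~2 V at the output
        for f0 in (1.0, 5.0, 10.0, 25.0, 50.0):
            src = make_waveform(WaveformParams(
                kind="sine", freq_hz=f0, amplitude_v=amplitude, fs=fs,
                duration_s=imp_dur))
            direct_in = src.with_samples(
                src.samples * input_loading(spec.input_impedance_ohm, 0.0))
            through_in = src.with_samples(
                src.samples * input_loading(spec.input_impedance_ohm, 10e6))
            r0 = windowed_rms(simulate_channel(spec, direct_in, rng_seed=rng),
                              imp_win).values
            r1 = windowed_rms(simulate_channel(spec, through_in, rng_seed=rng),
                              imp_win).values
            imp[f"{f0:g}Hz"] = input_impedance_estimate(r0, r1, series_ohm=10e6)
        report.stats["input_impedance_ohm"] = imp

    if "gain" in selected:
        grid = np.logspace(np.log10(0.01), np.log10(1000.0), 20001)
        mag = np.abs(frequency_response(spec, grid))
        report.stats["peak_gain"] = float(mag.max())
        report.stats["peak_gain_freq_hz"] = float(grid[int(np.argmax(mag))])

    if "corners" in selected:
        f_lo, f_hi = find_minus3db_corners(spec)
        report.stats["corner_low_hz"] = f_lo
        report.stats["corner_high_hz"] = f_hi

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / f"bench_{spec.label}.json")
        pd.DataFrame(report.summary_rows()).to_csv(
            out / f"bench_{spec.label}.csv", index=False)
        (out / f"bench_{spec.label}_manifest.json").write_text(json.dumps(
            {"spec": spec.to_dict(), "protocols": selected, "seed": seed,
             "full_length": full_length, "opbox_version": __version__},
            indent=2, sort_keys=True) + "\n")
    return report
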