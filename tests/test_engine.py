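"""Multi-subject engine: routing validation, chunk dispatch, onset detection,
ERP accumulation (streaming == batch), real-time spectra, video sync, and the
recording file format."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

import opbox
from opbox import (DeviceChunk, DigitalTrace, ERPAccumulator, RingBuffer,
                   SignalTrace, StreamingERP, VideoSyncRecord, decode_quadrature,
                   detect_onsets, dispatch_chunk, interpolate_frame_times,
                   load_routing, read_recording, realtime_spectrum,
                   start_subject, stop_subject, write_recording,
                   write_example_routing)
from opbox.errors import (ChannelCollisionError, CorruptRecordingError,
                          DuplicateSubjectError, StateError,
                          StreamIntegrityError, UnknownBoxError,
                          UnknownDeviceError, ValidationError)
from opbox.recording import RecordingWriter
from opbox.streams import DeviceStreamTracker


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def test_twelve_subjects_route_36_analog_channels(tmp_path):
    subs, boxes = write_example_routing(tmp_path, n_subjects=12)
    plan = load_routing(subs, boxes)
    assert len(plan.subjects) == 12
    assert plan.n_routed_analog == 36


def test_empty_subject_table_is_a_valid_plan(tmp_path):
    subs = tmp_path / "s.csv"
    subs.write_text("subject_id,box_id,protocol\n")
    _, boxes = write_example_routing(tmp_path, n_subjects=2)
    plan = load_routing(subs, boxes)
    assert plan.subjects == {}


def test_duplicate_subject_is_rejected(tmp_path):
    _, boxes = write_example_routing(tmp_path, n_subjects=2)
    subs = tmp_path / "dup.csv"
    subs.write_text("subject_id,box_id,protocol\nratA,box01,x\nratA,box02,x\n")
    with pytest.raises(DuplicateSubjectError):
        load_routing(subs, boxes)


def test_unknown_box_is_rejected(tmp_path):
    _, boxes = write_example_routing(tmp_path, n_subjects=1)
    subs = tmp_path / "bad.csv"
    subs.write_text("subject_id,box_id,protocol\nratA,box99,x\n")
    with pytest.raises(UnknownBoxError):
        load_routing(subs, boxes)


def test_channel_collision_is_rejected(tmp_path):
    subs = tmp_path / "s.csv"
    subs.write_text("subject_id,box_id,protocol\na,box1,x\nb,box2,x\n")
    boxes = tmp_path / "b.csv"
    boxes.write_text(
        "box_id,device_id,analog_channels,digital_channels,encoder_channels\n"
        "box1,dev0,0;1;5,0,\n"
        "box2,dev0,3;4;5,1,\n")
    with pytest.raises(ChannelCollisionError):
        load_routing(subs, boxes)


def test_unknown_device_is_rejected_when_devices_listed(tmp_path):
    subs, boxes = write_example_routing(tmp_path, n_subjects=2)
    with pytest.raises(UnknownDeviceError):
        load_routing(subs, boxes, devices=["some_other_device"])


def test_missing_columns_are_reported(tmp_path):
    subs = tmp_path / "s.csv"
    subs.write_text("subject,box\n")
    _, boxes = write_example_routing(tmp_path, n_subjects=1)
    with pytest.raises(ValidationError, match="missing columns"):
        load_routing(subs, boxes)


def test_start_stop_state_machine(tmp_path):
    subs, boxes = write_example_routing(tmp_path, n_subjects=2)
    plan = load_routing(subs, boxes)
    start_subject(plan, "rat01", 0.0)
    with pytest.raises(StateError):
        start_subject(plan, "rat01", 1.0)
    with pytest.raises(StateError):
        stop_subject(plan, "rat02", 1.0)
    stop_subject(plan, "rat01", 0.0)       # zero-length recording is valid
    assert plan.subjects["rat01"].stop_time_s == 0.0
    with pytest.raises(ValidationError):
        start_subject(plan, "nobody", 0.0)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _plan3(tmp_path):
    subs, boxes = write_example_routing(tmp_path, n_subjects=3,
                                        subjects_per_device=3)
    return load_routing(subs, boxes)


def _chunks(analog, digital, fs, chunk_len, device="dev0"):
    for i0 in range(0, analog.shape[0], chunk_len):
        yield DeviceChunk(device_id=device, start_index=i0,
                          analog=analog[i0:i0 + chunk_len],
                          digital=digital[i0:i0 + chunk_len], fs=fs)


def test_dispatch_with_no_active_subjects_is_empty(tmp_path, rng):
    plan = _plan3(tmp_path)
    chunk = DeviceChunk("dev0", 0, rng.normal(size=(100, 9)),
                        np.zeros((100, 3), bool), 1000.0)
    assert dispatch_chunk(plan, chunk) == {}


def test_dispatch_reconstructs_each_subject_stream_exactly(tmp_path, rng):
    plan = _plan3(tmp_path)
    fs, n = 1000.0, 60000
    analog = rng.normal(size=(n, 9)).astype(np.float32)
    digital = rng.random((n, 3)) > 0.5
    for sid in plan.subjects:
        start_subject(plan, sid, 0.0)
    got = {sid: [] for sid in plan.subjects}
    for chunk in _chunks(analog, digital, fs, 100):
        for sid, block in dispatch_chunk(plan, chunk).items():
            got[sid].append(block.analog)
    for sid, sub in plan.subjects.items():
        box = plan.boxes[sub.box_id]
        expect = analog[:, list(box.analog_channels)]
        assert np.array_equal(np.concatenate(got[sid]), expect)


def test_subject_slice_is_isolated_from_other_channels(tmp_path, rng):
    plan = _plan3(tmp_path)
    fs = 1000.0
    analog = rng.normal(size=(500, 9)).astype(np.float32)
    start_subject(plan, "rat02", 0.0)     # channels 3,4,5
    chunk = DeviceChunk("dev0", 0, analog, np.zeros((500, 3), bool), fs)
    block1 = dispatch_chunk(plan, chunk)["rat02"]
    perturbed = analog.copy()
    perturbed[:, [0, 1, 2, 6, 7, 8]] += 99.0
    block2 = dispatch_chunk(plan, DeviceChunk("dev0", 0, perturbed,
                                              np.zeros((500, 3), bool), fs))["rat02"]
    assert np.array_equal(block1.analog, block2.analog)


def test_late_start_maps_device_time_to_subject_clock(tmp_path, rng):
    plan = _plan3(tmp_path)
    fs = 1000.0
    analog = rng.normal(size=(2000, 9)).astype(np.float32)
    start_subject(plan, "rat01", 1.0)     # subject sample 0 = device sample 1000
    blocks = []
    for chunk in _chunks(analog, np.zeros((2000, 3), bool), fs, 400):
        out = dispatch_chunk(plan, chunk)
        if "rat01" in out:
            blocks.append(out["rat01"])
    assert blocks[0].sample_index == 0
    assert np.array_equal(blocks[0].analog, analog[1000:1200, 0:3])


def test_chunk_gap_raises_integrity_error():
    tracker = DeviceStreamTracker()
    c1 = DeviceChunk("dev0", 0, np.zeros((100, 2)), np.zeros((100, 1), bool), 1000.0)
    c2 = DeviceChunk("dev0", 150, np.zeros((100, 2)), np.zeros((100, 1), bool), 1000.0)
    tracker.check(c1)
    with pytest.raises(StreamIntegrityError):
        tracker.check(c2)
    assert "dev0" in tracker.discontinuous


# ---------------------------------------------------------------------------
# onset detection
# ---------------------------------------------------------------------------

def _led_trace(duration_s, fs=1000.0, dark=1.0, amp=1.0, noise=0.0, seed=0):
    # 1 s on / 2 s off schedule starting in the off state (phototransistor
    # voltage with a non-zero dark level)
    t = np.arange(int(duration_s * fs)) / fs
    on = (np.mod(t, 3.0) >= 2.0)
    x = dark + amp * on.astype(float)
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, x.size)
    return SignalTrace(x, fs)


def test_square_wave_yields_one_onset_per_cycle():
    tr = _led_trace(30.0)
    onsets = detect_onsets(tr)
    assert onsets.size == 10
    assert onsets[0] == pytest.approx(2.0, abs=1e-3)


def test_led_schedule_36min_yields_720_onsets():
    assert detect_onsets(_led_trace(36 * 60.0)).size == 720


def test_onset_count_robust_to_mild_noise():
    clean = detect_onsets(_led_trace(60.0), refractory_s=1.0)
    noisy = detect_onsets(_led_trace(60.0, noise=0.05, seed=3), refractory_s=1.0)
    assert noisy.size == clean.size == 20


def test_constant_trace_has_no_events():
    assert detect_onsets(SignalTrace(np.ones(1000), 1000.0)).size == 0


# ---------------------------------------------------------------------------
# ERP accumulation
# ---------------------------------------------------------------------------

def test_single_event_mean_is_that_window(rng):
    x = rng.normal(size=(2, 5000))
    acc = ERPAccumulator(2, 100, 900)
    acc.update(x, 1000.0, 0.0, [2.0])
    assert np.array_equal(acc.mean(), x[:, 1900:2900])
    assert acc.count == 1 and acc.skipped == 0


def test_events_outside_data_are_skipped_and_counted(rng):
    x = rng.normal(size=(1, 3000))
    acc = ERPAccumulator(1, 100, 900)
    acc.update(x, 1000.0, 0.0, [0.05, 1.0, 2.95])
    assert acc.count == 1
    assert acc.skipped == 2


def test_streaming_erp_is_bit_identical_to_batch(rng):
    fs, n = 1000.0, 60000
    x = rng.normal(size=(3, n))
    events = np.arange(1.0, 58.0, 3.0)
    batch = ERPAccumulator(3, 100, 900).update(x, fs, 0.0, events)

    acc = ERPAccumulator(3, 100, 900)
    stream = StreamingERP(acc, fs)
    stream.add_events(events)
    for i0 in range(0, n, 100):
        stream.push(x[:, i0:i0 + 100])
    stream.finalize()
    assert acc.count == batch.count
    assert acc.skipped == batch.skipped
    assert np.array_equal(acc.sum, batch.sum)


def test_template_recovered_from_low_snr_averaging():
    # per-trial SNR 0.1 (power, over the template support); 200 trials
    fs = 1000.0
    period, n_trials = 3.0, 200
    duration = 2.0 + period * n_trials + 1.0
    tpl_unit = opbox.evoked_template(opbox.EphysProfile(evoked_amplitude_uv=1.0), fs)
    unit_rms = np.sqrt(np.mean(tpl_unit ** 2)) / 1e-6   # per uV of amplitude
    bg = 80.0
    amp = np.sqrt(0.1) * bg / unit_rms
    prof = opbox.EphysProfile(n_eeg_channels=1, n_emg_channels=0, bands=(),
                              background_rms_uv=bg, evoked_amplitude_uv=amp,
                              event_period_s=period, event_start_s=2.0)
    analog, _, truth = opbox.synth_session(prof, fs, duration, 12345)
    events = truth["event_times_s"][:n_trials]
    acc = ERPAccumulator(1, 100, 900)
    acc.update(analog[0].samples[None, :], fs, 0.0, events)
    mean = acc.mean()[0]
    tpl = truth["template"]
    seg = mean[100:100 + tpl.size]          # event is at sample 100
    corr = np.corrcoef(seg, tpl)[0, 1]
    assert acc.count == n_trials
    assert corr > 0.95


# ---------------------------------------------------------------------------
# real-time spectra
# ---------------------------------------------------------------------------

def test_spectrum_not_ready_until_buffer_full():
    ring = RingBuffer(5000)
    ring.push(np.zeros(1000))
    assert realtime_spectrum(ring, 1000.0) is None


def test_tone_peaks_at_its_frequency():
    t = np.arange(5000) / 1000.0
    est = realtime_spectrum(np.sin(2 * np.pi * 10 * t), 1000.0)
    assert est.freqs_hz[np.argmax(est.log10_power)] == pytest.approx(10.0)
    assert est.freqs_hz.max() <= 100.0


def test_two_tone_power_ratio_follows_amplitude_ratio():
    t = np.arange(5000) / 1000.0
    x = 2.0 * np.sin(2 * np.pi * 6 * t) + 1.0 * np.sin(2 * np.pi * 40 * t)
    est = realtime_spectrum(x, 1000.0)
    p6 = 10 ** est.log10_power[np.argmin(np.abs(est.freqs_hz - 6.0))]
    p40 = 10 ** est.log10_power[np.argmin(np.abs(est.freqs_hz - 40.0))]
    assert p6 / p40 == pytest.approx(4.0, rel=0.05)


def test_mean_white_noise_spectrum_is_flat():
    acc = None
    for seed in range(50):
        x = np.random.default_rng(seed).normal(0, 1, 5000)
        est = realtime_spectrum(x, 1000.0)
        p = 10 ** est.log10_power
        acc = p if acc is None else acc + p
    f = est.freqs_hz
    band_means = [acc[(f >= lo) & (f < lo + 20) & (f > 0)].mean()
                  for lo in range(0, 100, 20)]
    assert max(band_means) / min(band_means) < 1.15


def test_streaming_ring_spectrum_equals_batch(rng):
    fs, n = 1000.0, 20000
    x = rng.normal(0, 1, n)
    ring = RingBuffer(5000)
    for i0 in range(0, n, 100):
        ring.push(x[i0:i0 + 100])
    stream_est = realtime_spectrum(ring, fs)
    batch_est = realtime_spectrum(x, fs)
    assert np.array_equal(stream_est.log10_power, batch_est.log10_power)


# ---------------------------------------------------------------------------
# quadrature decode edge cases
# ---------------------------------------------------------------------------

def test_static_lines_decode_to_zero():
    a = DigitalTrace(np.zeros(100, bool), 1000.0)
    b = DigitalTrace(np.ones(100, bool), 1000.0)
    dec = decode_quadrature(a, b)
    assert np.all(dec.counts == 0)


def test_swapped_channels_negate_counts():
    ang = SignalTrace(np.linspace(0, 4 * np.pi, 8000), 1000.0)
    a, b = opbox.quadrature_from_angle(ang, 200)
    fwd = decode_quadrature(a, b).counts[-1]
    rev = decode_quadrature(b, a).counts[-1]
    assert fwd == 400 and rev == -400


def test_double_step_counts_as_invalid_transition():
    a = DigitalTrace(np.array([0, 1, 0, 1], bool), 1000.0)
    b = DigitalTrace(np.array([0, 1, 0, 1], bool), 1000.0)  # (0,0)<->(1,1)
    dec = decode_quadrature(a, b)
    assert dec.invalid_transitions == 3
    assert dec.counts[-1] == 0


# ---------------------------------------------------------------------------
# video synchronization
# ---------------------------------------------------------------------------

def test_exact_linear_registration_interpolates_exactly():
    sync = VideoSyncRecord()
    for j in range(1, 61):          # polls at 10 Hz, frames at exactly 30 Hz
        t = 0.1 * j
        sync.register(t, int(np.floor(t * 30)))
    frames, times = interpolate_frame_times(sync)
    assert np.allclose(times, frames / 30.0, atol=1e-9)


def test_constant_camera_latency_is_recovered_within_half_frame():
    latency, cam_fps, fs = 0.0661, 30.0, 1000.0
    led = _led_trace(60.0, fs=fs)
    analog_onsets = detect_onsets(led, refractory_s=1.0)
    rng = np.random.default_rng(4)
    sync = VideoSyncRecord()
    for j in range(1, 600):
        t = 0.1 * j + rng.uniform(0, 0.01)      # poll-timer jitter
        sync.register(t, max(int(np.floor((t - latency) * cam_fps)), 0))
    frames, times = interpolate_frame_times(sync)
    delays = []
    for t_on in analog_onsets:
        k = int(np.ceil(t_on * cam_fps))        # first frame showing the LED
        if frames[0] <= k <= frames[-1]:
            delays.append(times[k - frames[0]] - t_on)
    delays = np.array(delays)
    assert delays.size >= 15
    assert abs(delays.mean() - latency) < 0.5 / cam_fps
    # no drift between first and last half of the recording
    half = delays.size // 2
    _, p = spstats.ttest_ind(delays[:half], delays[half:])
    assert p > 0.05


def test_non_monotone_frames_are_an_integrity_error():
    sync = VideoSyncRecord()
    sync.register(0.1, 3)
    with pytest.raises(StreamIntegrityError):
        sync.register(0.2, 2)
    with pytest.raises(StreamIntegrityError):
        sync.register(0.1, 5)


# ---------------------------------------------------------------------------
# recording format
# ---------------------------------------------------------------------------

def _meta(n_ch=3, fs=1000.0):
    return {"subject_id": "ratX", "fs": fs,
            "channel_names": [f"a{k}" for k in range(n_ch)], "units": "V"}


def test_recording_round_trip_is_bit_exact(tmp_path, rng):
    samples = rng.normal(size=(60000, 3)).astype(np.float32)
    events = [(1.0, "d0", "ttl_onset"), (4.0, "d0", "ttl_onset")]
    path = write_recording(tmp_path / "ratX.obx", _meta(), samples, events)
    rec = read_recording(path)
    assert np.array_equal(rec.samples, samples)
    assert rec.metadata["subject_id"] == "ratX"
    assert list(rec.events["time_s"]) == [1.0, 4.0]
    assert list(rec.events["label"]) == ["ttl_onset", "ttl_onset"]


def test_partial_final_frame_is_a_corruption_error(tmp_path, rng):
    samples = rng.normal(size=(100, 3)).astype(np.float32)
    path = write_recording(tmp_path / "bad.obx", _meta(), samples)
    with open(path, "ab") as fh:
        fh.write(b"\x00\x01")                    # 2 stray bytes
    with pytest.raises(CorruptRecordingError) as exc:
        read_recording(path)
    assert exc.value.byte_offset == 100 * 3 * 4


def test_writer_rejects_wrong_channel_count_and_use_after_close(tmp_path):
    w = RecordingWriter(tmp_path / "x.obx", _meta(n_ch=2))
    with pytest.raises(ValidationError):
        w.write_block(np.zeros((10, 3), np.float32))
    w.close()
    with pytest.raises(StateError):
        w.write_block(np.zeros((10, 2), np.float32))


def test_incremental_writes_equal_one_shot(tmp_path, rng):
    samples = rng.normal(size=(1000, 2)).astype(np.float32)
    with RecordingWriter(tmp_path / "inc.obx", _meta(n_ch=2)) as w:
        for i0 in range(0, 1000, 64):
            w.write_block(samples[i0:i0 + 64])
    one = write_recording(tmp_path / "one.obx", _meta(n_ch=2), samples)
    assert (tmp_path / "inc.obx").read_bytes() == one.read_bytes()
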