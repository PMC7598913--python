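"""CSV-driven subject/box/channel routing.

Two spreadsheets describe a rig: a subjects table (which subject sits in
which box, under which protocol) and a boxes table (which device channels
each box's amplifier occupies).  Schemas::

    InfoSubjects: subject_id,box_id,protocol
    InfoBoxes:    box_id,device_id,analog_channels,digital_channels,encoder_channels

Channel lists are semicolon-separated indices, e.g. ``0;1;2``; the encoder
field is an optional pair.  A validated :class:`RoutingPlan` also tracks each
subject's start/stop times; a subject's own session clock is zeroed at its
start, so asynchronous starts never perturb other subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import (ChannelCollisionError, DuplicateSubjectError, StateError,
                     UnknownBoxError, UnknownDeviceError, ValidationError)

SUBJECTS_COLUMNS = ["subject_id", "box_id", "protocol"]
BOXES_COLUMNS = ["box_id", "device_id", "analog_channels", "digital_channels",
                 "encoder_channels"]


@dataclass
class SubjectAssignment:
    subject_id: str
    box_id: str
    protocol: str = ""
    active: bool = False
    start_time_s: Optional[float] = None
    stop_time_s: Optional[float] = None

    def start_sample(self, fs: float) -> Optional[int]:
        if self.start_time_s is None:
            return None
        return int(math.ceil(self.start_time_s * fs - 1e-9))

    def stop_sample(self, fs: float) -> Optional[int]:
        if self.stop_time_s is None:
            return None
        return int(math.ceil(self.stop_time_s * fs - 1e-9))


@dataclass
class BoxChannelMap:
    box_id: str
    device_id: str
    analog_channels: tuple
    digital_channels: tuple = ()
    encoder_channels: Optional[tuple] = None

    def __post_init__(self):
        self.analog_channels = tuple(int(c) for c in self.analog_channels)
        self.digital_channels = tuple(int(c) for c in self.digital_channels)
        if self.encoder_channels is not None:
            self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
            if len(self.encoder_channels) not in (0, 2):
                raise ValidationError(
                    f"box {self.box_id}: encoder_channels must be a pair")
            if len(self.encoder_channels) == 0:
                self.encoder_channels = None


@dataclass
class RoutingPlan:
    subjects: dict = field(default_factory=dict)   # subject_id -> SubjectAssignment
    boxes: dict = field(default_factory=dict)      # box_id -> BoxChannelMap
    devices: Optional[set] = None                  # known device ids, if stated

    def validate(self) -> "RoutingPlan":
        for sid, sub in self.subjects.items():
            if sub.box_id not in self.boxes:
                raise UnknownBoxError(
                    f"subject {sid!r} references unknown box {sub.box_id!r}")
        if self.devices is not None:
            for box in self.boxes.values():
                if box.device_id not in self.devices:
                    raise UnknownDeviceError(
                        f"box {box.box_id!r} references unknown device "
                        f"{box.device_id!r}")
        seen = {}
        for box in self.boxes.values():
            for kind, chans in (("analog", box.analog_channels),
                                ("digital", box.digital_channels
                                 + (box.encoder_channels or ()))):
                for c in chans:
                    key = (box.device_id, kind, c)
                    if key in seen:
                        raise ChannelCollisionError(
                            f"device {box.device_id!r} {kind} channel {c} claimed "
                            f"by both box {seen[key]!r} and box {box.box_id!r}")
                    seen[key] = box.box_id
        return self

    @property
    def n_routed_analog(self) -> int:
        return sum(len(self.boxes[s.box_id].analog_channels)
                   for s in self.subjects.values())

    def subjects_on_device(self, device_id: str):
        return [s for s in self.subjects.values()
                if self.boxes[s.box_id].device_id == device_id]


def _parse_index_list(text) -> tuple:
    text = str(text).strip()
    if not text or text.lower() == "nan":
        return ()
    return tuple(int(tok) for tok in text.split(";") if tok.strip() != "")


def load_routing(subjects_csv, boxes_csv, devices=None) -> RoutingPlan:
    """Read and validate the two routing spreadsheets.

    ``devices`` optionally lists the device ids the backend actually exposes;
    when given, a box naming any other device is a validation error.  Unused
    device channels are allowed -- the backend reports every channel and the
    plan selects what each subject needs.
    """
    subs = pd.read_csv(subjects_csv, dtype=str, keep_default_na=False)
    boxes = pd.read_csv(boxes_csv, dtype=str, keep_default_na=False)
    for df, cols, name in ((subs, SUBJECTS_COLUMNS, "subjects"),
                           (boxes, BOXES_COLUMNS, "boxes")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"{name} CSV is missing columns {missing}")

    plan = RoutingPlan(devices=set(devices) if devices is not None else None)
    for _, row in boxes.iterrows():
        box = BoxChannelMap(
            box_id=row["box_id"].strip(),
            device_id=row["device_id"].strip(),
            analog_channels=_parse_index_list(row["analog_channels"]),
            digital_channels=_parse_index_list(row["digital_channels"]),
            encoder_channels=_parse_index_list(row["encoder_channels"]) or None,
        )
        if box.box_id in plan.boxes:
            raise ValidationError(f"box {box.box_id!r} defined twice")
        plan.boxes[box.box_id] = box

    for _, row in subs.iterrows():
        sid = row["subject_id"].strip()
        if not sid:
            continue
        if sid in plan.subjects:
            raise DuplicateSubjectError(f"subject {sid!r} listed twice")
        plan.subjects[sid] = SubjectAssignment(
            subject_id=sid, box_id=row["box_id"].strip(),
            protocol=row["protocol"].strip())
    return plan.validate()


def start_subject(plan: RoutingPlan, subject_id: str, t: float) -> RoutingPlan:
    """Mark a subject's recording as started at device time ``t`` (seconds).

    The subject's own session clock is zeroed at ``t``; other subjects are
    unaffected.  Starting an already-active subject is a state error.
    """
    if subject_id not in plan.subjects:
        raise ValidationError(f"unknown subject {subject_id!r}")
    sub = plan.subjects[subject_id]
    if sub.active:
        raise StateError(f"subject {subject_id!r} already started")
    sub.active = True
    sub.start_time_s = float(t)
    sub.stop_time_s = None
    return plan


def stop_subject(plan: RoutingPlan, subject_id: str, t: float) -> RoutingPlan:
    """Mark a subject's recording as stopped at device time ``t``."""
    if subject_id not in plan.subjects:
        raise ValidationError(f"unknown subject {subject_id!r}")
    sub = plan.subjects[subject_id]
    if not sub.active:
        raise StateError(f"subject {subject_id!r} is not recording")
    if sub.start_time_s is not None and t < sub.start_time_s:
        raise ValidationError("stop time precedes start time")
    sub.active = False
    sub.stop_time_s = float(t)
    return plan


def write_example_routing(out_dir, n_subjects: int = 12,
                          analog_per_subject: int = 3,
                          digital_per_subject: int = 1,
                          subjects_per_device: int = 6):
    """Write a pair of example routing CSVs (one box per subject, channels
    packed onto as many devices as needed).  Returns the two paths."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub_rows, box_rows = [], []
    for i in range(n_subjects):
        dev = i // subjects_per_device
        slot = i % subjects_per_device
        a0 = slot * analog_per_subject
        d0 = slot * digital_per_subject
        sid, bid = f"rat{i+1:02d}", f"box{i+1:02d}"
        sub_rows.append({"subject_id": sid, "box_id": bid, "protocol": "sim"})
        box_rows.append({
            "box_id": bid, "device_id": f"dev{dev}",
            "analog_channels": ";".join(str(a0 + k) for k in range(analog_per_subject)),
            "digital_channels": ";".join(str(d0 + k) for k in range(digital_per_subject)),
            "encoder_channels": "",
        })
    subjects_csv = out / "InfoSubjects.csv"
    boxes_csv = out / "InfoBoxes.csv"
    pd.DataFrame(sub_rows, columns=SUBJECTS_COLUMNS).to_csv(subjects_csv, index=False)
    pd.DataFrame(box_rows, columns=BOXES_COLUMNS).to_csv(boxes_csv, index=False)
    return subjects_csv, boxes_csv
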