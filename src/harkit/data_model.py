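"""Unified data model for multi-device wearable sensor recordings.

A recording session is represented by a :class:`Session`: immutable
:class:`Metadata` (who, when, at what rate, with which devices and
sensors) plus an ordered list of :class:`Sample` objects, one per tick
of the shared sampling clock.  Each sample carries one value per
declared channel and an integer activity label (0 is reserved for the
null / transition class; 1..12 are the activity codes of the standard
12-activity protocol: standing, sitting, lying, walking, stairs, waist
bends, arm elevation, knee bends, cycling, jogging, running, jumping).

Two serializations are supported:

* the plain-text log dialect of the public MHEALTH recordings —
  whitespace-delimited rows, no header, one row per sample, signal
  columns in a fixed device/sensor/axis order and the integer label
  last;
* a JSON session document with the metadata block stored once at the
  top level (never repeated per sample) and the sample array beside it.

Channel names are ``device/sensor/axis`` paths, e.g. ``chest/acc/x``,
and are globally unique within a session.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "ChannelLookupError",
    "SensorSpec",
    "DeviceSpec",
    "Metadata",
    "Sample",
    "Session",
    "ChannelMatrix",
    "mhealth_default_layout",
    "acceleration_channels",
    "read_mhealth_log",
    "write_mhealth_log",
    "session_to_json",
    "session_from_json",
    "select_channels",
]

#: Maximum activity code; 0 is the null/transition class.
MAX_LABEL = 12

#: Absolute tolerance (seconds) when checking sampling-clock regularity.
TIME_TOLERANCE = 1e-9


class ParseError(ValueError):
    """Raised when a log file or JSON document cannot be parsed."""


class ChannelLookupError(KeyError):
    """Raised when a requested channel name is not declared in the metadata."""


@dataclass(frozen=True)
class SensorSpec:
    """One sensing modality of a device (e.g. a triaxial accelerometer)."""

    sensor_type: str
    units: str
    axes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("sensor must declare at least one axis")
        object.__setattr__(self, "axes", tuple(self.axes))


@dataclass(frozen=True)
class DeviceSpec:
    """A body-worn device holding one or more sensors."""

    device_name: str
    sensors: tuple[SensorSpec, ...]

    def __post_init__(self) -> None:
        if not self.sensors:
            raise ValueError(f"device {self.device_name!r} declares no sensors")
        object.__setattr__(self, "sensors", tuple(self.sensors))

    def channel_names(self) -> list[str]:
        return [
            f"{self.device_name}/{sensor.sensor_type}/{axis}"
            for sensor in self.sensors
            for axis in sensor.axes
        ]


@dataclass(frozen=True)
class Metadata:
    """Session-level metadata, stored once per session.

    Times are seconds; ``sampling_rate`` is Hz and applies to every
    channel (all modalities share one clock).
    """

    session_id: str
    subject_id: str
    start_time: float
    end_time: float
    sampling_rate: float
    devices: tuple[DeviceSpec, ...]

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.end_time < self.start_time:
            raise ValueError("end_time must be >= start_time")
        names = [d.device_name for d in self.devices]
        if len(set(names)) != len(names):
            raise ValueError("device names must be unique")
        object.__setattr__(self, "devices", tuple(self.devices))

    def channel_names(self) -> list[str]:
        names: list[str] = []
        for device in self.devices:
            names.extend(device.channel_names())
        if len(set(names)) != len(names):
            raise ValueError("channel names must be globally unique")
        return names

    @property
    def n_channels(self) -> int:
        return len(self.channel_names())


@dataclass(frozen=True)
class Sample:
    """One tick of the biodata stream: timestamp, channel values, label."""

    timestamp: float
    values: tuple[float, ...]
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if not (0 <= self.label <= MAX_LABEL):
            raise ValueError(f"label {self.label} outside 0..{MAX_LABEL}")


@dataclass(frozen=True)
class Session:
    """A full recording: metadata plus the ordered sample stream."""

    metadata: Metadata
    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        self.validate()

    def validate(self) -> None:
        meta = self.metadata
        n_channels = meta.n_channels
        step = 1.0 / meta.sampling_rate
        prev_t: float | None = None
        for i, sample in enumerate(self.samples):
            if len(sample.values) != n_channels:
                raise ValueError(
                    f"sample {i} has {len(sample.values)} values, "
                    f"metadata declares {n_channels} channels"
                )
            if prev_t is not None:
                gap = sample.timestamp - prev_t
                if gap <= 0:
                    raise ValueError(f"timestamps not strictly increasing at sample {i}")
                if abs(gap - step) > TIME_TOLERANCE:
                    raise ValueError(
                        f"irregular sampling at sample {i}: gap {gap!r} != {step!r}"
                    )
            prev_t = sample.timestamp
        duration = meta.end_time - meta.start_time
        if len(self.samples) > duration * meta.sampling_rate + 1 + TIME_TOLERANCE:
            raise ValueError("more samples than the session duration allows")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    @property
    def values(self) -> np.ndarray:
        """All channel values as a (samples x channels) float array."""
        if not self.samples:
            return np.empty((0, self.metadata.n_channels))
        return np.array([s.values for s in self.samples], dtype=np.float64)


@dataclass
class ChannelMatrix:
    """A numeric view of selected channels: values, labels and the rate.

    This is the working container of the processing chain; it carries no
    device tree, only the ordered channel names, the (samples x channels)
    value table, the per-row integer labels and the sampling rate.
    """

    channel_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x channels)")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("values and labels disagree on row count")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("values and channel_names disagree on column count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def mhealth_default_layout() -> tuple[DeviceSpec, ...]:
    """Device tree matching the column order of the public MHEALTH logs.

    23 signal columns: chest acceleration (x, y, z), 2-lead ECG, then for
    the left ankle and the right wrist each a triaxial accelerometer,
    gyroscope and magnetometer.  The 24th column of a log row is the
    integer activity label.
    """
    acc = lambda: SensorSpec("acc", "m/s^2", ("x", "y", "z"))  # noqa: E731
    gyro = lambda: SensorSpec("gyro", "deg/s", ("x", "y", "z"))  # noqa: E731
    mag = lambda: SensorSpec("mag", "uT", ("x", "y", "z"))  # noqa: E731
    return (
        DeviceSpec("chest", (acc(), SensorSpec("ecg", "mV", ("lead1", "lead2")))),
        DeviceSpec("left-ankle", (acc(), gyro(), mag())),
        DeviceSpec("right-wrist", (acc(), gyro(), mag())),
    )


def acceleration_channels(layout: Iterable[DeviceSpec] | Metadata) -> list[str]:
    """Names of all accelerometer channels, in declaration order.

    For the default layout this is the 9-channel set used for activity
    recognition (chest, left ankle and right wrist, x/y/z each).
    """
    devices = layout.devices if isinstance(layout, Metadata) else tuple(layout)
    return [
        f"{d.device_name}/{s.sensor_type}/{axis}"
        for d in devices
        for s in d.sensors
        if s.sensor_type == "acc"
        for axis in s.axes
    ]


def read_mhealth_log(
    path,
    column_map: Sequence[DeviceSpec] | None = None,
    sampling_rate: float = 50.0,
    subject_id: str = "unknown",
    session_id: str | None = None,
) -> Session:
    """Parse a whitespace-delimited sensor log into a :class:`Session`.

    The log carries no time column; timestamps are synthesized as
    ``i / sampling_rate`` from the row index.  ``column_map`` describes
    the channel layout (default: the 23-signal-column MHEALTH dialect);
    the final column is always the integer activity label.

    Raises :class:`ParseError` on an empty file, a row with the wrong
    column count or a non-numeric cell, naming the offending line.
    """
    devices = tuple(column_map) if column_map is not None else mhealth_default_layout()
    channel_names = [n for d in devices for n in d.channel_names()]
    n_cols = len(channel_names) + 1

    samples: list[Sample] = []
    step = 1.0 / sampling_rate
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                values = tuple(float(p) for p in parts[:-1])
                label = int(parts[-1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
            i = len(samples)
            samples.append(Sample(timestamp=i * step, values=values, label=label))
    if not samples:
        raise ParseError(f"{path}: empty log file")

    meta = Metadata(
        session_id=session_id if session_id is not None else str(path),
        subject_id=subject_id,
        start_time=0.0,
        end_time=(len(samples) - 1) * step,
        sampling_rate=sampling_rate,
        devices=devices,
    )
    return Session(metadata=meta, samples=tuple(samples))


def write_mhealth_log(session: Session, path) -> None:
    """Write a session in the MHEALTH log dialect.

    One whitespace-delimited row per sample, channels in declared order,
    the integer label last.  Values are rendered with ``repr`` so a
    read-back reproduces them bit-for-bit.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for sample in session.samples:
            cells = [repr(v) for v in sample.values]
            cells.append(str(sample.label))
            fh.write("\t".join(cells))
            fh.write("\n")


def _metadata_to_dict(meta: Metadata) -> dict:
    return {
        "session_id": meta.session_id,
        "subject_id": meta.subject_id,
        "start_time": meta.start_time,
        "end_time": meta.end_time,
        "sampling_rate": meta.sampling_rate,
        "devices": [
            {
                "device_name": d.device_name,
                "sensors": [
                    {"sensor_type": s.sensor_type, "units": s.units, "axes": list(s.axes)}
                    for s in d.sensors
                ],
            }
            for d in meta.devices
        ],
    }


def _metadata_from_dict(d: dict) -> Metadata:
    devices = tuple(
        DeviceSpec(
            device_name=dev["device_name"],
            sensors=tuple(
                SensorSpec(s["sensor_type"], s["units"], tuple(s["axes"]))
                for s in dev["sensors"]
            ),
        )
        for dev in d["devices"]
    )
    return Metadata(
        session_id=d["session_id"],
        subject_id=d["subject_id"],
        start_time=float(d["start_time"]),
        end_time=float(d["end_time"]),
        sampling_rate=float(d["sampling_rate"]),
        devices=devices,
    )


def session_to_json(session: Session) -> str:
    """Serialize a session as a JSON document.

    The metadata block appears exactly once at the top level; the sample
    array holds ``{"t": ..., "v": [...], "label": ...}`` records.  Keys
    are sorted so the rendering is canonical: parsing and re-serializing
    is byte-stable.
    """
    doc = {
        "metadata": _metadata_to_dict(session.metadata),
        "samples": [
            {"t": s.timestamp, "v": list(s.values), "label": s.label}
            for s in session.samples
        ],
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def session_from_json(text: str) -> Session:
    """Parse a JSON session document produced by :func:`session_to_json`."""
    try:
        doc = json.loads(text)
        meta = _metadata_from_dict(doc["metadata"])
        samples = tuple(
            Sample(timestamp=float(s["t"]), values=tuple(s["v"]), label=int(s["label"]))
            for s in doc["samples"]
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ParseError(f"invalid session document: {exc}") from None
    return Session(metadata=meta, samples=samples)


def select_channels(session: Session, channel_names: Sequence[str]) -> ChannelMatrix:
    """Extract the named channels (in the requested order) as a matrix.

    Labels and the sampling rate are copied through; values are never
    altered.  An unknown name raises :class:`ChannelLookupError`.
    """
    declared = session.metadata.channel_names()
    index = {name: i for i, name in enumerate(declared)}
    cols = []
    for name in channel_names:
        if name not in index:
            raise ChannelLookupError(f"channel {name!r} not declared in session metadata")
        cols.append(index[name])
    all_values = session.values
    values = all_values[:, cols] if all_values.size else all_values[:, cols]
    return ChannelMatrix(
        channel_names=tuple(channel_names),
        values=values,
        labels=session.labels,
        sampling_rate=session.metadata.sampling_rate,
    )
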