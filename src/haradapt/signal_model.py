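"""Data model and I/O for 10-channel wearable recordings.

A recording is a 20 Hz multichannel time series from a thigh-worn node
combining a muscle-deformation air-pressure channel (an airbag pressed by
the rectus femoris, read out in kPa) with a 9-axis inertial unit
(accelerometer in g, gyroscope in deg/s, on-chip-fused Euler angles in
degrees).  Every sample carries one of seven activity labels.

This module owns the pressure-voltage conversion, CSV reading/writing and
the 2 s / 50 %-overlap sliding-window segmentation that all downstream
feature extraction operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven activity classes, in fixed order. Integer codes are 1-based
#: positions in this tuple.
ACTIVITIES = ("SIT", "STAND", "LIE", "WALK", "RUN", "UP", "DOWN")
ACTIVITY_CODES = {a: i + 1 for i, a in enumerate(ACTIVITIES)}
UNLABELED = "UNLABELED"

#: Fixed channel order; feature-vector layout depends on it.
CHANNELS = (
    "pressure",
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "euler_roll", "euler_pitch", "euler_yaw",
)

DEFAULT_SAMPLE_RATE = 20.0

# Sensor output span: 0.5-4.5 V maps linearly onto 0-40 kPa.
_VOLT_MIN, _VOLT_MAX = 0.5, 4.5


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class LabelError(ValueError):
    """An activity label is not one of the known codes."""


def labels_to_codes(labels) -> np.ndarray:
    """Map activity names to 1-based integer codes."""
    labels = np.asarray(labels)
    try:
        return np.array([ACTIVITY_CODES[str(l)] for l in labels], dtype=int)
    except KeyError as e:
        raise LabelError(
            f"unknown activity label {e.args[0]!r}; valid codes: {ACTIVITIES}"
        ) from None


def codes_to_labels(codes) -> np.ndarray:
    codes = np.asarray(codes, dtype=int)
    if codes.size and (codes.min() < 1 or codes.max() > len(ACTIVITIES)):
        raise LabelError(f"codes must lie in 1..{len(ACTIVITIES)}")
    return np.array([ACTIVITIES[c - 1] for c in codes])


def voltage_to_pressure(voltage):
    """Convert the air-pressure sensor's voltage output to kPa.

    The transducer is linear over its 0.5-4.5 V span, which maps onto
    0-40 kPa: ``a = (b - 0.5) * 10`` with ``b`` in volts and ``a`` in kPa.
    Vectorizes over array input.  Voltages outside the stated span are
    converted anyway but trigger a warning (out of the sensor's range).
    """
    v = np.asarray(voltage, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    if np.any((v < _VOLT_MIN) | (v > _VOLT_MAX)):
        warnings.warn(
            f"voltage outside the sensor's {_VOLT_MIN}-{_VOLT_MAX} V range; "
            "converted value returned anyway",
            stacklevel=2,
        )
    out = (v - _VOLT_MIN) * 10.0
    return float(out) if np.isscalar(voltage) else out


@dataclass
class SensorRecording:
    """One subject's labeled 10-channel time series.

    ``values`` is ``[n_samples, 10]`` in physical units (kPa, g, deg/s,
    degrees) with columns ordered as :data:`CHANNELS`; ``labels`` holds one
    activity code (or ``UNLABELED``) per sample.
    """

    subject_id: str
    values: np.ndarray
    labels: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    channels: tuple = CHANNELS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2 or self.values.shape[1] != len(CHANNELS):
            raise ValueError(
                f"values must be [n_samples, {len(CHANNELS)}], "
                f"got {self.values.shape}"
            )
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal the number of samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        bad = set(map(str, self.labels)) - set(ACTIVITIES) - {UNLABELED}
        if bad:
            raise LabelError(
                f"unknown activity label(s) {sorted(bad)}; valid codes: {ACTIVITIES}"
            )
        if self.values.size and self.values[:, 0].min() < 0:
            raise ValueError("pressure channel must be non-negative (kPa)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class Segment:
    """One fixed-length window with a single activity label."""

    values: np.ndarray  # [window_samples, 10]
    label: str
    subject_id: str
    start_index: int


@dataclass
class SegmentSet:
    """Ordered collection of pure-label windows from one or more recordings."""

    segments: list = field(default_factory=list)
    window_seconds: float = 2.0
    overlap_fraction: float = 0.5
    n_dropped: int = 0  # impure/unlabeled windows discarded by the purity rule

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=object)

    @property
    def subjects(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.segments], dtype=object)


def segment(
    recording: SensorRecording,
    window_seconds: float = 2.0,
    overlap_fraction: float = 0.5,
) -> SegmentSet:
    """Slide a fixed window over a recording and keep pure-label windows.

    At 20 Hz the default 2 s window covers 40 samples and advances by 20
    (50 % overlap).  Windows are half-open ``[start, start + w)`` with
    0-based starts at multiples of the step.  A window is kept only when
    all of its samples share one (known) activity label; mixed or
    unlabeled windows are dropped and counted in ``n_dropped``.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    w = int(round(window_seconds * recording.sample_rate))
    step = int(round(w * (1 - overlap_fraction)))
    step = max(step, 1)
    out = SegmentSet(window_seconds=window_seconds, overlap_fraction=overlap_fraction)
    n = recording.n_samples
    if n < w:
        warnings.warn(
            f"recording {recording.subject_id!r} shorter than one window "
            f"({n} < {w} samples); empty segment set",
            stacklevel=2,
        )
        return out
    for start in range(0, n - w + 1, step):
        lab = recording.labels[start : start + w]
        first = str(lab[0])
        if first != UNLABELED and all(str(x) == first for x in lab):
            out.segments.append(
                Segment(
                    values=recording.values[start : start + w].copy(),
                    label=first,
                    subject_id=recording.subject_id,
                    start_index=start,
                )
            )
        else:
            out.n_dropped += 1
    return out


def read_recording(
    path,
    subject_id: str | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    pressure_unit: str = "kPa",
    column_map: dict | None = None,
) -> SensorRecording:
    """Read one subject's CSV recording.

    The file must have a header naming the 10 channel columns plus a
    ``label`` column (``column_map`` may rename file columns onto the
    canonical names).  When ``pressure_unit`` is ``"V"`` the pressure
    column is converted from volts to kPa on the way in.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in (*CHANNELS, "label") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    vals = np.empty((len(df), len(CHANNELS)), dtype=float)
    for j, c in enumerate(CHANNELS):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(col.isna().to_numpy() & df[c].notna().to_numpy())
        if col.isna().any():
            row = int(bad[0]) if bad.size else int(np.flatnonzero(col.isna())[0])
            raise ParseError(f"non-numeric value in column {c!r} at data row {row}")
        vals[:, j] = col.to_numpy()
    if pressure_unit == "V":
        vals[:, 0] = voltage_to_pressure(vals[:, 0])
    elif pressure_unit != "kPa":
        raise SchemaError(f"pressure_unit must be 'kPa' or 'V', got {pressure_unit!r}")
    labels = df["label"].astype(str).to_numpy()
    if subject_id is None:
        subject_id = str(df["subject"].iloc[0]) if "subject" in df.columns else "unknown"
    return SensorRecording(
        subject_id=subject_id, values=vals, labels=labels, sample_rate=sample_rate
    )


def write_recording(recording: SensorRecording, path) -> None:
    """Write a recording as CSV (columns: time_s, 10 channels, label)."""
    t = np.arange(recording.n_samples) / recording.sample_rate
    df = pd.DataFrame({"time_s": t})
    for j, c in enumerate(CHANNELS):
        df[c] = recording.values[:, j]
    df["label"] = recording.labels
    df.to_csv(path, index=False)
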