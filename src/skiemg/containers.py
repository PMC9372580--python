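"""Domain containers for on-snow ski sessions and the tidy per-turn metric table.

A *skier-session* is one athlete on one day in one discipline — the grouping
unit of the random-intercept models downstream. Its raw signals are five
surface-EMG channels of the right thigh sampled at 1,926 Hz and five motion
channels (tri-axial trunk acceleration in g, knee and hip goniometer angles
in degrees with 180° = full extension) sampled at 148 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EMG_RATE_HZ = 1926.0
MOTION_RATE_HZ = 148.0

MUSCLES = ("VM", "RF", "VL", "BF", "SMST")
EXTENSORS = ("VM", "RF", "VL")
FLEXORS = ("BF", "SMST")
JOINTS = ("knee", "hip")
DISCIPLINES = ("SL", "GS", "SG", "DH")
LEGS = ("IL", "OL")

#: channel name -> (sampling rate Hz, units)
CHANNEL_SCHEMA = {
    "VM": (EMG_RATE_HZ, "V"),
    "RF": (EMG_RATE_HZ, "V"),
    "VL": (EMG_RATE_HZ, "V"),
    "BF": (EMG_RATE_HZ, "V"),
    "SMST": (EMG_RATE_HZ, "V"),
    "acc_x": (MOTION_RATE_HZ, "g"),
    "acc_y": (MOTION_RATE_HZ, "g"),
    "acc_z": (MOTION_RATE_HZ, "g"),
    "knee_angle": (MOTION_RATE_HZ, "deg"),
    "hip_angle": (MOTION_RATE_HZ, "deg"),
}

#: metrics the tidy table may hold
METRIC_NAMES = (
    "rms_pct_mvc",
    "mpf_hz",
    "burst_ms",
    "burst_pct",
    "turn_time_ms",
    "min_angle_deg",
    "max_angle_deg",
    "amplitude_deg",
    "peak_flex_vel_dps",
    "peak_ext_vel_dps",
    "run_time_s",
)


class ValidationError(ValueError):
    """Structured validation failure naming the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


@dataclass
class Channel:
    """One uniform-rate signal, time measured in seconds from session start."""

    rate_hz: float
    samples: np.ndarray
    units: str = ""
    start_s: float = 0.0

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(len(self.samples)) / self.rate_hz


@dataclass
class RunMarker:
    run_index: int
    start_s: float
    end_s: float
    complete: bool = True


@dataclass
class SessionRecording:
    session_id: str
    discipline: str
    channels: dict[str, Channel]
    run_markers: list[RunMarker]
    mvc_references: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.discipline not in DISCIPLINES:
            raise ValidationError("discipline", f"unknown discipline {self.discipline!r}")
        for name, (rate, _units) in CHANNEL_SCHEMA.items():
            if name not in self.channels:
                raise ValidationError(name, "channel missing from session")
            ch = self.channels[name]
            if ch.rate_hz <= 0:
                raise ValidationError(name, f"non-positive sampling rate {ch.rate_hz}")
            if abs(ch.rate_hz - rate) > 1e-6:
                raise ValidationError(name, f"rate {ch.rate_hz} Hz != expected {rate} Hz")
            if np.any(~np.isfinite(ch.samples)):
                raise ValidationError(name, "non-finite samples")
        for joint_ch in ("knee_angle", "hip_angle"):
            s = self.channels[joint_ch].samples
            if s.size and (s.min() <= 0 or s.max() > 180.0):
                raise ValidationError(joint_ch, "angles must lie in (0, 180] degrees")
        if not self.run_markers:
            raise ValidationError("run_markers", "no runs in session")
        prev_end = -np.inf
        for m in self.run_markers:
            if m.end_s <= m.start_s:
                raise ValidationError("run_markers", f"run {m.run_index} has end <= start")
            if m.start_s < prev_end:
                raise ValidationError("run_markers", f"run {m.run_index} overlaps previous run")
            prev_end = m.end_s
        if not any(m.complete for m in self.run_markers):
            raise ValidationError("run_markers", "no complete run in session")

    def run_marker(self, run_index: int) -> RunMarker | None:
        for m in self.run_markers:
            if m.run_index == run_index:
                return m
        return None


@dataclass
class MvcTrial:
    """One maximal voluntary contraction trial (isometric extension or flexion)."""

    muscle_group: str  # "extension" | "flexion"
    force_n: np.ndarray
    force_rate_hz: float
    emg: dict[str, np.ndarray]
    emg_rate_hz: float = EMG_RATE_HZ

    def validate(self) -> None:
        if self.muscle_group not in ("extension", "flexion"):
            raise ValidationError("muscle_group", f"unknown group {self.muscle_group!r}")
        if np.any(self.force_n < 0):
            raise ValidationError("force_n", "negative force")


@dataclass
class MvcTrialSet:
    trials: list[MvcTrial]

    def validate(self) -> None:
        groups = {t.muscle_group for t in self.trials}
        for g in ("extension", "flexion"):
            if g not in groups:
                raise ValidationError("trials", f"no {g} trial present")
        for t in self.trials:
            t.validate()

    def for_muscle(self, muscle: str) -> list[MvcTrial]:
        group = "extension" if muscle in EXTENSORS else "flexion"
        return [t for t in self.trials if t.muscle_group == group]


@dataclass
class TurnMetricsRow:
    """One scalar outcome keyed by (skier-session, run, cycle, leg, signal).

    ``leg`` is "IL"/"OL" for per-turn outcomes and "" for cycle- or run-level
    outcomes (movement amplitude, run time). ``signal`` is a muscle for EMG
    metrics, a joint for kinematic metrics, and "" for run time.
    """

    session_id: str
    discipline: str
    run_index: int
    run_label: str  # "First" | "Last"
    cycle_index: int
    leg: str
    signal: str
    metric: str
    value: float

    def validate(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValidationError("metric", f"unknown metric {self.metric!r}")
        if self.leg not in ("IL", "OL", ""):
            raise ValidationError("leg", f"unknown leg {self.leg!r}")
        if not np.isfinite(self.value):
            raise ValidationError("value", "non-finite value")
        if self.metric == "burst_pct" and not (0.0 <= self.value <= 100.0):
            raise ValidationError("burst_pct", f"{self.value} outside [0, 100]")
        if self.metric in ("rms_pct_mvc", "burst_ms", "turn_time_ms", "amplitude_deg") and self.value < 0:
            raise ValidationError(self.metric, f"{self.value} negative")
        if self.metric == "mpf_hz" and self.value <= 0:
            raise ValidationError("mpf_hz", f"{self.value} non-positive")
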