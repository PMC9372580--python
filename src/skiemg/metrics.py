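"""Per-turn scalar outcomes: EMG amplitude, spectral and burst metrics;
kinematic extrema, amplitudes and velocities; turn and run times.

EMG amplitude (RMS %MVC) is averaged over the retained points of the
normalized cycle grid; the mean power frequency and activation time are
measured on the native time base so Hz and ms values are exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .containers import JOINTS, MUSCLES, ConfigurationError, SessionRecording, TurnMetricsRow
from .preprocess import ARTIFACT_CYCLE_FRACTION, PreprocessedSession, _lowpass
from .segmentation import GRID_N, TurnCycle, edge_phase_mask, time_normalize

log = logging.getLogger(__name__)

# discipline -> low-pass cutoff (Hz) of the burst ("linear envelope") filter
BURST_CUTOFF_HZ = {"DH": 1.0, "SG": 2.0, "GS": 4.0, "SL": 7.0}
BURST_THRESHOLD_FRACTION = 0.20  # of the MVC maximal RMS
MPF_BAND_HZ = (20.0, 500.0)
MPF_MIN_SAMPLES = 128

#: scale factor turning the mean of rectified Gaussian EMG into its RMS
RECTIFIED_TO_RMS = math.sqrt(math.pi / 2.0)


def burst_envelope(emg_bandpassed: np.ndarray, rate_hz: float, discipline: str) -> np.ndarray:
    """Linear envelope for burst detection: rectify, low-pass, RMS-calibrate.

    The low-pass cutoff is discipline-specific (1-7 Hz). Low-passing the
    *rectified* signal is required — a <=7 Hz filter would annihilate raw
    EMG — and the sqrt(pi/2) factor maps the rectified mean back onto RMS
    units so the 20%-of-MVC threshold (defined on RMS) applies unchanged.
    """
    if discipline not in BURST_CUTOFF_HZ:
        raise ConfigurationError(f"unknown discipline {discipline!r}")
    return RECTIFIED_TO_RMS * _lowpass(np.abs(emg_bandpassed), rate_hz, BURST_CUTOFF_HZ[discipline])


def turn_rms_pct(grid_env_pct: np.ndarray, mask: np.ndarray | None = None) -> dict[str, float]:
    """Mean %MVC envelope over retained grid points of each leg half."""
    if mask is None:
        mask = edge_phase_mask(len(grid_env_pct))
    n = len(grid_env_pct)
    half = n // 2
    out = {}
    for leg, sl in (("IL", slice(0, half)), ("OL", slice(half, n))):
        m = mask[sl]
        if not m.any():
            out[leg] = float("nan")
        else:
            out[leg] = float(np.asarray(grid_env_pct)[sl][m].mean())
    return out


def turn_mpf(segment: np.ndarray, rate_hz: float, band_hz: tuple[float, float] = MPF_BAND_HZ) -> float:
    """Mean power frequency: power-weighted spectral mean over the band.

    Computed from a single untapered periodogram of the band-passed raw EMG
    segment. Returns NaN when the in-band power is zero.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) < MPF_MIN_SAMPLES:
        raise ConfigurationError(f"MPF segment too short ({len(segment)} < {MPF_MIN_SAMPLES} samples)")
    f, p = _signal.periodogram(segment, fs=rate_hz, window="boxcar", detrend="constant")
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    total = p[sel].sum()
    if total <= 0:
        return float("nan")
    return float((f[sel] * p[sel]).sum() / total)


def activation_time(
    envelope: np.ndarray,
    rate_hz: float,
    threshold: float,
) -> tuple[float, float]:
    """Total supra-threshold duration of a turn's envelope.

    Returns ``(burst_ms, burst_pct)``: the summed time the linear envelope
    exceeds the threshold (20% of the MVC maximal RMS, in the envelope's
    units), absolute and as a percentage of the turn. Multiple
    supra-threshold intervals are summed; no hysteresis or minimum-duration
    criterion is applied.
    """
    envelope = np.asarray(envelope, dtype=float)
    n = len(envelope)
    if n == 0:
        return 0.0, 0.0
    above = int(np.count_nonzero(envelope > threshold))
    burst_ms = 1000.0 * above / rate_hz
    return burst_ms, 100.0 * above / n


def turn_times_ms(switch_times: np.ndarray) -> np.ndarray:
    """Per-turn durations (ms) from consecutive switch times."""
    return 1000.0 * np.diff(np.asarray(switch_times, dtype=float))


def run_time_s(marker) -> float:
    """Run time from the start/end markers (s)."""
    return float(marker.end_s - marker.start_s)


@dataclass
class KinematicScalars:
    min_angle_deg: float
    max_angle_deg: float
    peak_flex_vel_dps: float  # most negative velocity (0 if none negative)
    peak_ext_vel_dps: float  # most positive velocity (0 if none positive)


def kinematic_scalars(angle_seg: np.ndarray, velocity_seg: np.ndarray) -> KinematicScalars:
    """Angle extrema and peak flexion/extension velocities over one turn."""
    angle_seg = np.asarray(angle_seg, dtype=float)
    velocity_seg = np.asarray(velocity_seg, dtype=float)
    return KinematicScalars(
        min_angle_deg=float(angle_seg.min()),
        max_angle_deg=float(angle_seg.max()),
        peak_flex_vel_dps=float(min(velocity_seg.min(), 0.0)),
        peak_ext_vel_dps=float(max(velocity_seg.max(), 0.0)),
    )


def select_comparison_runs(session: SessionRecording) -> tuple[int, int]:
    """The run pair entering the First/Last comparison.

    Runs 1 and 4 are always compared, falling back to runs 2 and 5 when the
    first or fourth run is incomplete (or absent).
    """
    def ok(idx: int) -> bool:
        m = session.run_marker(idx)
        return m is not None and m.complete

    if ok(1) and ok(4):
        return 1, 4
    if ok(2) and ok(5):
        return 2, 5
    raise ConfigurationError("fewer than 2 eligible runs: need complete runs (1, 4) or (2, 5)")


def _segment(samples: np.ndarray, rate_hz: float, a_s: float, b_s: float) -> np.ndarray:
    i0 = int(math.ceil(a_s * rate_hz - 1e-9))
    i1 = int(math.floor(b_s * rate_hz + 1e-9)) + 1
    return samples[max(i0, 0) : min(i1, len(samples))]


def build_metrics_table(
    prep: PreprocessedSession,
    cycles: list[TurnCycle],
    artifact_cycle_fraction: float = ARTIFACT_CYCLE_FRACTION,
) -> tuple[list[TurnMetricsRow], dict]:
    """Reduce a preprocessed session to the tidy per-turn metrics table.

    One row per (turn, muscle, metric) and per (turn, joint, metric);
    excluded first/last cycles and artifact-contaminated (cycle, muscle)
    pairs are absent. Only the First/Last comparison runs contribute.
    Returns the rows plus an audit summary with per-run retained/dropped
    cycle counts.
    """
    session = prep.session
    disc = session.discipline
    emg_rate = session.channels["VM"].rate_hz
    mot_rate = session.channels["acc_x"].rate_hz
    first, last = select_comparison_runs(session)
    labels = {first: "First", last: "Last"}
    mask = edge_phase_mask(GRID_N)

    burst_envs = {m: burst_envelope(prep.emg_bandpassed[m], emg_rate, disc) for m in MUSCLES}
    thresholds = {
        m: BURST_THRESHOLD_FRACTION * session.mvc_references[m] for m in MUSCLES
    }

    rows: list[TurnMetricsRow] = []
    summary = {"session_id": session.session_id, "runs": {}, "dropped_cycle_muscle": 0}

    for run_index, run_label in labels.items():
        marker = session.run_marker(run_index)
        rows.append(
            TurnMetricsRow(session.session_id, disc, run_index, run_label, -1, "", "", "run_time_s", run_time_s(marker))
        )
        run_cycles = [c for c in cycles if c.run_index == run_index]
        usable = [c for c in run_cycles if not c.excluded]
        summary["runs"][run_index] = {"cycles": len(run_cycles), "retained": len(usable)}
        for cyc in usable:
            base = dict(
                session_id=session.session_id,
                discipline=disc,
                run_index=run_index,
                run_label=run_label,
                cycle_index=cyc.cycle_index,
            )
            leg_bounds = {"IL": cyc.leg_bounds("IL"), "OL": cyc.leg_bounds("OL")}
            for leg, (a, b) in leg_bounds.items():
                rows.append(TurnMetricsRow(**base, leg=leg, signal="", metric="turn_time_ms", value=1000.0 * (b - a)))

            for muscle in MUSCLES:
                art = _segment(prep.artifact_masks[muscle], emg_rate, cyc.start_s, cyc.end_s)
                if art.size and art.mean() > artifact_cycle_fraction:
                    summary["dropped_cycle_muscle"] += 1
                    continue
                grid_env = time_normalize(cyc, prep.emg_env_pct[muscle], emg_rate)
                rms = turn_rms_pct(grid_env, mask)
                for leg, (a, b) in leg_bounds.items():
                    if np.isfinite(rms[leg]):
                        rows.append(TurnMetricsRow(**base, leg=leg, signal=muscle, metric="rms_pct_mvc", value=rms[leg]))
                    ra, rb = cyc.retained_bounds(leg)
                    seg = _segment(prep.emg_bandpassed[muscle], emg_rate, ra, rb)
                    if len(seg) >= MPF_MIN_SAMPLES:
                        mpf = turn_mpf(seg, emg_rate)
                        if np.isfinite(mpf):
                            rows.append(TurnMetricsRow(**base, leg=leg, signal=muscle, metric="mpf_hz", value=mpf))
                    env_seg = _segment(burst_envs[muscle], emg_rate, a, b)
                    burst_ms, burst_pct = activation_time(env_seg, emg_rate, thresholds[muscle])
                    rows.append(TurnMetricsRow(**base, leg=leg, signal=muscle, metric="burst_ms", value=burst_ms))
                    rows.append(TurnMetricsRow(**base, leg=leg, signal=muscle, metric="burst_pct", value=burst_pct))

            for joint in JOINTS:
                angle = prep.angles_filtered[joint]
                vel = prep.angular_velocities[joint]
                cycle_angles = _segment(angle, mot_rate, cyc.start_s, cyc.end_s)
                amplitude = float(cycle_angles.max() - cycle_angles.min())
                rows.append(TurnMetricsRow(**base, leg="", signal=joint, metric="amplitude_deg", value=amplitude))
                for leg, (a, b) in leg_bounds.items():
                    ks = kinematic_scalars(_segment(angle, mot_rate, a, b), _segment(vel, mot_rate, a, b))
                    rows.append(TurnMetricsRow(**base, leg=leg, signal=joint, metric="min_angle_deg", value=ks.min_angle_deg))
                    rows.append(TurnMetricsRow(**base, leg=leg, signal=joint, metric="max_angle_deg", value=ks.max_angle_deg))
                    rows.append(TurnMetricsRow(**base, leg=leg, signal=joint, metric="peak_flex_vel_dps", value=ks.peak_flex_vel_dps))
                    rows.append(TurnMetricsRow(**base, leg=leg, signal=joint, metric="peak_ext_vel_dps", value=ks.peak_ext_vel_dps))

    log.info(
        "metrics table for %s: %d rows, %d (cycle, muscle) pairs dropped for artifacts",
        session.session_id,
        len(rows),
        summary["dropped_cycle_muscle"],
    )
    return rows, summary
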