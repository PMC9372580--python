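"""Signal conditioning: EMG band-pass, artifact rejection, baseline removal,
RMS envelope, MVC normalization; goniometer/accelerometer low-pass and
differentiation.

All filters are Butterworth and applied zero-phase (forward-backward with
``scipy.signal.sosfiltfilt``), so effective attenuation is the squared
single-pass magnitude response; this keeps EMG, acceleration, and angle
channels phase-aligned for segmentation. Discipline-specific low-pass
cutoffs reflect the slower turn rhythm of the speed events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .containers import (
    JOINTS,
    MUSCLES,
    ConfigurationError,
    MvcTrialSet,
    SessionRecording,
)

log = logging.getLogger(__name__)

# EMG conditioning
EMG_BAND_HZ = (20.0, 500.0)
EMG_BAND_ORDER = 2
RMS_EPOCH_MS = 125.0
BASELINE_WINDOW_S = 1.0
ARTIFACT_SD_FACTOR = 6.0
ARTIFACT_CYCLE_FRACTION = 0.05  # drop a cycle when >5% of its EMG samples are flagged

# MVC reference extraction
MVC_RMS_WINDOW_MS = 500.0
MVC_FORCE_RETENTION = 0.90
MVC_PLATEAU_FRACTION = 0.90

# discipline -> 4th-order low-pass cutoff (Hz)
ANGLE_CUTOFF_HZ = {"DH": 0.5, "SG": 1.0, "GS": 2.0, "SL": 2.5}
ACCR_CUTOFF_HZ = {"DH": 0.8, "SG": 1.0, "GS": 2.0, "SL": 3.0}
LOWPASS_ORDER = 4


def _lowpass(x: np.ndarray, rate_hz: float, cutoff_hz: float, order: int = LOWPASS_ORDER) -> np.ndarray:
    if cutoff_hz <= 0 or cutoff_hz >= rate_hz / 2:
        raise ConfigurationError(f"low-pass cutoff {cutoff_hz} Hz outside (0, Nyquist={rate_hz / 2})")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def bandpass_emg(
    raw: np.ndarray,
    rate_hz: float,
    band_hz: tuple[float, float] = EMG_BAND_HZ,
    order: int = EMG_BAND_ORDER,
) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass (20-500 Hz) of raw EMG."""
    lo, hi = band_hz
    if not 0 < lo < hi:
        raise ConfigurationError(f"invalid EMG band {band_hz}")
    if hi >= rate_hz / 2:
        raise ConfigurationError(f"EMG band edge {hi} Hz >= Nyquist {rate_hz / 2} Hz")
    sos = signal.butter(order, band_hz, btype="bandpass", fs=rate_hz, output="sos")
    log.debug("bandpass_emg: order=%d band=%s fs=%g", order, band_hz, rate_hz)
    return signal.sosfiltfilt(sos, np.asarray(raw, dtype=float))


def _sliding_mean_truncated(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; windows truncated at the edges (O(n))."""
    n = len(x)
    c = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    i = np.arange(n)
    lo = np.clip(i - (window - 1) // 2, 0, n)
    hi = np.clip(i + window // 2 + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def rms_envelope(x: np.ndarray, rate_hz: float, epoch_ms: float = RMS_EPOCH_MS) -> np.ndarray:
    """Sliding root-mean-square over a centered epoch, one value per sample.

    Edge samples use a truncated window, so the output has the input length.
    """
    if epoch_ms <= 0:
        raise ConfigurationError(f"RMS epoch {epoch_ms} ms must be positive")
    x = np.asarray(x, dtype=float)
    window = max(1, int(round(rate_hz * epoch_ms / 1000.0)))
    if window >= len(x):
        raise ConfigurationError(f"RMS epoch ({window} samples) not shorter than signal ({len(x)})")
    return np.sqrt(_sliding_mean_truncated(x * x, window))


def remove_baseline(x: np.ndarray, rate_hz: float, window_s: float = BASELINE_WINDOW_S) -> np.ndarray:
    """Subtract a centered 1-s moving average (reflection padding at edges)."""
    x = np.asarray(x, dtype=float)
    window = int(round(rate_hz * window_s)) | 1  # odd, so the window is symmetric
    if len(x) < window:
        raise ConfigurationError(f"signal shorter than baseline window ({window} samples)")
    baseline = ndimage.uniform_filter1d(x, size=window, mode="reflect")
    return x - baseline


@dataclass
class ArtifactReport:
    mask: np.ndarray  # True where flagged
    intervals: list[tuple[int, int]]  # [start, stop) sample index pairs
    mean: float
    sd: float


def artifact_mask(env: np.ndarray, sd_factor: float = ARTIFACT_SD_FACTOR) -> ArtifactReport:
    """Flag envelope samples outside mean +/- sd_factor*SD of the segment.

    Statistics are computed over the segment passed in (per run, by
    convention of the pipeline); a zero-variance envelope yields no flags.
    """
    env = np.asarray(env, dtype=float)
    if env.size == 0:
        raise ConfigurationError("empty envelope")
    m, s = float(env.mean()), float(env.std())
    if s == 0.0:
        mask = np.zeros(env.shape, dtype=bool)
        return ArtifactReport(mask, [], m, s)
    mask = (env > m + sd_factor * s) | (env < m - sd_factor * s)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    intervals = [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]
    return ArtifactReport(mask, intervals, m, s)


@dataclass
class MvcReference:
    reference_rms: float
    retained_trials: list[int]
    peak_forces: list[float]
    per_trial_max_rms: list[float]


def _plateau_interval(force: np.ndarray, fraction: float = MVC_PLATEAU_FRACTION) -> tuple[int, int]:
    """Longest contiguous interval where force >= fraction * trial peak."""
    peak = float(force.max())
    if peak <= 0:
        raise ConfigurationError("trial has no positive force (no detectable plateau)")
    above = force >= fraction * peak
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    spans = list(zip(edges[::2], edges[1::2]))
    a, b = max(spans, key=lambda ab: ab[1] - ab[0])
    return int(a), int(b)


def _max_windowed_rms(x: np.ndarray, rate_hz: float, window_ms: float) -> float:
    w = int(round(rate_hz * window_ms / 1000.0))
    if len(x) < w:
        raise ConfigurationError(f"plateau shorter than the {window_ms:.0f}-ms RMS window")
    c = np.concatenate(([0.0], np.cumsum(x * x, dtype=float)))
    means = (c[w:] - c[:-w]) / w
    return float(np.sqrt(means.max()))


def mvc_reference(
    trials: MvcTrialSet,
    muscles: tuple[str, ...] = MUSCLES,
    window_ms: float = MVC_RMS_WINDOW_MS,
    retention: float = MVC_FORCE_RETENTION,
) -> dict[str, MvcReference]:
    """Per-muscle maximal RMS from MVC trials.

    For each trial the force plateau is located (longest interval at >=90% of
    the trial's peak force) and the maximal ``window_ms`` RMS of the
    band-limited EMG inside it is extracted. Trials whose peak force is
    within ``1 - retention`` of the best trial are averaged into the
    reference; weaker trials are discarded.
    """
    trials.validate()
    refs: dict[str, MvcReference] = {}
    for muscle in muscles:
        group = trials.for_muscle(muscle)
        peaks, maxima = [], []
        for t in group:
            a, b = _plateau_interval(t.force_n)
            t0, t1 = a / t.force_rate_hz, b / t.force_rate_hz
            e0, e1 = int(round(t0 * t.emg_rate_hz)), int(round(t1 * t.emg_rate_hz))
            emg = bandpass_emg(t.emg[muscle], t.emg_rate_hz)
            maxima.append(_max_windowed_rms(emg[e0:e1], t.emg_rate_hz, window_ms))
            peaks.append(float(t.force_n.max()))
        best = max(peaks)
        retained = [i for i, p in enumerate(peaks) if p >= retention * best]
        ref = float(np.mean([maxima[i] for i in retained]))
        log.debug("mvc_reference %s: %d/%d trials retained, ref=%.4g V", muscle, len(retained), len(group), ref)
        refs[muscle] = MvcReference(ref, retained, peaks, maxima)
    return refs


def normalize_to_mvc(env: np.ndarray, reference_rms: float) -> np.ndarray:
    """Express an RMS envelope in %MVC: 100 * env / reference."""
    if reference_rms <= 0:
        raise ConfigurationError(f"MVC reference must be positive, got {reference_rms}")
    return 100.0 * np.asarray(env, dtype=float) / reference_rms


def lowpass_angles(angle: np.ndarray, rate_hz: float, discipline: str) -> np.ndarray:
    """Zero-phase 4th-order low-pass at the discipline's goniometer cutoff."""
    if discipline not in ANGLE_CUTOFF_HZ:
        raise ConfigurationError(f"unknown discipline {discipline!r}")
    return _lowpass(angle, rate_hz, ANGLE_CUTOFF_HZ[discipline])


def lowpass_accr(accr: np.ndarray, rate_hz: float, discipline: str) -> np.ndarray:
    """Zero-phase 4th-order low-pass at the discipline's AccR cutoff."""
    if discipline not in ACCR_CUTOFF_HZ:
        raise ConfigurationError(f"unknown discipline {discipline!r}")
    return _lowpass(accr, rate_hz, ACCR_CUTOFF_HZ[discipline])


def angular_velocity(angle_deg: np.ndarray, rate_hz: float) -> np.ndarray:
    """Central-difference joint angular velocity in deg/s.

    Negative during flexion (angle decreasing toward 0°), positive during
    extension (angle increasing toward 180°).
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    if len(angle_deg) < 3:
        raise ConfigurationError("need at least 3 samples to differentiate")
    return np.gradient(angle_deg, 1.0 / rate_hz)


# ---------------------------------------------------------------------------
# session-level convenience used by the pipeline


@dataclass
class PreprocessedSession:
    """All conditioned signals of one session, on their native time bases."""

    session: SessionRecording
    emg_bandpassed: dict[str, np.ndarray]  # per muscle, 1926 Hz, baseline-free
    emg_env_pct: dict[str, np.ndarray]  # 125-ms RMS envelope in %MVC
    artifact_masks: dict[str, np.ndarray]  # per muscle, True where flagged
    angles_filtered: dict[str, np.ndarray]  # per joint, 148 Hz
    angular_velocities: dict[str, np.ndarray]  # per joint, deg/s
    accr_filtered: np.ndarray  # 148 Hz
    mvc_references: dict[str, float] = field(default_factory=dict)


def preprocess_session(session: SessionRecording) -> PreprocessedSession:
    """Run the full conditioning chain on every channel of a session.

    Artifact statistics (mean, SD of the RMS envelope) are computed per run
    segment rather than per session, to respect run-level nonstationarity.
    """
    session.validate()
    if not session.mvc_references:
        raise ConfigurationError("session has no MVC references; run mvc_reference first")
    disc = session.discipline
    emg_bp: dict[str, np.ndarray] = {}
    env_pct: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for muscle in MUSCLES:
        ch = session.channels[muscle]
        x = bandpass_emg(ch.samples, ch.rate_hz)
        x = remove_baseline(x, ch.rate_hz)
        emg_bp[muscle] = x
        env = rms_envelope(x, ch.rate_hz)
        env_pct[muscle] = normalize_to_mvc(env, session.mvc_references[muscle])
        mask = np.zeros(len(env), dtype=bool)
        for m in session.run_markers:
            a = int(round(m.start_s * ch.rate_hz))
            b = int(round(m.end_s * ch.rate_hz))
            rep = artifact_mask(env[a:b])
            mask[a:b] = rep.mask
        masks[muscle] = mask

    angles_f: dict[str, np.ndarray] = {}
    velocities: dict[str, np.ndarray] = {}
    for joint in JOINTS:
        ch = session.channels[f"{joint}_angle"]
        af = lowpass_angles(ch.samples, ch.rate_hz, disc)
        angles_f[joint] = af
        velocities[joint] = angular_velocity(af, ch.rate_hz)

    from .segmentation import compute_accr  # local import to avoid a cycle

    acc = [session.channels[f"acc_{ax}"] for ax in "xyz"]
    accr = compute_accr(acc[0].samples, acc[1].samples, acc[2].samples)
    accr_f = lowpass_accr(accr, acc[0].rate_hz, disc)
    log.info("preprocessed session %s (%s): %d muscles, %d runs", session.session_id, disc, len(MUSCLES), len(session.run_markers))
    return PreprocessedSession(
        session=session,
        emg_bandpassed=emg_bp,
        emg_env_pct=env_pct,
        artifact_masks=masks,
        angles_filtered=angles_f,
        angular_velocities=velocities,
        accr_filtered=accr_f,
        mvc_references=dict(session.mvc_references),
    )
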