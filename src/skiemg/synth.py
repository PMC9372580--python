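"""Seeded synthetic skier-sessions with known ground truth.

The generator emulates the statistical and temporal structure the analysis
assumes, not ski-snow mechanics: each run is a sequence of alternating
right/left turns; the trunk-acceleration resultant dips at every turn switch
(unweighting) and peaks mid-turn under load; each muscle's EMG is a
band-limited stochastic carrier (so the mean power frequency is a known
spectral centroid) amplitude-modulated by a raised-cosine burst per turn;
knee/hip angles oscillate at the turn frequency between configured extrema
(180° = full extension). Per-turn EMG drives carry a skier-session random
offset, optional additive run and leg effects, and per-turn jitter — the
variance components the mixed-model layer is asked to recover.

All randomness flows from one ``numpy.random.Generator`` seeded from the
config; identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import signal as _signal

from .containers import (
    Channel,
    ConfigurationError,
    EMG_RATE_HZ,
    JOINTS,
    MOTION_RATE_HZ,
    MUSCLES,
    MvcTrial,
    MvcTrialSet,
    RunMarker,
    SessionRecording,
)

# Discipline-typical defaults: turn durations from observed per-leg turn
# times (SL ~0.8 s, GS ~1.47 s, Speed ~2.1-2.4 s), turns/run inside the
# plausible per-discipline ranges, run counts matching training practice.
TURN_DURATION_S = {"SL": 0.80, "GS": 1.47, "SG": 2.0, "DH": 2.4}
TURNS_PER_RUN = {"SL": 45, "GS": 30, "SG": 25, "DH": 20}
TURNS_PER_RUN_RANGE = {"SL": (40, 60), "GS": (25, 50), "SG": (15, 40), "DH": (15, 35)}
N_RUNS = {"SL": 6, "GS": 5, "SG": 5, "DH": 5}

#: inside-leg burst peak per muscle (%MVC); the outside leg adds leg_effect
DEFAULT_IL_AMPLITUDE = {"VM": 38.0, "RF": 42.0, "VL": 38.0, "BF": 22.0, "SMST": 16.0}
#: OL - IL offset per muscle (%MVC); RF loads the inside leg harder
DEFAULT_LEG_EFFECT = {"VM": 10.0, "RF": -8.0, "VL": 10.0, "BF": 5.0, "SMST": 4.0}
DEFAULT_MPF_HZ = {"VM": 85.0, "RF": 90.0, "VL": 95.0, "BF": 80.0, "SMST": 75.0}
DEFAULT_MVC_RMS_V = {"VM": 0.20, "RF": 0.18, "VL": 0.22, "BF": 0.15, "SMST": 0.12}

ACCR_SWITCH_G = 0.7  # unweighted resultant at the switch
ACCR_PEAK_G = 1.8  # mid-turn load
ACCR_IDLE_G = 1.0  # standing between runs
LATERAL_AMP_G = 0.25


def _per_muscle(value: Any, default: dict[str, float]) -> dict[str, float]:
    if value is None:
        return dict(default)
    if isinstance(value, (int, float)):
        return {m: float(value) for m in MUSCLES}
    out = dict(default)
    out.update({k: float(v) for k, v in value.items()})
    return out


@dataclass
class SynthConfig:
    """Generator parameters; defaults describe a typical GS training session."""

    discipline: str = "GS"
    n_runs: int | None = None
    turns_per_run: int | None = None
    mean_turn_duration_s: float | None = None
    turn_duration_cv: float = 0.05
    amplitude_pct_mvc: dict[str, float] | None = None  # inside-leg burst peak
    leg_effect_pct_mvc: dict[str, float] | float | None = None  # OL - IL
    run_effect_pct_mvc: dict[str, Any] | None = None  # muscle -> shift (or {"IL":..,"OL":..})
    run_effect_onset: int = 4  # runs >= this index receive the shift
    between_session_sd_pct_mvc: float = 6.0
    turn_jitter_sd_pct_mvc: float = 4.0
    burst_duty_cycle: float = 0.6
    tonic_pct_mvc: float = 3.0
    emg_noise_pct_mvc: float = 1.0
    mpf_center_hz: dict[str, float] | None = None
    mpf_bandwidth_hz: float = 50.0
    vibration_noise_sd: float = 0.05  # g
    artifact_rate: float = 0.0  # expected artifacts per muscle per run
    angle_max_deg: dict[str, float] = field(default_factory=lambda: {"knee": 140.0, "hip": 130.0})
    angle_rom_deg: dict[str, float] = field(default_factory=lambda: {"knee": 30.0, "hip": 25.0})
    angle_noise_deg: float = 0.3
    mvc_ref_rms_v: dict[str, float] | None = None
    mvc_trial_forces: tuple[float, ...] = (1.0, 0.96, 0.92)
    inter_run_gap_s: float = 5.0
    incomplete_runs: tuple[int, ...] = ()
    emg_rate_hz: float = EMG_RATE_HZ
    motion_rate_hz: float = MOTION_RATE_HZ
    seed: int = 0
    session_id: str = "synthetic-01"

    def __post_init__(self) -> None:
        if self.discipline not in TURN_DURATION_S:
            raise ConfigurationError(f"unknown discipline {self.discipline!r}")
        if self.n_runs is None:
            self.n_runs = N_RUNS[self.discipline]
        if self.turns_per_run is None:
            self.turns_per_run = TURNS_PER_RUN[self.discipline]
        if self.mean_turn_duration_s is None:
            self.mean_turn_duration_s = TURN_DURATION_S[self.discipline]
        self.amplitude_pct_mvc = _per_muscle(self.amplitude_pct_mvc, DEFAULT_IL_AMPLITUDE)
        if isinstance(self.leg_effect_pct_mvc, (int, float)):
            self.leg_effect_pct_mvc = {m: float(self.leg_effect_pct_mvc) for m in MUSCLES}
        else:
            self.leg_effect_pct_mvc = _per_muscle(self.leg_effect_pct_mvc, DEFAULT_LEG_EFFECT)
        self.mpf_center_hz = _per_muscle(self.mpf_center_hz, DEFAULT_MPF_HZ)
        self.mvc_ref_rms_v = _per_muscle(self.mvc_ref_rms_v, DEFAULT_MVC_RMS_V)
        self.run_effect_pct_mvc = self.run_effect_pct_mvc or {}
        self.validate()

    def validate(self) -> None:
        if self.n_runs < 2:
            raise ConfigurationError("n_runs must be >= 2")
        if self.mean_turn_duration_s <= 0:
            raise ConfigurationError("mean_turn_duration_s must be positive")
        lo, hi = TURNS_PER_RUN_RANGE[self.discipline]
        if not lo <= self.turns_per_run <= hi:
            raise ConfigurationError(
                f"turns_per_run {self.turns_per_run} outside plausible {self.discipline} range [{lo}, {hi}]"
            )
        if self.turns_per_run <= 0:
            raise ConfigurationError("empty runs are not allowed")
        if not 0 < self.burst_duty_cycle <= 1:
            raise ConfigurationError("burst_duty_cycle must lie in (0, 1]")
        for m, a in self.amplitude_pct_mvc.items():
            if a < 0:
                raise ConfigurationError(f"amplitude for {m} must be >= 0")
        for m, c in self.mpf_center_hz.items():
            if not 20.0 < c < 500.0:
                raise ConfigurationError(f"mpf_center_hz[{m}]={c} outside the 20-500 Hz analysis band")
        if self.vibration_noise_sd < 0 or self.artifact_rate < 0:
            raise ConfigurationError("noise and artifact rates must be >= 0")

    def run_effect_for(self, muscle: str, leg: str) -> float:
        eff = self.run_effect_pct_mvc.get(muscle, 0.0)
        if isinstance(eff, dict):
            return float(eff.get(leg, 0.0))
        return float(eff)


@dataclass
class GroundTruth:
    """Latent per-turn truth used for recovery tests."""

    session_id: str
    discipline: str
    switch_times_s: list[list[float]]  # per run
    turn_sides: list[list[str]]  # per run, "right"/"left"
    turn_legs: list[list[str]]  # per run, "IL"/"OL"
    expected_drive_pct: dict[str, list[list[float]]]  # muscle -> per run -> per turn (no jitter)
    realized_drive_pct: dict[str, list[list[float]]]  # with per-turn jitter
    retained_mean_drive_pct: dict[str, list[list[float]]]  # mean envelope over retained phase
    burst_windows_s: dict[str, list[list[tuple[float, float]]]]  # envelope > 20 %MVC
    artifact_times_s: dict[str, list[list[float]]]  # muscle -> per run -> centers
    session_offset_pct: float
    between_session_var: float
    residual_var: float
    run_effects: dict[str, Any]
    leg_effects: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


def _bandlimited_carrier(n: int, rate_hz: float, center_hz: float, bandwidth_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed around ``center_hz``.

    The band is symmetric about the center, so the carrier's spectral
    centroid — hence the measured mean power frequency — sits at the center.
    """
    lo = max(center_hz - bandwidth_hz / 2.0, 1.0)
    hi = min(center_hz + bandwidth_hz / 2.0, rate_hz / 2.0 - 1.0)
    sos = _signal.butter(4, (lo, hi), btype="bandpass", fs=rate_hz, output="sos")
    x = _signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _raised_cosine_envelope(t: np.ndarray, start: float, duration: float, duty: float, peak: float, tonic: float) -> np.ndarray:
    """Per-turn %MVC envelope: tonic floor plus a raised-cosine burst.

    The burst occupies the central ``duty`` fraction of the turn and peaks at
    ``peak`` mid-turn, mirroring the loading phase of a carved turn.
    """
    phi = (t - start) / duration
    b0, b1 = (1.0 - duty) / 2.0, (1.0 + duty) / 2.0
    env = np.full(t.shape, tonic)
    inside = (phi >= b0) & (phi <= b1)
    u = (phi[inside] - b0) / duty
    env[inside] = tonic + (peak - tonic) * 0.5 * (1.0 - np.cos(2.0 * math.pi * u))
    return env


def generate_session(config: SynthConfig, rng: np.random.Generator | None = None) -> tuple[SessionRecording, GroundTruth]:
    """Generate one synthetic skier-session and its latent ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gap = config.inter_run_gap_s
    mean_dur = config.mean_turn_duration_s

    # --- timeline: per-run switch times -----------------------------------
    switch_times: list[np.ndarray] = []
    run_markers: list[RunMarker] = []
    cursor = gap
    for r in range(1, config.n_runs + 1):
        durations = mean_dur * (1.0 + config.turn_duration_cv * rng.standard_normal(config.turns_per_run))
        durations = np.clip(durations, 0.3 * mean_dur, None)
        s = cursor + np.concatenate(([0.0], np.cumsum(durations)))
        switch_times.append(s)
        run_markers.append(RunMarker(r, float(s[0]), float(s[-1]), complete=r not in config.incomplete_runs))
        cursor = float(s[-1]) + gap
    total_s = cursor

    n_mot = int(round(total_s * config.motion_rate_hz)) + 1
    n_emg = int(round(total_s * config.emg_rate_hz)) + 1
    t_mot = np.arange(n_mot) / config.motion_rate_hz
    t_emg = np.arange(n_emg) / config.emg_rate_hz

    # --- acceleration and angles ------------------------------------------
    accr = np.full(n_mot, ACCR_IDLE_G)
    lateral = np.zeros(n_mot)
    angles = {j: np.full(n_mot, config.angle_max_deg[j]) for j in JOINTS}
    turn_sides: list[list[str]] = []
    turn_legs: list[list[str]] = []
    for s in switch_times:
        sides, legs = [], []
        for i in range(len(s) - 1):
            side = "right" if i % 2 == 0 else "left"
            sides.append(side)
            legs.append("IL" if side == "right" else "OL")
            a, b = s[i], s[i + 1]
            sel = (t_mot >= a) & (t_mot < b)
            phi = (t_mot[sel] - a) / (b - a)
            bump = 0.5 * (1.0 - np.cos(2.0 * math.pi * phi))
            accr[sel] = ACCR_SWITCH_G + (ACCR_PEAK_G - ACCR_SWITCH_G) * bump
            lateral[sel] = LATERAL_AMP_G * np.sin(math.pi * phi) * (1.0 if side == "right" else -1.0)
            for j in JOINTS:
                angles[j][sel] = config.angle_max_deg[j] - config.angle_rom_deg[j] * bump
        turn_sides.append(sides)
        turn_legs.append(legs)
        # push-off / run-out tapers so the boundary switches stay genuine
        # local minima of AccR after low-pass filtering
        taper = 0.5 * min(1.0, gap)
        pre = (t_mot >= s[0] - taper) & (t_mot < s[0])
        accr[pre] = ACCR_IDLE_G + (ACCR_SWITCH_G - ACCR_IDLE_G) * (t_mot[pre] - (s[0] - taper)) / taper
        post = (t_mot >= s[-1]) & (t_mot < s[-1] + taper)
        accr[post] = ACCR_SWITCH_G + (ACCR_IDLE_G - ACCR_SWITCH_G) * (t_mot[post] - s[-1]) / taper

    acc_x = lateral + config.vibration_noise_sd * rng.standard_normal(n_mot)
    acc_y = config.vibration_noise_sd * rng.standard_normal(n_mot)
    acc_z = np.sqrt(np.maximum(accr**2 - lateral**2, 0.0)) + config.vibration_noise_sd * rng.standard_normal(n_mot)
    for j in JOINTS:
        angles[j] = np.clip(angles[j] + config.angle_noise_deg * rng.standard_normal(n_mot), 1e-3, 180.0)

    # --- per-turn EMG drives ----------------------------------------------
    session_offset = config.between_session_sd_pct_mvc * rng.standard_normal()
    expected: dict[str, list[list[float]]] = {m: [] for m in MUSCLES}
    realized: dict[str, list[list[float]]] = {m: [] for m in MUSCLES}
    retained_mean: dict[str, list[list[float]]] = {m: [] for m in MUSCLES}
    burst_windows: dict[str, list[list[tuple[float, float]]]] = {m: [] for m in MUSCLES}
    env_pct = {m: np.full(n_emg, 0.0) for m in MUSCLES}
    duty = config.burst_duty_cycle
    for m in MUSCLES:
        for r, s in enumerate(switch_times):
            run_index = r + 1
            exp_run, real_run, ret_run, bw_run = [], [], [], []
            for i in range(len(s) - 1):
                leg = turn_legs[r][i]
                drive = config.amplitude_pct_mvc[m] + session_offset
                if leg == "OL":
                    drive += config.leg_effect_pct_mvc[m]
                if run_index >= config.run_effect_onset:
                    drive += config.run_effect_for(m, leg)
                exp_run.append(drive)
                peak = drive + config.turn_jitter_sd_pct_mvc * rng.standard_normal()
                peak = max(peak, 0.0)
                real_run.append(peak)
                a, b = s[i], s[i + 1]
                sel = (t_emg >= a) & (t_emg < b)
                env = _raised_cosine_envelope(t_emg[sel], a, b - a, duty, peak, config.tonic_pct_mvc)
                env_pct[m][sel] = env
                # truth restricted to the retained (non-edge) phase of this
                # turn: cycle phases 10-40% / 60-90% map to turn phases 20-80%
                phi = (t_emg[sel] - a) / (b - a)
                keep = (phi >= 0.20) & (phi < 0.80)
                ret_run.append(float(env[keep].mean()) if keep.any() else float("nan"))
                above = env > 20.0
                if above.any():
                    tt = t_emg[sel][above]
                    bw_run.append((float(tt[0]), float(tt[-1])))
                else:
                    bw_run.append((float(a), float(a)))
            expected[m].append(exp_run)
            realized[m].append(real_run)
            retained_mean[m].append(ret_run)
            burst_windows[m].append(bw_run)

    # --- raw EMG volts ------------------------------------------------------
    channels: dict[str, Channel] = {}
    artifact_times: dict[str, list[list[float]]] = {m: [] for m in MUSCLES}
    for m in MUSCLES:
        carrier = _bandlimited_carrier(n_emg, config.emg_rate_hz, config.mpf_center_hz[m], config.mpf_bandwidth_hz, rng)
        ref_v = config.mvc_ref_rms_v[m]
        raw = (env_pct[m] / 100.0) * ref_v * carrier
        if config.emg_noise_pct_mvc > 0:
            raw = raw + (config.emg_noise_pct_mvc / 100.0) * ref_v * rng.standard_normal(n_emg)
        # artifacts: short high-amplitude transients; the 125-ms RMS smear must
        # clear mean + 6 SD of the run envelope, so scale well past the bursts
        amp_v = 40.0 * (max(config.amplitude_pct_mvc.values()) + config.between_session_sd_pct_mvc) / 100.0 * ref_v
        for marker in run_markers:
            centers = []
            n_art = rng.poisson(config.artifact_rate)
            for _ in range(n_art):
                c = rng.uniform(marker.start_s + 0.2, marker.end_s - 0.2)
                i0 = int(round((c - 0.015) * config.emg_rate_hz))
                i1 = int(round((c + 0.015) * config.emg_rate_hz))
                tt = np.arange(i1 - i0) / config.emg_rate_hz
                raw[i0:i1] += amp_v * math.sqrt(2.0) * np.sin(2.0 * math.pi * 300.0 * tt)
                centers.append(float(c))
            artifact_times[m].append(centers)
        channels[m] = Channel(config.emg_rate_hz, raw, units="V")

    channels["acc_x"] = Channel(config.motion_rate_hz, acc_x, units="g")
    channels["acc_y"] = Channel(config.motion_rate_hz, acc_y, units="g")
    channels["acc_z"] = Channel(config.motion_rate_hz, acc_z, units="g")
    channels["knee_angle"] = Channel(config.motion_rate_hz, angles["knee"], units="deg")
    channels["hip_angle"] = Channel(config.motion_rate_hz, angles["hip"], units="deg")

    rec = SessionRecording(
        session_id=config.session_id,
        discipline=config.discipline,
        channels=channels,
        run_markers=run_markers,
        mvc_references={},
    )
    truth = GroundTruth(
        session_id=config.session_id,
        discipline=config.discipline,
        switch_times_s=[list(map(float, s)) for s in switch_times],
        turn_sides=turn_sides,
        turn_legs=turn_legs,
        expected_drive_pct=expected,
        realized_drive_pct=realized,
        retained_mean_drive_pct=retained_mean,
        burst_windows_s=burst_windows,
        artifact_times_s=artifact_times,
        session_offset_pct=float(session_offset),
        between_session_var=config.between_session_sd_pct_mvc**2,
        residual_var=config.turn_jitter_sd_pct_mvc**2,
        run_effects=dict(config.run_effect_pct_mvc),
        leg_effects=dict(config.leg_effect_pct_mvc),
    )
    return rec, truth


def generate_mvc_trials(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    noise: float = 0.03,
    n_trials: int = 3,
) -> MvcTrialSet:
    """Synthetic MVC trials: a force plateau plus synchronized EMG.

    Each trial ramps to its peak force, holds a 2-s plateau, and releases.
    During the plateau every muscle of the group carries EMG whose RMS equals
    its configured maximal RMS (times multiplicative noise when
    ``noise > 0``), so the reference-extraction chain closes the loop on the
    configured value. Trial peak forces vary (``mvc_trial_forces``) so the
    10%-of-max retention rule is exercised.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fr, er = config.motion_rate_hz, config.emg_rate_hz
    ramp_s, plateau_s = 1.0, 2.0
    total_s = 2 * ramp_s + plateau_s
    n_f = int(round(total_s * fr)) + 1
    n_e = int(round(total_s * er)) + 1
    t_f = np.arange(n_f) / fr
    t_e = np.arange(n_e) / er
    force_shape = np.interp(t_f, [0, ramp_s, ramp_s + plateau_s, total_s], [0, 1, 1, 0])
    plateau_e = (t_e >= ramp_s) & (t_e <= ramp_s + plateau_s)

    trials: list[MvcTrial] = []
    for group, max_force in (("extension", 1000.0), ("flexion", 400.0)):
        muscles = [m for m in MUSCLES if (m in ("VM", "RF", "VL")) == (group == "extension")]
        forces = list(config.mvc_trial_forces)
        while len(forces) < n_trials:
            forces.append(forces[-1])
        for frac in forces[:n_trials]:
            force = max_force * frac * force_shape
            emg: dict[str, np.ndarray] = {}
            for m in MUSCLES:
                ref_v = config.mvc_ref_rms_v[m]
                if m in muscles:
                    # unit-RMS tone carrier keeps the 500-ms windowed RMS stable,
                    # so the configured maximum is recovered to the trial noise
                    amp = ref_v * (1.0 + noise * rng.standard_normal()) if noise > 0 else ref_v
                    carrier = math.sqrt(2.0) * np.sin(2.0 * math.pi * config.mpf_center_hz[m] * t_e)
                    x = np.zeros(n_e)
                    x[plateau_e] = amp * carrier[plateau_e]
                    if noise > 0:
                        x = x + 0.05 * ref_v * rng.standard_normal(n_e)
                else:
                    x = 0.02 * ref_v * rng.standard_normal(n_e) if noise > 0 else np.zeros(n_e)
                emg[m] = x
            trials.append(MvcTrial(group, force, fr, emg, er))
    return MvcTrialSet(trials)


def simulate_turn_table(
    n_sessions: int,
    turns_per_run: int,
    sigma_id: float,
    sigma_e: float,
    rng: np.random.Generator,
    mean: float = 30.0,
    run_effect: float = 0.0,
    leg_effect: float = 0.0,
    interaction: float = 0.0,
    family: str = "normal",
    gamma_shape: float = 50.0,
):
    """Directly simulate a tidy per-turn table under the random-intercept model.

    This bypasses the signal chain: it draws per-turn responses for a
    First/Last x IL/OL design with a skier-session random intercept, and is
    the workhorse of the statistical recovery, type-I and coverage checks.
    For "lognormal" and "gamma" the linear predictor acts on the log scale
    and ``sigma_id``/``sigma_e`` are latent-scale standard deviations
    (``sigma_e`` is ignored for gamma; dispersion comes from ``gamma_shape``).
    """
    import pandas as pd

    rows = []
    for s in range(n_sessions):
        b = sigma_id * rng.standard_normal()
        for run in ("First", "Last"):
            for i in range(turns_per_run):
                leg = "IL" if i % 2 == 0 else "OL"
                eta = (
                    mean
                    + b
                    + (run_effect if run == "Last" else 0.0)
                    + (leg_effect if leg == "OL" else 0.0)
                    + (interaction if (run == "Last" and leg == "OL") else 0.0)
                )
                if family == "normal":
                    value = eta + sigma_e * rng.standard_normal()
                elif family == "lognormal":
                    value = math.exp(eta + sigma_e * rng.standard_normal())
                elif family == "gamma":
                    mu = math.exp(eta)
                    value = rng.gamma(gamma_shape, mu / gamma_shape)
                else:
                    raise ConfigurationError(f"unknown family {family!r}")
                rows.append({"session_id": f"S{s:03d}", "run": run, "leg": leg, "value": value})
    return pd.DataFrame(rows)
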