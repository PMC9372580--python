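"""End-to-end orchestration: simulate -> preprocess -> segment -> metrics -> models.

``run_pipeline`` drives any number of synthetic skier-sessions (or one
session read from disk) through the full chain and writes a reproducible
bundle: the tidy metrics CSV, a cycle-interval audit file, one model report
per (metric, signal) with the full effect-size summary, and a provenance
JSON (config, seed, stage parameters, retained/dropped cycle counts).
Identical config + seed reproduce the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .containers import ConfigurationError, MUSCLES, JOINTS, SessionRecording
from .metrics import build_metrics_table
from .mixedfx import ModelSpec, classify_terms, cv_decomposition, fit_model
from .preprocess import mvc_reference, preprocess_session
from .segmentation import build_cycles, detect_turn_switches, infer_first_turn, write_cycle_intervals
from .synth import SynthConfig, generate_mvc_trials, generate_session

log = logging.getLogger(__name__)

#: responses modelled per signal kind; cycle/run-level responses drop the leg factor
EMG_RESPONSES = ("rms_pct_mvc", "mpf_hz", "burst_ms", "burst_pct")
JOINT_RESPONSES = ("min_angle_deg", "max_angle_deg", "peak_flex_vel_dps", "peak_ext_vel_dps")
RUN_ONLY_RESPONSES = ("amplitude_deg", "run_time_s", "turn_time_ms")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    n_sessions: int = 1
    synth: SynthConfig | None = None
    input_session: str | None = None
    family: str = "auto"
    first_turn: str = "auto"
    alpha: float = 0.05
    write_sessions: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.input_session is None):
            raise ConfigurationError("provide exactly one of a synth config or an input session path")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        synth = raw.pop("synth", None)
        raw.update(overrides)
        if synth is not None:
            synth = SynthConfig(**synth)
        return cls(synth=synth, **raw)


def _config_digest(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))

    d = dataclasses.asdict(cfg)
    d.pop("outdir", None)  # where the bundle lands does not affect its content
    d.pop("log_level", None)
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_session(
    session: SessionRecording,
    first_turn: str = "auto",
) -> tuple[list, list, dict]:
    """Preprocess, segment and reduce one session to metric rows.

    ``first_turn="auto"`` infers each run's opening turn side from the sign
    of the low-passed lateral trunk acceleration; "right"/"left" force it.
    """
    prep = preprocess_session(session)
    mot_rate = session.channels["acc_x"].rate_hz
    lateral_f = None
    if first_turn == "auto":
        from .preprocess import lowpass_accr

        lateral_f = lowpass_accr(session.channels["acc_x"].samples, mot_rate, session.discipline)
    switches = []
    per_run_side: dict[int, str] = {}
    for marker in session.run_markers:
        pad = 2.0
        a = max(0.0, marker.start_s - pad)
        i0 = int(round(a * mot_rate))
        i1 = int(round((marker.end_s + pad) * mot_rate))
        seg = prep.accr_filtered[i0:i1]
        s = detect_turn_switches(seg, mot_rate, session.discipline, t0_s=i0 / mot_rate)
        s = s[(s >= marker.start_s - 0.25) & (s <= marker.end_s + 0.25)]
        switches.extend(s)
        if lateral_f is not None and len(s) >= 2:
            per_run_side[marker.run_index] = infer_first_turn(lateral_f, mot_rate, (s[0], s[1]))
    switches = np.array(sorted(switches))
    base_side = "right" if first_turn == "auto" else first_turn
    cycles = build_cycles(switches, session.run_markers, first_turn=base_side, first_turn_per_run=per_run_side or None)
    rows, summary = build_metrics_table(prep, cycles)
    return rows, cycles, summary


def analyze_metrics(table: pd.DataFrame, family: str = "auto", alpha: float = 0.05) -> list[dict]:
    """Fit one model per (metric, signal) and assemble report rows."""
    if len(table) == 0:
        raise ConfigurationError("no data: metrics table is empty")
    reports: list[dict] = []
    combos: list[tuple[str, str, str]] = []
    for metric in EMG_RESPONSES:
        combos += [(metric, m, "run*leg") for m in MUSCLES]
    for metric in JOINT_RESPONSES:
        combos += [(metric, j, "run*leg") for j in JOINTS]
    combos += [("turn_time_ms", "", "run*leg")]
    combos += [("amplitude_deg", j, "run") for j in JOINTS]
    combos += [("run_time_s", "", "run")]
    for metric, sig, fixed in combos:
        sub = table[(table["metric"] == metric) & (table["signal"] == sig)]
        if len(sub) == 0:
            continue
        if sub["session_id"].nunique() < 2:
            log.warning("skipping %s/%s: fewer than 2 sessions", metric, sig)
            continue
        sub = sub.rename(columns={"run_label": "run"})
        spec = ModelSpec(response=metric, fixed=fixed, family=family)
        try:
            fit = fit_model(sub, spec, alpha=alpha)
        except Exception as exc:  # a single failed response should not kill the bundle
            log.warning("model failed for %s/%s: %s", metric, sig, exc)
            continue
        classes = classify_terms(fit, alpha=alpha)
        try:
            cv = cv_decomposition(fit)
        except Exception:  # CVs are undefined for non-positive-mean responses
            from .mixedfx import CvDecomposition

            cv = CvDecomposition(float("nan"), float("nan"), float("nan"))
        report = {
            "metric": metric,
            "signal": sig,
            "family": fit.family,
            "n_obs": fit.n_obs,
            "n_sessions": fit.n_groups,
            "singular": fit.singular,
            "aic": fit.aic,
            "var_random": fit.var_random,
            "var_residual": fit.var_residual,
            "var_fixed": fit.var_fixed,
            "r2m": fit.r2m,
            "r2c": fit.r2c,
            "icc_adj": fit.icc_adj,
            "icc_cond": fit.icc_cond,
            "cv_random_pct": cv.cv_random,
            "cv_intra_pct": cv.cv_intra,
            "cv_syst_pct": cv.cv_syst,
            "p_values": {t: fit.p_values[t] for t in fit.terms[1:]},
            "effect_class": {t: c.label for t, c in classes.items()},
            "icc_cond_per_term": {t: c.icc_cond for t, c in classes.items()},
            "emmeans": fit.emmeans,
            "emmean_diffs_last_minus_first": fit.emmean_diffs,
            "n_tests": len(fit.terms) - 1,
        }
        reports.append(report)
    return reports


def reports_to_frame(reports: list[dict]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for term, p in r["p_values"].items():
            rows.append(
                {
                    "metric": r["metric"],
                    "signal": r["signal"],
                    "family": r["family"],
                    "term": term,
                    "p": p,
                    "icc_adj": r["icc_adj"],
                    "icc_cond_term": r["icc_cond_per_term"][term],
                    "effect_class": r["effect_class"][term],
                    "r2m": r["r2m"],
                    "r2c": r["r2c"],
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full chain and write the report bundle; returns a summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(cfg.seed)
    all_rows: list = []
    all_cycles_paths = []
    session_summaries = []

    if cfg.synth is not None:
        child_seeds = seed_seq.spawn(cfg.n_sessions)
        for i, ss in enumerate(child_seeds):
            rng = np.random.default_rng(ss)
            scfg = dataclasses.replace(cfg.synth, session_id=f"{cfg.synth.session_id}-{i:03d}")
            session, truth = generate_session(scfg, rng)
            trials = generate_mvc_trials(scfg, rng)
            refs = mvc_reference(trials)
            session.mvc_references = {m: r.reference_rms for m, r in refs.items()}
            if cfg.write_sessions:
                sdir = outdir / "sessions" / session.session_id
                sio.write_session(session, sdir)
                sio.write_ground_truth(truth, sdir / sio.TRUTH_NAME)
            rows, cycles, summary = process_session(session, first_turn=cfg.first_turn)
            cyc_path = outdir / "cycles" / f"{session.session_id}.tsv"
            cyc_path.parent.mkdir(parents=True, exist_ok=True)
            write_cycle_intervals(cycles, cyc_path)
            all_cycles_paths.append(str(cyc_path))
            all_rows.extend(rows)
            session_summaries.append(summary)
    else:
        session = sio.read_session(cfg.input_session)
        rows, cycles, summary = process_session(session, first_turn=cfg.first_turn)
        cyc_path = outdir / "cycles" / f"{session.session_id}.tsv"
        cyc_path.parent.mkdir(parents=True, exist_ok=True)
        write_cycle_intervals(cycles, cyc_path)
        all_cycles_paths.append(str(cyc_path))
        all_rows.extend(rows)
        session_summaries.append(summary)

    metrics_path = outdir / "metrics.csv"
    table = sio.rows_to_frame(all_rows)
    sio.write_metrics_table(table, metrics_path)

    reports = []
    if table["session_id"].nunique() >= 2:
        reports = analyze_metrics(table, family=cfg.family, alpha=cfg.alpha)
        (outdir / "reports.json").write_text(json.dumps(reports, indent=1, default=float), encoding="utf-8")
        reports_to_frame(reports).to_csv(outdir / "reports.csv", index=False)
    else:
        log.info("single session: skipping model fitting (needs >= 2 skier-sessions)")

    provenance = {
        "seed": cfg.seed,
        "config_sha256": _config_digest(cfg),
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
        "n_sessions": len(session_summaries),
        "session_summaries": session_summaries,
        "n_metric_rows": int(len(table)),
        "n_reports": len(reports),
        "cycle_files": all_cycles_paths,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str), encoding="utf-8")
    return {"metrics": str(metrics_path), "reports": reports, "table": table, "provenance": provenance}
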