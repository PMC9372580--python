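import numpy as np
import pytest

from skiemg.containers import CHANNEL_SCHEMA, Channel, RunMarker, SessionRecording
from skiemg.pipeline import process_session
from skiemg.preprocess import mvc_reference
from skiemg.synth import SynthConfig, generate_mvc_trials, generate_session


def make_session_with_refs(config: SynthConfig, seed=None):
    """Generate a session with MVC references attached (full closed loop)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    session, truth = generate_session(config, rng)
    refs = mvc_reference(generate_mvc_trials(config, rng))
    session.mvc_references = {m: r.reference_rms for m, r in refs.items()}
    return session, truth


@pytest.fixture(scope="session")
def gs_config():
    return SynthConfig(discipline="GS", n_runs=4, turns_per_run=25, seed=7)


@pytest.fixture(scope="session")
def gs_session_truth(gs_config):
    return make_session_with_refs(gs_config)


@pytest.fixture(scope="session")
def gs_processed(gs_session_truth):
    session, truth = gs_session_truth
    rows, cycles, summary = process_session(session)
    return session, truth, rows, cycles, summary


def tiny_session(n_runs=1, run_len_s=3.0, gap_s=1.0) -> SessionRecording:
    """A minimal schema-valid session for I/O tests (flat signals)."""
    markers = []
    t = gap_s
    for r in range(1, n_runs + 1):
        markers.append(RunMarker(r, t, t + run_len_s, True))
        t += run_len_s + gap_s
    total = t
    channels = {}
    rng = np.random.default_rng(3)
    for name, (rate, units) in CHANNEL_SCHEMA.items():
        n = int(total * rate)
        if name.endswith("_angle"):
            samples = 120.0 + 5.0 * rng.standard_normal(n).clip(-3, 3)
        elif name.startswith("acc"):
            samples = 1.0 + 0.01 * rng.standard_normal(n)
        else:
            samples = 1e-4 * rng.standard_normal(n)
        channels[name] = Channel(rate, samples, units=units)
    return SessionRecording(
        session_id="tiny",
        discipline="GS",
        channels=channels,
        run_markers=markers,
        mvc_references={m: 0.2 for m in ("VM", "RF", "VL", "BF", "SMST")},
    )
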