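# skiemg

On-snow neuromuscular analysis of alpine ski turns: a tested pipeline from
raw multi-channel session recordings (surface EMG, trunk acceleration, joint
angles) to per-turn outcome tables and mixed-model effect sizes, plus a
seeded synthetic-session generator with known ground truth so every stage is
verifiable without athlete data.

## Who this is for

Sport scientists and biomechanists who monitor elite alpine skiers in the
field and want to know whether repeating high-intensity training runs alters
neuromuscular activity — and, just as importantly, whether an apparently
significant change is larger than the skier's own between-session
variability.

A *skier-session* (one athlete, one day, one discipline: SL, GS, SG or DH)
yields five thigh EMG channels at 1,926 Hz (VM, RF, VL, BF, SMST), tri-axial
trunk acceleration and knee/hip goniometer angles at 148 Hz (180° = full
extension), plus isometric MVC trials for normalization. The first and
fourth runs of a session are compared (runs 2 and 5 if either is
incomplete).

## The method

**Signal conditioning.** EMG: zero-phase 2nd-order Butterworth band-pass
20–500 Hz, artifact flagging at the envelope mean ± 6 SD per run, 1-s
moving-average baseline removal, 125-ms sliding RMS, normalization to the
MVC reference (best 500-ms RMS within the force plateau, averaged over
trials within 10% of the maximal force). Angles and the acceleration
resultant AccR = √(x²+y²+z²) are low-passed with 4th-order Butterworth
filters at discipline-specific cutoffs (angles: 0.5/1/2/2.5 Hz, AccR:
0.8/1/2/3 Hz for DH/SG/GS/SL).

**Segmentation.** Turn switches are local minima of the filtered AccR (the
skier unweights between turns). A cycle is a right turn (inside leg, IL,
with right-leg instrumentation) plus a left turn (outside leg, OL),
time-normalized to 200 grid points; edge-change phases (0–10%, 40–60%,
90–100% of the cycle) are masked from EMG averaging, and the first/last
cycles of each run are excluded.

**Per-turn outcomes.** RMS %MVC over retained grid points per leg; mean
power frequency MPF = Σf·P(f)/ΣP(f) over 20–500 Hz; burst duration = time
the linear envelope (rectified EMG low-passed at 1/2/4/7 Hz per discipline)
exceeds 20% of the MVC maximal RMS, in ms and % of turn; turn/run times;
angle extrema, movement amplitude and peak flexion/extension velocities.

**Inference.** Each outcome is fitted with a random-intercept model

    value ~ run + leg + run:leg + (1 | skier-session)

(run only for cycle-level outcomes). Normal, lognormal and gamma (log-link)
families compete on ML AIC. Effect sizes come from the variance components:

    ICC_adj  = σ²_id / (σ²_id + σ²_e)
    ICC_cond = σ²_id / (σ²_id + σ²_e + σ²_f)
    R²m + ICC_cond = R²c

A significant factor is still called **negligible** when ICC_cond ≈ ICC_adj
(its systematic variance moves nothing); otherwise ICC_cond < 0.5 / < 0.75 /
≤ 0.9 / > 0.9 maps to very strong / strong / moderate / small fixed effects.
Reports also include estimated marginal means with Wald 95% CIs, Last−First
differences per leg, and a CV decomposition (between-session, within-session,
systematic).

## Worked example

Simulate eight GS skier-sessions in which only the outside-leg vastus
medialis drive increases by 8 %MVC from the fourth run onward, then run the
full chain:

```python
from skiemg import PipelineConfig, SynthConfig, run_pipeline

cfg = PipelineConfig(
    outdir="demo_out", seed=1, n_sessions=8,
    synth=SynthConfig(discipline="GS", n_runs=4, turns_per_run=25,
                      run_effect_pct_mvc={"VM": {"OL": 8.0}}),
    family="auto",
)
result = run_pipeline(cfg)
vm = next(r for r in result["reports"]
          if r["metric"] == "rms_pct_mvc" and r["signal"] == "VM")
```

The VM RMS report prints:

```
family       : gamma
p(run)       : 0.9824
p(run:leg)   : 0.0
ICC_adj      : 0.553
ICC_cond(run): 0.503
class(run)   : negligible
Last-First IL: +0.0 %MVC [-0.7; 0.7]
Last-First OL: +3.5 %MVC [2.5; 4.4]
```

Read: the skewed RMS distribution selects the gamma family; there is no run
main effect (the inside leg did not change), a strong run × leg interaction
(p < 0.001), and the marginal-mean difference localizes the increase on the
outside leg (+3.5 %MVC on the retained-phase mean, consistent with the +8
%MVC injected burst peak). The bundle in `demo_out/` holds the tidy
`metrics.csv`, per-session cycle-interval audit files, `reports.json/csv`
with every fit, and a `provenance.json` that reproduces the run bit for bit.

The same stages are available as a CLI for single sessions:

```bash
skiemg simulate --discipline GS --seed 1 --out session/
skiemg preprocess --session session/ --out processed/
skiemg segment --session session/ --processed processed/ --out cycles.tsv
skiemg metrics --session session/ --out metrics.csv
skiemg all --config demo.yaml --seed 1 --out bundle/
```

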