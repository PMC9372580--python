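# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `skiemg`, and what the passing test suite does and does
not establish about real on-snow recordings.

## Signal model and conditioning

All filters are Butterworth, applied zero-phase (`sosfiltfilt`). Field
protocols rarely state whether filtering is phase-compensated; we require
it, because turn segmentation aligns EMG to acceleration and a causal
4th-order filter at 2 Hz would lag the AccR minima by tens of milliseconds. The cost is that effective attenuation is the *squared*
single-pass magnitude response; all documented cutoffs refer to the
single-pass design.

* EMG: 2nd-order band-pass 20–500 Hz (valid for sampling rates above
  1 kHz; the 1,926 Hz channels give a 963 Hz Nyquist).
* Baseline: subtraction of a centered 1-s moving average (window forced to
  an odd sample count so a linear trend is removed exactly; reflection
  padding at the edges).
* RMS envelope: sliding 125-ms root-mean-square with a 1-sample hop and a
  centered window, truncated at segment edges. Disjoint 125-ms blocks would
  serve equally for scalar outcomes but cannot be drawn as a continuous
  envelope; the sliding form is strictly more informative and reduces to the
  block value under averaging.
* Artifact rule: envelope samples outside mean ± 6 SD are flagged, with the
  statistics computed **per run segment** — runs differ systematically in
  snow contact and vibration level, so session-level statistics would let a
  quiet run mask artifacts in a loud one. A cycle is dropped for a muscle
  when more than 5% of its EMG samples are flagged (`ARTIFACT_CYCLE_FRACTION`,
  config-overridable); this replaces the visual-inspection step of the field
  protocol with a deterministic rule.
* MVC reference: per trial, the force plateau is the longest interval at
  ≥ 90% of the trial's peak force; the reference extraction takes the
  maximal 500-ms windowed RMS of band-passed EMG inside it. Trials whose
  peak force falls below 90% of the best trial are discarded; the reference
  is the mean over retained trials. A trial without a plateau long enough to
  hold the 500-ms window is an error.
* Angular velocity: central differences of the filtered angle; negative =
  flexion (angle decreasing from 180° full extension).

## Segmentation

A turn switch is a local minimum of the low-passed AccR — the unweighting
between edge changes. (The alternative reading, an inflection of the AccR
derivative, identifies the same instant for the signals at hand: the
derivative's upward zero crossing *is* the minimum.) A minimum-separation
guard of `0.5 / f_cutoff` seconds suppresses noise-induced double minima;
detection runs per run segment with 2 s of context so boundary switches are
interior points of the analyzed window.

Turn polarity (whether a run opens on a right or a left turn) is not
derivable from AccR. By default it is inferred per run from the sign of the
low-passed lateral trunk acceleration over the opening turn (positive =
right turn, for the standard mounting); a config key forces `right`/`left`
for mirrored hardware. Switches within 0.25 s of a run marker count as
belonging to the run, absorbing small detection offsets at the boundaries.

Cycles pair a right (inside-leg) and a left (outside-leg) turn; trailing
unpaired turns are trimmed and the first and last cycles of every run are
flagged excluded (turn entry/exit transients). Each leg half is linearly
interpolated onto 100 grid points (100 per leg keeps cycle percentages
integral); the edge-change mask removes [0,10)%, [40,60)% and [90,100]% of
the cycle — half-open interior boundaries, exactly 120 of 200 points
retained.

## Per-turn outcomes

* **RMS %MVC**: mean of the normalized envelope over retained grid points of
  each leg half.
* **MPF**: power-weighted mean of a single untapered periodogram over
  20–500 Hz, computed on the native-rate band-passed EMG of each leg's
  retained window (not the time-normalized grid, which would distort the
  spectrum). Segments shorter than 128 samples are refused; zero in-band
  power yields a flagged missing value. A taper can be configured but is off
  by default: per-turn segments are long (≥ 0.4 s) and the centroid is
  insensitive to leakage at that length.
* **Burst (activation time)**: the "linear envelope" is the rectified
  band-passed EMG, low-passed at 1/2/4/7 Hz (DH/SG/GS/SL) and multiplied by
  √(π/2). Rectification is necessary — a ≤ 7 Hz filter applied to raw EMG
  would annihilate it — and the √(π/2) factor maps the mean of rectified
  Gaussian noise back onto its RMS, so the 20%-of-MVC threshold (defined in
  RMS units) applies without bias. Durations are counted on the native time
  base (sample count × dt, summed over all supra-threshold intervals; no
  hysteresis or minimum-duration rule).
* **Kinematics**: per-turn angle extrema; movement amplitude per cycle
  (max − min); peak extension velocity = most positive, peak flexion = most
  negative filtered velocity, clipped at zero when a turn has no phase of
  that sign.
* **Run selection**: runs 1 and 4 labelled First/Last, falling back to 2 and
  5 when either is incomplete; anything less is an error.

## Mixed models and effect sizes

Per outcome and signal: `value ~ run + leg + run:leg + (1 | skier-session)`
with treatment coding (First, IL as references); run-only for cycle- and
run-level outcomes. Three families compete on maximum-likelihood AIC:

* **normal** — linear mixed model (statsmodels MixedLM, ML). The reported
  log-likelihood is recomputed in closed form from the fitted components
  (Woodbury identity per group), which also guards against an optimizer
  quirk that occasionally returns a boundary fit; a Powell restart is tried
  whenever the random-intercept variance collapses.
* **lognormal** — the same LMM on log responses; its AIC is corrected by the
  log-transform Jacobian (+2 Σ log y) so all three AICs live on the response
  scale.
* **gamma, log link** — no mixed-model implementation exists in the
  installed stack, so the marginal likelihood is maximized here directly:
  the random intercept is integrated by 25-node Gauss–Hermite quadrature
  (the per-group integrand reduces to three sufficient statistics, so the
  quadrature is exact in cost O(groups × nodes)), warm-started from the
  lognormal fit, with a numeric-Hessian covariance at the optimum. The
  latent-scale residual variance of the gamma family is trigamma(shape).

Families requiring positivity are skipped (with a log message) when any
response is ≤ 0. A random-intercept variance below 1e-8 is reported as
`singular=True`, never raised.

Effect sizes use the variance components: σ²_f is the empirical variance of
the fixed-effect linear predictor over the observed design (latent scale for
the log-link families), giving R²m, R²c, ICC_adj and ICC_cond with the exact
identity R²m + ICC_cond = R²c. p-values are Wald z-tests on coefficients,
α = 0.05, no multiple-testing correction (each report carries the count of
tests performed so users can apply their own).

**Classification of a factor** is two-step: non-significant → negligible;
significant but |ICC_adj − ICC_cond| < τ (τ = 0.01, overridable) →
negligible, because adding that factor's systematic variance to the
denominator moved nothing; otherwise ICC_cond buckets the size (< 0.5 very
strong, < 0.75 strong, ≤ 0.9 moderate, > 0.9 small). For this step ICC_cond
is computed with the *factor's own* predictor variance (its columns,
including interactions containing it); the fit-level ICC_cond keeps the full
fixed variance so the R² identity holds. This per-factor reading is what
makes "significant yet negligible" calls stable: a spurious small effect has
tiny systematic variance no matter how small its p-value.

**Estimated marginal means** are computed on a balanced run(×leg) reference
grid with Wald 95% CIs from the coefficient covariance; log-link families
are back-transformed by exp (so cell values are conditional medians /
geometric-scale means), and Last−First differences on the response scale use
the delta method.

**CV decomposition**: for the normal family, 100·√(σ²)/grand-mean per
component (between-session, within-session, systematic). For log-link
families the random and systematic components map to the response scale via
CV = √(exp(σ²) − 1); the gamma within-session CV is 1/√shape. The exact
published definition of the systematic component is not available; the
√σ²_f form is an interpretation and is labelled as such in reports. CVs are
undefined (NaN in reports) for outcomes with non-positive grand mean, such
as peak flexion velocity.

## Synthetic sessions: what they emulate, what they don't

The generator reproduces the *statistical and temporal* structure the
analysis assumes, not ski mechanics:

* Runs of alternating right/left turns; turn durations normal around the
  discipline mean (SL 0.80 s, GS 1.47 s, SG 2.0 s, DH 2.4 s; CV 5%), turn
  counts per run inside the plausible per-discipline ranges (defaults
  SL 45, GS 30, SG 25, DH 20), run counts SL 6, GS/SG/DH 5.
* AccR dips to 0.7 g at every switch, peaks at 1.8 g mid-turn (raised
  cosine), idles at 1 g between runs with short push-off/run-out tapers so
  boundary switches remain genuine minima; lateral acceleration alternates
  sign with turn side; additive Gaussian vibration noise (default SD
  0.05 g).
* Each muscle's EMG is a unit-RMS band-limited noise carrier centered on its
  configured MPF (symmetric 50-Hz band, so the spectral centroid equals the
  center), amplitude-modulated by a per-turn raised-cosine burst over the
  central 60% of the turn. The per-turn burst peak is
  IL amplitude (+ leg effect on OL) (+ run effect from the configured onset
  run) + a session-level random offset (SD 6 %MVC, matching a
  between-session CV near 17%) + per-turn jitter (SD 4 %MVC) — the variance
  components the model layer recovers. Ground truth stores both the
  expected (jitter-free) and realized drives, the retained-phase envelope
  mean each RMS estimate should match, and the 20 %MVC crossing times.
* Artifacts (off by default) are 30-ms, 300-Hz tone transients at 40× the
  maximal burst amplitude — strong enough that their 125-ms RMS smear clears
  the mean + 6 SD rule despite inflating the run SD themselves.
* MVC trials: trapezoid force to a 2-s plateau with per-trial peak forces
  (1.0, 0.96, 0.92 of maximum by default) exercising the 10% retention rule;
  plateau EMG is a unit-RMS tone at the muscle's MPF center scaled to the
  configured maximal RMS (multiplicative trial noise plus a broadband floor
  in noisy mode), so the extraction chain closes the loop on the configured
  value.

Not emulated: ski–snow interaction forces, terrain and gate geometry, snow
and weather covariates, co-contraction structure, within-run fatigue drift,
and EMG amplitude distributions in raw volts (only %MVC-relative quantities
are meaningful; raw scales are arbitrary). Passing recovery tests therefore
demonstrate that the *pipeline* is unbiased and the effect-size machinery is
calibrated under the assumed structure — they do not validate the
physiological assumptions against real recordings.

## Problem sizes

The statistical checks run at desk scale, chosen once: variance-component
recovery at 25 replicates of 40 sessions × 15 turns/leg/run; type-I error at
200 null replicates of 20 sessions × 10 turns; CI coverage at 50 replicates;
the end-to-end null pipeline at 30 sessions of 4 runs × 25 turns (GS) in the
test suite and 20 sessions in the acceptance script. Published per-turn
tables from real athlete data (marginal-mean differences, p-values) are
specific to those recordings and are not reproduction targets; the
recovery, calibration and stability properties above stand in for them.

## Known limitations

* The gamma GLMM uses one quadrature rule (25 nodes) and Wald inference;
  no profile-likelihood intervals.
* Lognormal and gamma back-transforms report geometric-scale means, not
  arithmetic means; with moderate latent variance the difference is small
  but systematic.
* Burst detection applies no hysteresis; envelopes hovering at the 20%
  threshold can fragment into many short intervals (durations still sum
  correctly).
* The artifact rule shares the known weakness of any mean ± k·SD criterion:
  heavy artifact contamination inflates the SD and can self-mask; the
  per-run statistics bound the damage to one run.
* Polarity inference assumes the standard accelerometer mounting; mirrored
  hardware requires the explicit `first_turn` override.
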