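# Methods

This note documents the models, numerical choices and limitations behind
`dsp_spiro`, in the order the pipeline runs.

## Synthetic data

The synthetic module stands in for human recordings that are not publicly
available. It is calibrated to the published cohort description and to the
qualitative signal properties the detection pipeline exploits; it is not a
physiological simulator.

**Cohort.** Continuous characteristics are drawn from lower-truncated
normals (age ≥ 18 y, BMI ≥ 15 kg/m², volumes/flows ≥ 0.5) whose defaults
are the published cohort moments: age 30.3 ± 6.7 y, BMI 23.9 ± 3.3 kg/m²,
FVC 4.0 ± 1.1 L, FEV1 3.2 ± 0.7 L, PEF 6.9 ± 1.7 L/s, 44.4 % male, and the
published ethnicity frequencies. The truncated distributions are
*moment-matched*: the underlying location/scale are solved (Newton-type
root finding on the truncated-normal moment equations) so the post-
truncation mean/SD equal the configured values — naive truncation at
age ≥ 18 would bias the mean age upward by ≈ 0.5 y, which is ~7 standard
errors at n = 10,000. FEV1 draws are clipped to the same subject's FVC;
because draws are independent this clipping biases the FEV1 mean slightly
low (≈ 0.1 L), which we accept as the price of the hard physiological
constraint.

**Breath timelines.** Cycle boundaries (inspiration onset, expiration
onset, cycle end) are drawn from clipped normals per maneuver. Low-effort
breathing has long gentle expirations (mean 3.5 s); forceful breathing has
short sharp ones (mean 1.2 s). Inspirations average 2.0–2.4 s and
inter-cycle pauses ≈ 0.7–0.8 s (clipped to ≤ 1.0 s so the TSEng minimum in
a pause always falls inside the ±1 s association window of the next
inspiration onset). A *closing inhalation onset* is annotated after the
final expiration: the validity rule needs a subsequent inspiration to
close the last cycle, and a breathing subject always supplies one.

**Tracheal audio** (default 8 kHz; configurable, ≥ 2 kHz required) is
band-limited Gaussian noise (50–1000 Hz, with extra energy mixed into
800–1000 Hz where tracheal coupling is strongest) multiplied by a smooth
airflow envelope: a Hann bump per phase, expiration peaking 1.5× above
inspiration, forceful maneuvers 4× above low-effort, near-zero in pauses,
and a decaying expiration tail before the first inspiration (the subject
was already breathing when recording started; without it the first TSEng
minimum sits on the signal boundary and is undetectable as a peak).
Additive white sensor noise is scaled to `snr_db` relative to the nominal
peak envelope.

**Chest acceleration** (default 100 Hz; ≥ 20 Hz required) is a piecewise-
cosine Z-axis waveform rising from a minimum at each inspiration onset to
a maximum at the expiration onset and descending monotonically to the next
inspiration onset, so the annotated events are its only extrema. Amplitude
defaults to 0.02 g (halved for low-effort), plus slow sinusoidal drift,
white noise set by `snr_db`, optional exponential artifact spikes, and
attenuated copies on X/Y. No amplitude, duration or SNR figures were
reported for the real recordings; all signal-level defaults here are
package choices and remain configurable — passing tests demonstrate that
the pipeline recovers the structure this generator produces, not that it
would perform identically on real patch data (no occlusions, swallowing,
speech, wheeze or posture changes are modeled).

**Feature cohorts.** For modeling-stage tests the cohort generator skips
the signal stages: each subject has a latent 185-vector of feature means
(between-subject SD 1), rows scatter around it (within-subject SD 0.3),
and one spirometric target is `intercept + Σ coef·latent + subject effect
+ N(0, noise_sd)`. The planted outcome is a function of the *latent*
state, so it is constant within subject (matching how a single spirometry
reference serves all of a subject's breaths) and exactly recoverable by
least squares when the noise terms are zeroed.

## Phase detection

Conditioning follows the published recipe: IMU-Z → 2nd-order Butterworth
5 Hz low-pass (zero-phase) → 0.5 s moving median → 0.5 s moving mean →
linear resampling onto a uniform 20 Hz grid; audio → 50–1000 Hz band-pass
(zero-phase) → TSEng = ln(moving variance over 20 ms, centered windows
shrinking at the edges, variance floored at 1e-12 before the log) → 2 Hz
low-pass → 20 Hz grid → the same median/mean smoothing.

Numerical choices:

* **Zero-phase filtering** uses forward-backward filtering with
  Gustafsson initial conditions rather than padded `filtfilt`: padding
  leaves direction-dependent edge transients for the lightly damped 50 Hz
  band edge (measured asymmetry ~0.6 full scale), while the Gustafsson
  solution is symmetric under time reversal to ~1e-13 — a property the
  test suite asserts.
* The 2 Hz TSEng low-pass runs after block-average decimation of the raw
  log-variance to ~200 Hz; its impulse response spans seconds, which is
  intractable to solve exactly at audio rate and irrelevant above the
  final 20 Hz envelope rate. Smoothing is likewise applied on the 20 Hz
  grid. Both reorderings are transparent for a ≤ 2 Hz envelope.
* **Extrema**: candidate peaks must have prominence ≥ 20 % of the
  envelope's interquartile range (computed on the conditioned envelope,
  whole recording); the ≥ 1.5 s spacing rule keeps the higher-prominence
  peak, ties to the earlier one. A constant envelope (IQR = 0) yields no
  extrema, with a logged warning.
* **Association**: IMU minima pair with TSEng minima nearest-first within
  ±1 s, each TSEng minimum used at most once, ties to the earlier IMU
  minimum; unpaired minima are dropped. Expiration events (IMU maxima)
  need no acoustic confirmation by default; `strict_expiration=True`
  requires a TSEng minimum (the expiratory-turnaround dip) within the
  window.
* All intervals are half-open `[start, end)` in seconds from session t=0.

## Feature inventory

The published feature count (185) is reproduced as: 13 MFCCs × 3 orders ×
2 statistics × 2 phases = 156, plus 3 axes × 2 range measures × 2 phases
= 12 acceleration features, plus 17 envelope/timing features (per phase:
duration, TSEng mean/SD/max/trapezoidal area, filtered-audio RMS and
zero-crossing rate; cycle-level: total duration, inspiratory duty
fraction, expiration/inspiration TSEng area ratio). The composition of the
original set beyond the MFCC and IMU-range blocks is unreported; the
17-feature completion is this package's choice of the most conventional
breath descriptors, and the inventory is versioned in
`dsp_spiro.features.FEATURE_NAMES`.

MFCCs use 25 ms Hamming frames with 10 ms hop, power spectra on the next
power-of-two FFT, a 26-filter triangular HTK-mel bank (0 Hz to Nyquist),
ln with a 1e-10 floor, an orthonormal type-II DCT, and coefficients
c0–c12 (`include_c0=False` switches to c1–c13). Deltas are regression
derivatives with half-width K = 2 and replicated edge frames; SDs use the
n−1 denominator (0 for a single frame); quantiles are linear-interpolated.
For modality grouping, the 12 acceleration ranges plus the 4 pure timing
features form the IMU-derived set; the remaining 169 are tracheal-sound
derived.

## Boruta screening

Regression forests (targets are continuous), 500 trees by default with
√p feature subsampling, scored by impurity-decrease importances as in the
algorithm's reference implementations. Each iteration rebuilds one
row-permuted shadow per original feature; a feature hits when its
importance strictly exceeds the best shadow. Hits are tested two-sided
against Binomial(iterations, ½) at α = 0.05 with Bonferroni correction
over *all* input features; significantly-high features are confirmed,
significantly-low ones rejected and removed from competition. Two details
matter for calibration and were chosen after measuring their Type-I
behavior on pure-noise designs: the shadow field keeps its full original
width even as features are rejected, and the Bonferroni denominator stays
at the full feature count — shrinking either lets a feature with a lucky
sample correlation accumulate hits late in the run and be falsely
confirmed. Features still undecided at the iteration budget are tentative
(rejected by default policy). The screen runs once per modality × index on
the full table, before cross-validation, mirroring the study protocol —
including its acknowledged optimistic bias.

## Modeling and evaluation

The elastic net minimizes `(1/2n)Σ(yᵢ−β₀−xᵢβ)² + λ[α‖β‖₁ +
(1−α)/2‖β‖₂²]` (the `(1−α)/2` ridge convention; λ values are
convention-dependent). Predictors are z-scored from training rows only
(constant columns get SD surrogate 1 and a forced-zero coefficient), y is
centered, the intercept is unpenalized, and coefficients are returned
de-standardized. Coordinate descent is delegated to scikit-learn's
`ElasticNet`, whose objective matches exactly; the test suite verifies the
fit against the soft-threshold closed form on orthonormal designs and
against OLS at λ = 0. λ grids are log-spaced from the data-driven
`λ_max = max|Xᵀ(y−ȳ)|/(nα)` down to `λ_max·10⁻⁴` (50 points) with mixing
α ∈ {0.1, …, 1.0} by default.

Tuning is an inner leave-one-*training*-subject-out grid search minimizing
mean subject-level RMSE (the inner unit of exchangeability matches the
outer fold unit), warm-started along each descending λ path; ties prefer
the larger λ, then the larger α (the sparser model). Demographic
covariates (age, sex, BMI, ethnicity dummies with Caucasian reference) are
penalized alongside the sensor features. Each breath row's target is the
subject's single reference value, so per-subject RMSE and MAE are computed
over a subject's rows and averaged unweighted across subjects; training
error refits the selected procedure on all rows and predicts all rows.

Breathing modes are compared with `RMSE_{s,m} = γ₀ + γ₁·mode + u_s + ε`,
`u_s ~ N(0, τ²)`, fit by maximum likelihood (statsmodels `MixedLM`), with
γ₁ tested by a likelihood-ratio test against the intercept-only model
(χ²₁). The design may be partially crossed. The ML-based LRT is mildly
anticonservative at small n; the suite checks its Type-I error stays
within [0.03, 0.07] at the study's own cohort size (18 subjects).
Reports flag each LOSO RMSE against the spirometry repeatability
benchmarks: 0.15 L for FVC and FEV1, 0.67 L/s for PEF.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to exercise the claimed
property with useful Monte-Carlo resolution: cohort calibration at
n = 10,000 (3-SE bands); event recovery over 20 seeds × 5 cycles per SNR
level with a ±0.5 s matching tolerance and a 0.02 allowance on the
monotonicity comparison of seed-averaged recalls; support recovery over
20 cohorts of 50 subjects × 5 breaths at a 4:1 signal-to-noise variance
ratio with a test-scale tuning grid (α ∈ {0.5, 1.0}, 15-point λ path to
λ_max/100); Boruta calibration over 20 seeds of 60 × 50 designs with
100-tree forests; mixed-model calibration over 1000 replicates. Library
defaults (500 trees, 10 × 50 tuning grid, 100 Boruta iterations) are
larger than these test-scale settings.

## Known limitations

* The acoustic generator does not model adventitious sounds, mouth-
  radiated turbulence, device-coupling physics or disease-specific
  acoustics, and it does not link audio content to the spirometric
  targets — end-to-end prediction accuracy on real recordings cannot be
  inferred from these tests.
* Time alignment between streams is declared (shared t = 0), never
  estimated; no cross-correlation alignment is attempted.
* Boruta applied once pre-CV inherits the protocol's optimistic bias.
* The mixed model uses a random intercept only; random slopes are not
  supported (nor estimable at these cohort sizes).
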