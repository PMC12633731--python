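# Methods

This note documents the models, conventions and numerical choices behind
`finstroke`, in the spirit of a statistics package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stroke-cycle model and polar timing

A trial is a sequence of annotated stroke cycles, each split at `t_mid`
into a propulsive phase (adduction while swimming; stance while walking)
and a recovery phase (abduction; swing). Event times are mapped onto a
0–360° circle **phase-wise**: propulsion onto [0°, 180°) and recovery
onto [180°, 360°), each linearly. This pins the phase boundary at 180°
regardless of the propulsion fraction, so "just after the start of
recovery" is always just past 180° for both behaviours even though a
walking stance occupies a different fraction of the cycle than a
swimming power stroke. A raw-time mapping (elapsed fraction × 360°) is
available via `mode="time"` for sensitivity checks. The mapping is
monotone within a cycle and surjective onto [0°, 360°).

## EMG processing chain

Order: centre → band-pass → denoise → envelope → threshold → rate
filter. Magnitude metrics (RIA, amplitude) are computed from the
centred, band-passed signal; the denoised signal is used only to build
the detection envelope. Rectification is the absolute value.

- **Centring** subtracts the mean of a quiet window; windows shorter
  than 50 ms are rejected as unreliable baselines.
- **Band-pass 40–4000 Hz** is a zero-phase Butterworth cascade:
  2nd-order high-pass at 40 Hz plus 10th-order low-pass at 4000 Hz.
  The asymmetry is deliberate: a steep high-pass at 40 Hz has an
  impulse response tens of milliseconds long and visibly smears burst
  edges, while the gentle 2nd-order section (≈ −48 dB at 10 Hz after
  forward–backward filtering) keeps edges sharp; the upper edge can
  afford a sharp 10th-order section (> 20 dB attenuation by 4500 Hz).
- **Denoising** is wavelet-domain empirical Bayes (sym4, symmetric
  extension, decomposition level min(⌊log₂ n⌋ − 4, 10)). Each detail
  level is modelled as a two-component Gaussian scale mixture: noise
  variance σ² from the level's median absolute deviation (MAD/0.6745),
  slab weight and variance estimated from coefficients above the
  universal threshold σ√(2 ln n). Coefficients are replaced by their
  posterior mean, which suppresses noise-dominated coefficients toward
  zero while passing burst energy nearly unchanged (energy retention
  ≥ 0.9 at SNR 10 is asserted by test). Symmetric extension matters:
  periodic extension wraps end-of-record burst energy to t = 0 and
  creates spurious detections.
- **Envelope**: centred moving RMS over 400 samples (40 ms at 10 kHz),
  boundary windows truncated to the record, so a constant input maps to
  itself everywhere.
- **Detection**: maximal runs of the envelope strictly above 25% of its
  mean over the *whole trial* (a per-cycle baseline is a documented
  alternative; the whole-trial mean is used because the threshold should
  not change between cycles of one recording). Onset is the first
  supra-threshold sample; offset the time just after the last.
- **Rate filter** (100 Hz physiological limit): a full on–off cycle at
  100 Hz lasts 10 ms, so inter-burst gaps < 10 ms are merged *first*,
  then bursts < 10 ms are dropped. The order matters (merging can
  rescue a short burst adjacent to another) and both thresholds are
  configurable. The operation is idempotent.

A centred-RMS envelope inevitably biases detected boundaries outward by
up to half the window (≈ 17 ms at the default threshold); the ±20 ms
detection tolerance used in validation equals the half-window and the
measured bias and spread sit inside it.

### Burst metrics and normalization

Bursts straddling a cycle or phase boundary are clipped to the scope; a
clipped fragment counts as one burst in each scope it intersects.
Per scope: activation duration is summed fragment length (so the phase
durations sum exactly to the full-cycle duration); duty factor is
100 × duration / scope length; amplitude is the mean of the top 5% of
rectified samples pooled across the scope's fragments; RIA% is the ratio
of summed trapezoidal integrals of the rectified signal to the summed
theoretical maxima (channel max amplitude × fragment duration) — a ratio
of sums, not a mean of ratios, which keeps it within [0, 100].

The per-channel normalizer is the largest of the *same per-scope
amplitude statistic* across all cycles and both behaviours of that
fish × channel. Normalizing by the largest whole-burst amplitude
instead would let fragments of a clipped burst exceed 100%, because the
top 5% of a fragment containing a burst's loudest stretch exceeds the
top 5% of the whole burst. With the per-scope maximum, every amp% and
RIA% is bounded by 100 with equality attained somewhere on each channel.

## Kinematic variables

All coordinates are in body lengths (BL). Speed over ground is the
nose-path polyline length over elapsed time; the 3D path is the default
(the horizontal projection is available by flag, since either reading of
"distance travelled along the path" is defensible). Swing distances are
x–y polyline lengths over one full cycle, excluding z. Elevation
statistics are extrema of the fin-tip z coordinate; ties are broken by
first occurrence and logged. The adduction angle is the oriented angle
at the fin-base vertex between the base→nose and base→tip rays in the
x–y plane, unwrapped across frames so a fin sweeping past the body axis
continues beyond 180° instead of reflecting; the branch is oriented so
adduction increases the angle. Angular velocity uses central differences
on the unsmoothed angle (no smoothing is applied by default since none
is documented for the source workflow; a low-pass option exists).
"Maximum" and "routine" velocities are the means of the top 5% and top
20% of magnitudes within each sign class (negative = abduction),
reported signed; an empty sign class yields a missing value, not zero.
Cycles with missing frames are dropped unless interpolation is
explicitly enabled.

## Circular statistics

Descriptives: mean direction from the resultant vector; R̄ = mean
resultant length; angular variance 1 − R̄ (unit-free) and, for
degree-scale reporting, the angular deviation √(2(1 − R̄)) in degrees —
both are exposed because published tables are ambiguous about which
convention "±a.var." uses. The circular s.e.m. is the large-sample
formula √((1 − α̂₂)/(2nR̄²)) with α̂₂ the second trigonometric moment
about the mean. R̄ ≈ 0 flags the mean as undefined.

Tests: Rayleigh uses z = nR̄² with the standard asymptotic series.
The Hermans–Rasson statistic is the trigonometric-moment form with the
2.895 sine term; its null is Monte-Carlo (default 10 000 uniform
resamples at matched n, seeded). The Kuiper von Mises check fits (μ, κ)
by maximum likelihood (Best–Fisher approximation for A₁⁻¹), transforms
through the fitted CDF and refers V = D⁺ + D⁻ to a parametric-bootstrap
null with parameters refitted per replicate (default 500 reps), since
the fitted-parameter case has no usable closed form. Watson–Williams
uses the (1 + 3/8κ̂) correction with κ̂ from the pooled within-sample
resultant and warns when the pooled R̄ < 0.45. The two-sample Watson U²
uses the asymptotic tail 2Σ(−1)^{k−1}exp(−2k²π²U²) when both n ≥ 8,
else a pooled permutation p. Degenerate samples (all angles identical)
short-circuit: the von Mises fit is flagged and uniformity rejected.

Decision tree: per sample, Kuiper p ≥ α routes uniformity testing to
Rayleigh, otherwise to Hermans–Rasson; a two-sample comparison runs only
when both samples are non-uniform; Watson–Williams is chosen iff both
samples pass the von Mises check *and* each sample's R̄ exceeds 0.45
(the cutoff is applied per sample, both must exceed), else Watson U².
Every result records a selection trace for auditability.

## Mixed models

`fit_lme` fits REML linear mixed models with a random intercept per
fish via statsmodels' MixedLM (ML is used only when nested models are
compared). Heteroskedastic residuals ("per_<factor>" variance
structure) are handled by feasible GLS: per-level residual SDs from a
first homoskedastic fit rescale the response, design and random-effect
column, and the model is refit on the homoskedastic scale; the scales
are logged. Fits whose intercept variance collapses to the boundary
(≤ 10⁻¹⁰ of the response variance) or that fail to converge after
optimizer retries fall back to an ordinary linear model with fish as a
fixed blocking factor, with a warning.

ANOVA-type tables use Wald F per fixed term with **containment**
denominator degrees of freedom: terms varying within fish get
N − M − p_inner, terms constant within fish get M − p_outer (M = number
of fish), mirroring the df style of nlme-based reports. Marginal and
conditional R² follow the variance-decomposition definition:
R²m = var(Xβ̂)/(var(Xβ̂) + σ²_fish + σ²_ε) and R²c adds σ²_fish to the
numerator. Estimated marginal means average fixed-effect predictions
over a balanced reference grid (equal weight per factor combination),
which makes them equal arithmetic group means in balanced designs,
exactly; their s.e.m. comes from the fixed-effect covariance. Pairwise
contrasts use t statistics on containment df; Bonferroni multiplies by
the family size — by default every contrast computed in the call (e.g.
6 muscle pairs × 2 behaviours = 12), overridable where a table's family
is defined differently.

Cohen's d is the pooled-SD standardized mean difference. The Evans Blue
analysis subtracts the per-section background from each cell intensity
(negative values are kept — dark cells are data), fits per size-class
OLS of adjusted intensity on % fin length + treatment (interaction on
request), and reports Cohen's d per muscle.

## Synthetic-data generator

The generator emulates the study design end to end: 4 fish × 10 cycles
per behaviour by default; swimming cycles 0.20 ± 0.02 s with a 0.50
propulsion fraction; walking cycles 0.60 ± 0.06 s with 0.55 (fin-beat
frequencies of ≈ 5 and ≈ 1.7 Hz chosen to be consistent with duty
factors and activation durations typical of reported swimming/walking
fin use). EMG is sampled at 10 kHz, video at 500 frames s⁻¹.

- **EMG**: bursts are Gaussian-noise carriers band-passed 40–4000 Hz
  with trapezoidal amplitude envelopes (5 ms rise/fall), inserted at
  scheduled cycle-phase positions jittered by a von Mises draw on the
  cycle circle (κ = 50 by default) so that timing ground truth is
  exactly von Mises. Carriers are synthesized inside the burst support
  only, so a noiseless configuration is identically zero outside bursts.
  Baseline Gaussian noise (SD 0.1 against burst amplitudes of 0.5–1.0,
  i.e. SNR 5–10 by muscle) and occasional low-frequency artifacts
  (0.2 s⁻¹, 2–15 Hz, Hann-windowed) complete the trace. Bursts whose
  jittered schedules overlap are merged in the ground truth and flagged.
  The default schedule follows the qualitative activation pattern of the
  four fin muscle groups, including the walking adductor's
  near-continuous activity through stance and swing — which means
  adjacent walking adductor bursts can legitimately merge under the
  100 Hz rate filter, a property of the emulated biology.
- **Kinematics**: the fish advances at constant speed along +x; fin
  elevation, adduction angle and (walking) nose elevation are sinusoids
  in stroke-phase angle, so per-cycle extrema, ranges and extreme
  timings have exact closed forms; swing-path truth uses adaptive
  quadrature of the analytic path speed. What it does *not* emulate:
  digitization noise, calibration error, missing frames, or
  musculoskeletal dynamics — passing tests show the pipeline's numerics
  are correct, not that it is robust to tracking error.
- **Study tables**: response = grand mean + behaviour effect + muscle
  effect + interaction + Normal fish intercept (SD 5) + residual
  (SD 10), defaults on a duty-factor-like percentage scale.
- **Fluorescence**: cell intensity = baseline + treatment shift of
  d × SD + slope × (% fin length) + noise + constant per-section
  background.

Determinism: all streams derive from the config seed and a BLAKE2 digest
of (trial, stream) labels, so identical configs give bit-identical
outputs across processes.

## Validation problem sizes

The test suite and the reproduction script use: 100 cycles × 4 muscles
for burst detection accuracy; 2000 uniform simulations per n ∈
{10, 50, 200} for circular-test calibration (the Hermans–Rasson rate is
computed against a single seeded 2000-replicate null table per n, which
yields the same empirical type-I error as per-sample Monte-Carlo
p-values at a fraction of the cost); 50 constructed sample pairs for
decision-tree conformance; 500 replicate mixed-model fits (4 fish × 10
cycles/behaviour) for CI coverage; and one analytic walking trial for
the kinematic closed forms.

## Known limitations

- The centred-RMS envelope biases burst boundaries outward by an amount
  set by the window and threshold; boundary timings should be compared
  between conditions processed identically, not read as absolute onsets.
- The FGLS variance-structure option is a two-pass approximation, not a
  jointly estimated heteroskedastic mixed model.
- Containment df are a convention; Satterthwaite-style approximations
  can differ for unbalanced designs.
- The decision tree's routing depends on stochastic sub-tests (bootstrap
  and Monte-Carlo p-values); seeds are recorded so routing is
  reproducible.
- Multi-group (> 2) circular comparisons and circular–linear correlation
  are out of scope.
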