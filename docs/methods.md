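# Methods

## Scope and model

`circlegait` implements a complete analysis chain for assessing
progression of Parkinson's disease (PD) from circular-walking trials
recorded by a single tri-axial accelerometer worn on the lower back
(L5), sampled at 100 Hz. The chain has four stages:

1. **Preprocessing** — realignment for static sensor tilt, gravity/offset
   removal, and template-matching segmentation of the anterior-posterior
   (AP) acceleration into step cycles.
2. **Feature extraction** — 24 gait characteristics per trial, averaged
   over the clockwise / counter-clockwise pair of trials of a visit.
3. **Longitudinal modelling** — annualisation of biannual visits,
   log/z transforms, and generalized estimating equations (GEE) with
   exchangeable working correlation over up to five yearly time points.
4. **Marker screening** — conjunctive criteria (four for early-stage PD,
   three for middle-stage PD), each tested at α = 0.10 with a clinical
   direction gate, identifying features that qualify as candidate
   progression markers.

Because raw clinical recordings of this kind are not redistributable, the
package ships a first-class synthetic-data layer whose generative
parameters are known exactly, giving every stage a parameter-recovery test
surface.

## Synthetic walking signal

Each stride *i* realises a stride time `T_i ~ N(μ, σ²)` (defaults
μ = 1.05 s, σ = 0.02 s; σ = 0.05 s is used for the PD-like segmentation
studies, see below). A stride splits into two steps whose durations
differ by a configurable asymmetry offset (±a/2, preserving `T_i`). A
*step phase* φ(t) advances by exactly 1 per step, piecewise-linearly and
continuously; each axis is

    x(t) = Σ_k A_k sin(π k φ(t)) + ε(t),  ε ~ N(0, σ_n²)

so harmonic k of the *stride* frequency has amplitude `A_k`. Even-k terms
repeat every step (the biphasic vertical/AP pattern); odd-k terms flip
sign between the two steps of a stride and carry the left/right
structure. Default amplitudes (≈0.1–2 m/s², step-frequency harmonic
dominant on VT/AP, stride-frequency harmonic dominant on ML) follow
typical lower-trunk acceleration magnitudes during comfortable gait; the
original device range and resolution make these directly representable.
Phase continuity means stride-time jitter widens spectral peaks without
introducing artifacts — the causal path the width-of-peak-power feature
is designed to detect. Gravity rides on VT, a static tilt rotates the
whole trial about the ML axis, and white sensor noise is added last.
Ground-truth step-onset times are returned exactly.

Not emulated: centripetal components of walking in a 1.2 m circle,
double-support transients, foot-strike impact shapes, or freezing
episodes. Passing tests therefore demonstrate correctness of the
*computational chain* under a controlled quasi-periodic signal model, not
clinical validity on patient recordings.

## Preprocessing

**Realignment** applies the minimal rigid rotation taking the mean
standing-window acceleration vector onto +VT (axis = cross product,
angle = arccos of the normalised dot product). This avoids Euler-angle
conventions and is unique for any non-antiparallel input. A standing mean
outside [0.5 g, 1.5 g] aborts as a calibration failure.

**Offset removal** subtracts the mean of the first 20 samples (0.2 s of
quiet standing) from each axis, removing the gravity offset on VT.

**Segmentation** works on the AP axis: (1) the dominant step frequency is
the Welch-PSD peak in 1.2–3.5 Hz, accepted only when it exceeds 5× the
median band power (pure noise is thereby rejected); (2) initial onset
candidates are AP peaks separated by at least half a step period; (3) the
step template is the pointwise mean of candidate cycles resampled to the
median cycle length, circularly anchored at its steepest upward
zero-crossing; (4) onsets are normalized-cross-correlation maxima above
0.3 with the same minimum separation; (5) the template is re-formed from
the detected cycles until the onset count stabilises (≤ 5 iterations).
The anchoring step matters: template matching alone locks onsets at an
arbitrary phase fraction c of the step cycle, and an onset at phase c
contaminates each stride duration with c times the local stride-time
change; anchoring at the sharp AP rise (the initial-contact convention)
pins that phase to the cycle boundary. The 0.3 threshold and 5-iteration
cap were chosen for stability on synthetic parameter sweeps and are
exposed in the pipeline configuration. Fewer than four onsets, or no
dominant frequency, sets a failure flag instead of raising.

**Validation** matches estimated to reference onsets by nearest time,
pairs stride durations through that matching, and reports the mean
absolute stride-duration difference (ms and % of the mean stride) plus
ICC(2,1) (two-way random effects, absolute agreement, single measurement,
computed by `pingouin`). On ten synthetic trials with stride-time SD
0.05 s and noise SD 0.3 m/s² the segmenter recovers stride durations with
a mean absolute error around 10–15 ms and pooled ICC above 0.9. The
0.05 s jitter level reflects the high stride-to-stride variability of
impaired circular gait; at low jitter the ICC is bounded above by the
ratio of true stride variance to total variance (σ²_true/(σ²_true+σ²_err))
and is uninformative about segmenter quality, so the agreement study is
run at the impaired-gait variability level.

## The 24 features

Temporal features come from the segmentation: number of steps, total
walking duration, step-time asymmetry (|mean odd-indexed − mean
even-indexed step duration|; leg identity is unobservable from one
sensor), median stride time, and stride-time variability (SD after
trimming ceil(0.05 n) values from each tail — guaranteeing at least one
trimmed value per tail).

Amplitude and rhythmicity features are computed on the raw, unfiltered
walking segment: per-axis SD ("movement intensity"); step and stride
regularity as the normalised unbiased autocovariance at a lag of one
step/stride period, maximised within ±10% of the median period (robust to
one-sample quantisation; unbiased normalisation may slightly exceed 1 and
is reported unclipped).

Spectral features use a Welch PSD with a 900-sample Hanning window, 50%
overlap and a 9000-point FFT (resolution 0.0111 Hz). Harmonic ratios are
Σ even / Σ odd harmonic amplitudes of the stride frequency for VT and AP
(biphasic per stride) and the inverse for ML (monophasic); amplitudes of
harmonics 1–20 are evaluated directly at k·f₀ over an integer number of
strides rather than read off the Welch grid, avoiding bin-snapping bias.
The index of harmonicity is P₁ / Σ₁⁶ Pᵢ with each Pᵢ the PSD maximum
within ±0.15 Hz of the harmonic; its fundamental is the step frequency
for VT/AP and the stride frequency for ML, mirroring the harmonic-ratio
parity logic. Normalised peak power is the dominant PSD peak in
0.3–5 Hz divided by the trapezoid-integrated PSD; width of peak power is
that peak's full width at half maximum by linear interpolation (for a
pure tone this reduces to the Hanning mainlobe FWHM, ≈0.16 Hz, which the
tests verify).

Flagged features (failed preconditions) are NaN with a quality mask; the
clockwise/counter-clockwise average falls back to the available side.

## Longitudinal models

Biannual visits are averaged into years (a single missed visit leaves the
remaining one); a feature is log-transformed when its pooled skewness
exceeds 1 (offset 1 − min(x) enforces positivity when needed) and then
z-scored using the mean and SD of per-subject means over the two groups
entering the comparison, so coefficients are comparable across features.

Progression models are identity-link Gaussian GEE with exchangeable
working correlation on Group (PD = 1), Time (years from 0) and
Group × Time, with backward elimination of candidate confounders (trial
duration as gait-speed proxy, age, ON/OFF medication; only age and
medication when duration or a clinical rating is the outcome) at
α = 0.05, dropping the least significant each refit. Ties break by
dropping the later candidate in the fixed order. Annual change re-fits
Time within one group on the raw scale, reusing the confounders retained
by the two-group model, and divides the coefficient and SE by the group's
first-year mean (×100). The clinical-rating association regresses each
transformed feature on the gait rating over the pooled groups.

Two numerical safeguards matter in cohorts of this size (≈25 subjects per
group, 5 years, ~50% attrition by year five):

* the moment estimate of the exchangeable correlation can exceed 1 under
  strong between-subject heterogeneity, making the working covariance
  indefinite; it is clipped to [−0.95, 0.95];
* the plain robust sandwich is anti-conservative with ~50 clusters
  (empirical Group × Time type-I error ≈ 0.08 at nominal 0.05). All
  inference therefore uses the Mancl–DeRouen bias-reduced sandwich with a
  t reference on (clusters − parameters) degrees of freedom, which brings
  the simulated type-I error to ≈ 0.06.

Noise-free trajectories (zero residual variance) break the GEE scale
estimate; the annual-change slope then falls back to exact least squares,
with p defined as 1 for a zero slope and 0 otherwise.

## Marker screening

A feature is an early-stage marker when it meets E1–E4, and a mid-stage
marker when it meets M1–M3, all at α = 0.10 with a direction gate
(two-sided p plus a sign check — equivalent to a one-sided test at 0.05):

* E1/M1 — Group × Time interaction in the worsening direction;
* E2/M2 — within-group annual change in the worsening direction (the
  sign gate uses the raw Time coefficient, since the percent divides by a
  baseline whose own sign would cancel out of the check);
* E3/M3 — association with the clinical gait rating in the worsening
  direction (adjusted slope);
* E4 — baseline Group difference of the mid-stage model in the worsening
  direction (an early-progressing symptom should still be present,
  possibly at ceiling, in the middle stage; no mid-stage analogue exists
  without a more advanced group).

Under independence the per-feature false-marker level is 0.10⁴ = 10⁻⁴
(early) and 0.10³ = 10⁻³ (mid); criteria sharing data are positively
dependent, so these are conservative upper bounds (verified by null
simulation as ≤). A Bonferroni correction over 24 features at family-wise
0.05 (≈0.002) is reported for reference. Worsening directions ship as
data so the clinical convention is auditable.

## Simulation studies and problem sizes

The operating-characteristic studies (in `circlegait.validation`) use
cohort dimensions mirroring the target study design — 25/22/27 subjects
in HC/early/mid groups, five years, retention 100/82.3/77.0/63.5/51.4%,
16.4% of PD visits ON medication:

* type-I error of the Group × Time test: 500 null replicates;
* recovery of a planted 0.10 z-units/yr interaction and a planted 6%/yr
  annual change: 200 replicates each, judged within two Monte-Carlo SEs;
* end-to-end screen: 100 replicate cohorts in which exactly two features
  (harmonic ratio ML, stride-time variability — one per worsening
  direction) carry all stage-criterion effects; the screen must return
  exactly that marker set. These studies run on a reduced bank of eight
  named features (two planted, six null) to keep the runtime of a
  100-replicate study practical; the full 24-feature screen is exercised
  end-to-end elsewhere in the suite. The planted effect sizes
  (interaction ≈ 0.8 between-subject SDs per 4 years, mid-stage baseline
  shift ≈ 2.7 SDs) were calibrated for per-criterion power ≈ 0.99 so the
  conjunction succeeds in well over 90% of replicates;
* null screen: 60 fully null cohorts; false-marker rates are checked
  against the (conservative) independence bounds.

## Known limitations

* The template-matching segmenter is a faithful reconstruction of the
  published approach, validated against synthetic ground truth, not a
  bit-level reproduction of the original (unpublished) implementation.
* Linear GEE does not model exponential early-phase progression.
* The synthetic cohort generator imposes linear group trajectories with
  Gaussian heterogeneity; it does not emulate informative dropout
  (attrition is independent of outcome), phenotype subtypes, or
  medication-dose effects.
* Marker identification here is population-level screening, not
  individual-level prediction.
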