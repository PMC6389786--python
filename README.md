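# circlegait

Quantitative assessment of **circular gait** (walking in small circles)
from a single lower-back tri-axial accelerometer, and **longitudinal
screening of gait features as progression markers** for early- and
middle-stage Parkinson's disease (PD).

Gait deteriorates measurably in PD years before many other motor signs,
and turning-dominated walking stresses exactly the control systems the
disease degrades. A body-fixed sensor at L5 sampling at 100 Hz captures
this cheaply and objectively — but turning raw accelerations into
defensible progression markers requires a careful chain: step-cycle
segmentation, a validated feature bank, longitudinal models that tolerate
dropout and within-subject correlation, and a multi-criterion screen with
honest error control. `circlegait` implements that chain, plus a
synthetic-data layer with exact ground truth so every stage is testable
without access to clinical recordings.

## What it computes

**Preprocessing** — tilt realignment (rigid rotation of the standing mean
onto +VT), removal of the 20-sample initial offset, and template-matching
step segmentation of the AP acceleration.

**24 gait features** per visit (clockwise/counter-clockwise averaged):
number of steps, total duration, step-time asymmetry, median stride time,
trimmed stride-time variability; per-axis signal SD; step/stride
regularity (normalised unbiased autocovariance at one step/stride lag);
harmonic ratios HR = ΣA_even / ΣA_odd of the stride-frequency harmonics
(inverted for ML); index of harmonicity IH = P₁ / Σ₁⁶ Pᵢ; normalised
peak power and width (FWHM) of the dominant spectral peak. Spectral
estimates use Welch's method (900-sample Hanning window, 50% overlap,
9000-point FFT).

**Longitudinal GEE** — per feature, identity-link Gaussian GEE with
exchangeable working correlation and small-sample-corrected sandwich
errors:

    y_it = β₀ + β₁·Group_i + β₂·t + β₃·(Group_i × t) + γ'·confounders + ε_it

with backward elimination of confounders (trial duration, age,
medication) at α = 0.05, percent annual change (Time coefficient over the
first-year mean), and the regression of each feature on the clinical gait
rating (gait-UPDRS III).

**Marker screen** — a feature is an early-stage marker when it meets four
conjunctive criteria (interaction, within-group annual change, clinical
association, mid-stage baseline difference), and a mid-stage marker when
it meets the three analogous criteria, each at α = 0.10 with a clinical
direction gate. Under independence this implies per-feature levels of
0.1⁴ = 10⁻⁴ (early) and 0.1³ = 10⁻³ (mid), stricter than a 24-feature
Bonferroni reference of ≈0.002.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from circlegait.simulate import GaitSignalParams, generate_gait_accel
from circlegait.preprocess import realign_axes, remove_initial_offset, \
    segment_step_cycles, validate_segmentation
from circlegait.features import extract_feature_vector

params = GaitSignalParams(n_strides=18, mean_stride_time=1.05,
                          stride_time_sd=0.02, noise_sd=0.15, seed=5)
trial, truth = generate_gait_accel(params)
trial = remove_initial_offset(realign_axes(trial))
seg = segment_step_cycles(trial)
print(validate_segmentation(seg, truth))
vec = extract_feature_vector(trial, seg)
for name in ("median_stride_time", "stride_time_variability",
             "harmonic_ratio_vt", "index_harmonicity_vt", "width_peak_power_ap"):
    print(f"{name:28s} {vec[name]:.4f}")
```

prints

```
SegmentationAgreement(mean_abs_diff_ms=3.353..., mean_abs_diff_pct=0.319...,
                      icc=0.972..., n_matched=29, count_mismatch=False)
median_stride_time           1.0500
stride_time_variability      0.0144
harmonic_ratio_vt            3.2983
index_harmonicity_vt         0.8582
width_peak_power_ap          0.1612
```

i.e. the segmenter recovers stride durations to ~3 ms on this trial, the
median stride time matches the generator's 1.05 s, and the spectral
features sit where the injected harmonic structure puts them (the
0.16 Hz peak width is the Hanning mainlobe of a near-perfectly periodic
signal).

The cohort side, end to end from a simulated cohort table to the marker
report:

```bash
circlegait simulate-cohort --seed 1 --out cohort.csv
circlegait screen-markers cohort.csv --out marker_report.json
```

or the whole chain (trials → features → models → screen) in one call:

```bash
circlegait run-all --seed 1 --outdir results/
```

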