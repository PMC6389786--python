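"""Parameter-recovery and operating-characteristic studies.

These functions quantify how well the pipeline recovers known ground truth
from its own synthetic data: stride-duration agreement of the segmenter,
type-I error and effect recovery of the GEE engine, and end-to-end marker
recovery of the criterion screen.  They are used by the test suite and the
reproduction script; rep counts are arguments so callers choose their
precision/runtime trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .longitudinal import fit_progression_gee, percent_annual_change
from .preprocess import (
    realign_axes,
    remove_initial_offset,
    segment_step_cycles,
    validate_segmentation,
)
from .screening import screen_cohort
from .simulate import CohortParams, GaitSignalParams, generate_cohort, generate_gait_accel

__all__ = [
    "segmentation_recovery_study",
    "type_one_error_study",
    "interaction_recovery_study",
    "annual_change_recovery_study",
    "planted_screen_params",
    "null_screen_params",
    "screen_recovery_study",
    "null_screen_study",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class SegmentationRecovery:
    mean_abs_error_ms: float
    icc: float
    n_trials: int
    n_strides: int


def segmentation_recovery_study(n_trials: int = 10, seed: int = 0,
                                stride_time_sd: float = 0.05,
                                noise_sd: float = 0.3) -> SegmentationRecovery:
    """Stride-duration agreement between detected and ground-truth onsets,
    pooled over several jittered, noisy trials (ICC(2,1) on the pooled
    stride pairs)."""
    from .preprocess import _icc_2_1

    errs, est_all, ref_all = [], [], []
    for s in _spawn_seeds(seed, n_trials):
        params = GaitSignalParams(n_strides=25, stride_time_sd=stride_time_sd,
                                  noise_sd=noise_sd, seed=s)
        trial, onsets = generate_gait_accel(params)
        trial = remove_initial_offset(realign_axes(trial))
        seg = segment_step_cycles(trial)
        if seg.failed:
            continue
        rep = validate_segmentation(seg, onsets)
        errs.append(rep.mean_abs_diff_ms)
        # rebuild the matched stride pairs for pooled ICC
        est_t = seg.onset_times
        ref = np.sort(onsets)
        match = np.searchsorted(ref, est_t)
        match = np.clip(match, 1, ref.size - 1)
        match = np.where(np.abs(ref[match] - est_t) < np.abs(ref[match - 1] - est_t),
                         match, match - 1)
        for i in range(est_t.size - 2):
            j = match[i]
            if j + 2 < ref.size and match[i + 2] == j + 2:
                est_all.append(est_t[i + 2] - est_t[i])
                ref_all.append(ref[j + 2] - ref[j])
    icc = _icc_2_1(np.asarray(est_all), np.asarray(ref_all))
    return SegmentationRecovery(float(np.mean(errs)), float(icc), n_trials, 25)


def _two_group_cohort(seed: int, slope: float = 0.0, n: int = 25) -> pd.DataFrame:
    params = CohortParams(
        n_per_group={"HC": n, "EarlyPD": n, "MidPD": 0},
        baseline_mean={"f1": {"HC": 0.0, "EarlyPD": 0.0, "MidPD": 0.0}},
        annual_slope={"f1": {"HC": 0.0, "EarlyPD": slope, "MidPD": 0.0}},
        between_subject_sd={"f1": 1.0},
        residual_sd={"f1": 0.5},
        features=("f1",),
        seed=seed,
    )
    tab = generate_cohort(params)
    return tab.drop(columns=["age", "medication", "updrs_gait"])


def type_one_error_study(n_reps: int = 500, seed: int = 0, alpha: float = 0.05,
                         n_per_group: int = 25) -> float:
    """Rejection rate of the Group x Time test under a fully null cohort."""
    hits = 0
    for s in _spawn_seeds(seed, n_reps):
        fit = fit_progression_gee(_two_group_cohort(s, 0.0, n_per_group), "early", "f1")
        if fit.pvalues["group_time"] < alpha:
            hits += 1
    return hits / n_reps


def interaction_recovery_study(n_reps: int = 200, seed: int = 0,
                               slope: float = 0.10) -> tuple[float, float]:
    """Mean Group x Time estimate and its Monte-Carlo SE under a planted
    interaction of ``slope`` z-units/year."""
    ests = []
    for s in _spawn_seeds(seed, n_reps):
        fit = fit_progression_gee(_two_group_cohort(s, slope), "early", "f1")
        ests.append(fit.params["group_time"])
    return float(np.mean(ests)), float(np.std(ests, ddof=1) / np.sqrt(n_reps))


def annual_change_recovery_study(n_reps: int = 200, seed: int = 0,
                                 percent: float = 6.0) -> tuple[float, float]:
    """Mean recovered annual change (% of first-year mean) and its MC SE,
    for a planted within-group trend of ``percent`` %/year."""
    base = 100.0
    ests = []
    for s in _spawn_seeds(seed, n_reps):
        params = CohortParams(
            n_per_group={"HC": 0, "EarlyPD": 0, "MidPD": 27},
            baseline_mean={"f1": {"HC": base, "EarlyPD": base, "MidPD": base}},
            annual_slope={"f1": {"HC": 0.0, "EarlyPD": 0.0, "MidPD": base * percent / 100.0}},
            between_subject_sd={"f1": 10.0},
            residual_sd={"f1": 5.0},
            features=("f1",),
            seed=s,
        )
        tab = generate_cohort(params).drop(columns=["age", "medication", "updrs_gait"])
        ch = percent_annual_change(tab, "MidPD", "f1")
        ests.append(ch.percent_per_year)
    return float(np.mean(ests)), float(np.std(ests, ddof=1) / np.sqrt(n_reps))


#: Reduced feature bank for the end-to-end screen studies: two planted
#: markers plus six null features, all with their shipped worsening
#: directions.
SCREEN_FEATURES = (
    "harmonic_ratio_ml",        # planted, worsens by decreasing
    "stride_time_variability",  # planted, worsens by increasing
    "sd_ml",
    "step_regularity_ap",
    "index_harmonicity_ml",
    "norm_peak_power_ap",
    "width_peak_power_ml",
    "median_stride_time",
)
PLANTED = ("harmonic_ratio_ml", "stride_time_variability")

_NULL_LEVELS = {
    "sd_ml": (1.1, 0.12, 0.08),
    "step_regularity_ap": (0.78, 0.08, 0.05),
    "index_harmonicity_ml": (0.60, 0.06, 0.04),
    "norm_peak_power_ap": (0.8, 0.10, 0.07),
    "width_peak_power_ml": (0.30, 0.04, 0.03),
    "median_stride_time": (1.05, 0.07, 0.04),
}


def planted_screen_params(seed: int) -> CohortParams:
    """Cohort in which exactly two features carry all stage-criterion
    effects (group x time decline, within-group trend, clinical-rating
    association, mid-stage baseline shift); the other six are null."""
    baselines = {f: {g: v[0] for g in ("HC", "EarlyPD", "MidPD")}
                 for f, v in _NULL_LEVELS.items()}
    slopes = {f: {g: 0.0 for g in ("HC", "EarlyPD", "MidPD")} for f in _NULL_LEVELS}
    bsd = {f: v[1] for f, v in _NULL_LEVELS.items()}
    rsd = {f: v[2] for f, v in _NULL_LEVELS.items()}

    baselines["harmonic_ratio_ml"] = {"HC": 2.1, "EarlyPD": 2.0, "MidPD": 1.3}
    slopes["harmonic_ratio_ml"] = {"HC": 0.0, "EarlyPD": -0.25, "MidPD": -0.20}
    bsd["harmonic_ratio_ml"] = 0.30
    rsd["harmonic_ratio_ml"] = 0.20

    baselines["stride_time_variability"] = {"HC": 0.025, "EarlyPD": 0.028, "MidPD": 0.040}
    slopes["stride_time_variability"] = {"HC": 0.0, "EarlyPD": 0.004, "MidPD": 0.005}
    bsd["stride_time_variability"] = 0.004
    rsd["stride_time_variability"] = 0.003

    return CohortParams(
        n_per_group={"HC": 25, "EarlyPD": 22, "MidPD": 27},
        baseline_mean=baselines,
        annual_slope=slopes,
        between_subject_sd=bsd,
        residual_sd=rsd,
        severity_loading={"harmonic_ratio_ml": -0.12, "stride_time_variability": 0.0020},
        features=SCREEN_FEATURES,
        seed=seed,
    )


def null_screen_params(seed: int) -> CohortParams:
    """Fully null cohort over the same reduced feature bank."""
    params = planted_screen_params(seed)
    for f in PLANTED:
        base = params.baseline_mean[f]["HC"]
        params.baseline_mean[f] = {g: base for g in ("HC", "EarlyPD", "MidPD")}
        params.annual_slope[f] = {g: 0.0 for g in ("HC", "EarlyPD", "MidPD")}
    params.severity_loading = {}
    return params


@dataclass
class ScreenStudy:
    exact_rate: float
    early_exact_rate: float
    mid_exact_rate: float
    false_early_rate: float  # per null feature per rep
    false_mid_rate: float
    n_reps: int


def screen_recovery_study(n_reps: int = 100, seed: int = 0) -> ScreenStudy:
    """Fraction of replicate cohorts in which the screen recovers exactly
    the two planted markers, for each stage and jointly."""
    early_hits = mid_hits = both = 0
    false_early = false_mid = 0
    n_null = len(SCREEN_FEATURES) - len(PLANTED)
    for s in _spawn_seeds(seed, n_reps):
        tab = generate_cohort(planted_screen_params(s))
        rep = screen_cohort(tab, features=list(SCREEN_FEATURES))
        e_ok = set(rep.early_markers) == set(PLANTED)
        m_ok = set(rep.mid_markers) == set(PLANTED)
        early_hits += e_ok
        mid_hits += m_ok
        both += e_ok and m_ok
        false_early += len(set(rep.early_markers) - set(PLANTED))
        false_mid += len(set(rep.mid_markers) - set(PLANTED))
    return ScreenStudy(both / n_reps, early_hits / n_reps, mid_hits / n_reps,
                       false_early / (n_reps * n_null), false_mid / (n_reps * n_null),
                       n_reps)


@dataclass
class NullScreenStudy:
    false_early_rate: float  # per feature per rep
    false_mid_rate: float
    n_reps: int
    n_features: int


def null_screen_study(n_reps: int = 60, seed: int = 0) -> NullScreenStudy:
    """False-marker rates of the screen on fully null cohorts."""
    false_early = false_mid = 0
    for s in _spawn_seeds(seed, n_reps):
        tab = generate_cohort(null_screen_params(s))
        rep = screen_cohort(tab, features=list(SCREEN_FEATURES))
        false_early += len(rep.early_markers)
        false_mid += len(rep.mid_markers)
    k = len(SCREEN_FEATURES)
    return NullScreenStudy(false_early / (n_reps * k), false_mid / (n_reps * k),
                           n_reps, k)
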