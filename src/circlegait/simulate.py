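"""Synthetic gait signals and longitudinal cohorts with known ground truth.

Real recordings from the study population this package targets are not
redistributable, so every downstream stage is exercised against simulated
data whose generative parameters are known exactly.  Two generators are
provided:

* :func:`generate_gait_accel` builds a tri-axial lower-back acceleration
  trial — a quiet-standing prefix followed by quasi-periodic walking — from
  explicit stride timing, harmonic amplitude structure, sensor tilt and
  noise, returning the exact step-onset times as ground truth.
* :func:`generate_cohort` builds a long-format subject x year table of gait
  features with group-specific baselines and annual slopes, between-subject
  heterogeneity, confounder effects, a clinical gait rating driven by a
  latent severity, and monotone attrition.

The walking signal model: each stride ``i`` realises a stride time
``T_i ~ N(mean_stride_time, stride_time_sd^2)`` split into two steps whose
durations differ by the configured asymmetry offset.  A step phase
``phi_step(t)`` advances by exactly 1 per step, piecewise-linearly and
continuously, and each axis is a sum of sinusoids at harmonics ``k`` of the
stride frequency, ``sum_k A_k sin(pi k phi_step(t))``.  Harmonics with even
``k`` repeat every step (the biphasic VT/AP pattern); odd ``k`` alternate
sign between the two steps of a stride and carry left/right structure.
Phase continuity means stride-time jitter widens the spectral peaks without
creating artifacts, which is what the width-of-peak-power feature responds
to.  Gravity rides on the VT axis, a static sensor tilt rotates the whole
trial, and white noise is added last.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import FEATURE_NAMES, G, GROUPS, SAMPLE_RATE, AccelTrial

__all__ = [
    "GaitSignalParams",
    "CohortParams",
    "generate_gait_accel",
    "generate_cohort",
    "split_to_biannual_visits",
    "default_cohort_params",
    "write_trial_csv",
    "write_cohort_csv",
]

# Even-dominant amplitude lists (m/s^2) for VT and AP — the step-frequency
# harmonic (k=2) dominates — and an odd-dominant list for ML.  Magnitudes
# follow typical lower-trunk accelerations during comfortable walking.
_DEFAULT_AMPS_VT = (0.5, 2.0, 0.25, 0.8, 0.12, 0.3)
_DEFAULT_AMPS_ML = (1.2, 0.25, 0.45, 0.12, 0.15, 0.05)
_DEFAULT_AMPS_AP = (0.4, 1.4, 0.2, 0.55, 0.1, 0.25)


@dataclass
class GaitSignalParams:
    """Generative parameters of one synthetic walking trial.

    ``step_asymmetry`` is a constant offset (s) added to every second step's
    duration (and subtracted, halved, from its partner so the stride time is
    preserved).  ``harmonic_amps_*`` are amplitudes for harmonics 1..K of
    the stride frequency.  ``standing_duration`` must cover the 20-sample
    window used downstream for offset removal.
    """

    sample_rate: float = SAMPLE_RATE
    n_strides: int = 18
    mean_stride_time: float = 1.05
    stride_time_sd: float = 0.02
    step_asymmetry: float = 0.0
    harmonic_amps_vt: tuple[float, ...] = _DEFAULT_AMPS_VT
    harmonic_amps_ml: tuple[float, ...] = _DEFAULT_AMPS_ML
    harmonic_amps_ap: tuple[float, ...] = _DEFAULT_AMPS_AP
    noise_sd: float = 0.15
    standing_duration: float = 2.0
    tilt_deg: float = 0.0
    direction: str = "clockwise"
    seed: int = 0

    def validate(self) -> None:
        if self.mean_stride_time <= 0:
            raise ValueError("mean_stride_time must be positive")
        if self.stride_time_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.standing_duration < 0.2:
            raise ValueError("standing_duration must be >= 0.2 s to cover the offset window")
        if self.n_strides < 3:
            raise ValueError("need at least 3 strides for downstream feature definitions")
        for amps in (self.harmonic_amps_vt, self.harmonic_amps_ml, self.harmonic_amps_ap):
            if not np.all(np.isfinite(amps)):
                raise ValueError("harmonic amplitudes must be finite")


def _step_onset_times(params: GaitSignalParams, rng: np.random.Generator) -> np.ndarray:
    """Realise stride times and split them into alternating step onsets.

    Returns 2*n_strides + 1 onset times (the last marks the end of the final
    step), so consecutive differences are step durations and alternate
    differences are stride durations.
    """
    T = rng.normal(params.mean_stride_time, params.stride_time_sd, params.n_strides)
    if (T <= 0).any():
        raise ValueError("stride_time_sd too large: a realised stride time is <= 0")
    half = params.step_asymmetry / 2.0
    durs = np.empty(2 * params.n_strides)
    durs[0::2] = T / 2.0 - half
    durs[1::2] = T / 2.0 + half
    if (durs <= 0).any():
        raise ValueError("step_asymmetry too large for the realised stride times")
    return params.standing_duration + np.concatenate([[0.0], np.cumsum(durs)])


def _harmonic_sum(phi_step: np.ndarray, amps: tuple[float, ...]) -> np.ndarray:
    out = np.zeros_like(phi_step)
    for k, a in enumerate(amps, start=1):
        if a:
            out += a * np.sin(np.pi * k * phi_step)
    return out


def _tilt_rotation(tilt_deg: float) -> np.ndarray:
    """Rotation of the sensor frame about the ML axis by ``tilt_deg``."""
    c, s = np.cos(np.radians(tilt_deg)), np.sin(np.radians(tilt_deg))
    # axes ordered (VT, ML, AP)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def generate_gait_accel(params: GaitSignalParams) -> tuple[AccelTrial, np.ndarray]:
    """Generate a synthetic trial and its ground-truth step onset times.

    Returns
    -------
    trial : AccelTrial
        Standing prefix followed by walking; ``trial_bounds`` delimit the
        walking portion.
    onsets : ndarray
        Exact step-onset times in seconds (2*n_strides + 1 values).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    onsets = _step_onset_times(params, rng)
    fs = params.sample_rate
    n = int(round(onsets[-1] * fs)) + 1
    t = np.arange(n) / fs

    # Step phase: 0 before walking, advances by 1 per step, clamped at the end.
    phi_step = np.interp(t, onsets, np.arange(onsets.size, dtype=float))
    walking = (t >= onsets[0]) & (t <= onsets[-1])

    vt = np.where(walking, _harmonic_sum(phi_step, params.harmonic_amps_vt), 0.0) + G
    ml = np.where(walking, _harmonic_sum(phi_step, params.harmonic_amps_ml), 0.0)
    ap = np.where(walking, _harmonic_sum(phi_step, params.harmonic_amps_ap), 0.0)

    xyz = np.column_stack([vt, ml, ap]) @ _tilt_rotation(params.tilt_deg).T
    if params.noise_sd > 0:
        xyz = xyz + rng.normal(0.0, params.noise_sd, xyz.shape)

    start = int(round(onsets[0] * fs))
    trial = AccelTrial(
        time=t,
        acc_vt=xyz[:, 0],
        acc_ml=xyz[:, 1],
        acc_ap=xyz[:, 2],
        direction=params.direction,
        trial_bounds=(start, n),
        sample_rate=fs,
    )
    return trial, onsets


# ---------------------------------------------------------------------------
# Longitudinal cohort generator
# ---------------------------------------------------------------------------

#: Year-on-study retention fractions observed in five-year movement-disorder
#: cohorts of this size; dropout is monotone (no returns after a miss).
DEFAULT_RETENTION = (1.0, 0.823, 0.770, 0.635, 0.514)

# Plausible healthy-control baselines for the 24 features during circular
# walking, with PD groups shifted toward impairment.  Units follow the
# feature definitions (counts, s, m/s^2, dimensionless, 1/Hz, Hz).
_HC_BASELINES = {
    "n_steps": 19.0,
    "total_duration": 11.5,
    "step_time_asymmetry": 0.015,
    "median_stride_time": 1.05,
    "stride_time_variability": 0.025,
    "sd_vt": 1.6,
    "sd_ml": 1.1,
    "sd_ap": 1.2,
    "step_regularity_vt": 0.80,
    "step_regularity_ap": 0.72,
    "stride_regularity_vt": 0.85,
    "stride_regularity_ap": 0.78,
    "harmonic_ratio_vt": 2.4,
    "harmonic_ratio_ml": 2.1,
    "harmonic_ratio_ap": 2.2,
    "index_harmonicity_vt": 0.55,
    "index_harmonicity_ml": 0.60,
    "index_harmonicity_ap": 0.50,
    "norm_peak_power_vt": 0.9,
    "norm_peak_power_ml": 0.7,
    "norm_peak_power_ap": 0.8,
    "width_peak_power_vt": 0.25,
    "width_peak_power_ml": 0.30,
    "width_peak_power_ap": 0.28,
}

# Features for which an increase reflects gait worsening; the rest worsen by
# decreasing (kept consistent with the screening direction table).
_INCREASE_WORSENS = {
    "n_steps", "total_duration", "step_time_asymmetry", "stride_time_variability",
    "index_harmonicity_vt", "index_harmonicity_ml", "index_harmonicity_ap",
    "width_peak_power_vt", "width_peak_power_ml", "width_peak_power_ap",
}


@dataclass
class CohortParams:
    """Generative parameters of a longitudinal three-group cohort.

    ``baseline_mean`` and ``annual_slope`` are feature -> group -> value
    mappings; ``between_subject_sd`` and ``residual_sd`` are feature -> value
    (between-subject heterogeneity and the iid visit residual — together
    they induce an exchangeable within-subject correlation).
    ``confounder_effects`` maps feature -> {total_duration, age, medication}
    coefficients applied to centred confounders.  ``severity_loading`` ties a
    feature to the latent severity that also drives the clinical gait
    rating (``updrs_loading``).
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: {"HC": 25, "EarlyPD": 22, "MidPD": 27})
    n_years: int = 5
    baseline_mean: dict[str, dict[str, float]] = field(default_factory=dict)
    annual_slope: dict[str, dict[str, float]] = field(default_factory=dict)
    between_subject_sd: dict[str, float] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)
    confounder_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    severity_loading: dict[str, float] = field(default_factory=dict)
    age_mean: float = 63.0
    age_sd: float = 8.0
    p_on_medication: float = 0.164
    retention_by_year: tuple[float, ...] = DEFAULT_RETENTION
    updrs_loading: float = 1.2
    features: tuple[str, ...] = FEATURE_NAMES
    seed: int = 0

    def validate(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not 0.0 <= self.p_on_medication <= 1.0:
            raise ValueError("p_on_medication must be a probability")
        ret = np.asarray(self.retention_by_year[: self.n_years], dtype=float)
        if (np.diff(ret) > 0).any():
            raise ValueError("retention fractions must be non-increasing in year")
        if ((ret < 0) | (ret > 1)).any():
            raise ValueError("retention fractions must lie in [0, 1]")
        for table, label in ((self.between_subject_sd, "between_subject_sd"), (self.residual_sd, "residual_sd")):
            for f, v in table.items():
                if v < 0:
                    raise ValueError(f"negative variance component {label}[{f}]")


def default_cohort_params(**overrides) -> CohortParams:
    """Cohort parameters matching the study conditions: 25/22/27 subjects in
    HC / early-PD / mid-PD, five annual assessments, 16.4% of PD visits ON
    medication, and the observed retention schedule.  Baselines and slopes
    encode modest worsening in the PD groups."""
    baselines: dict[str, dict[str, float]] = {}
    slopes: dict[str, dict[str, float]] = {}
    bsd: dict[str, float] = {}
    rsd: dict[str, float] = {}
    for f in FEATURE_NAMES:
        base = _HC_BASELINES[f]
        scale = abs(base) if base else 1.0
        sign = 1.0 if f in _INCREASE_WORSENS else -1.0
        baselines[f] = {
            "HC": base,
            "EarlyPD": base + sign * 0.05 * scale,
            "MidPD": base + sign * 0.15 * scale,
        }
        slopes[f] = {
            "HC": sign * 0.002 * scale,
            "EarlyPD": sign * 0.02 * scale,
            "MidPD": sign * 0.03 * scale,
        }
        bsd[f] = 0.10 * scale
        rsd[f] = 0.06 * scale
    params = CohortParams(
        baseline_mean=baselines,
        annual_slope=slopes,
        between_subject_sd=bsd,
        residual_sd=rsd,
        confounder_effects={f: {"total_duration": 0.0, "age": 0.0, "medication": 0.0} for f in FEATURE_NAMES},
    )
    return dataclasses.replace(params, **overrides)


def _baseline_severity(group: str) -> float:
    return {"HC": 0.0, "EarlyPD": 1.0, "MidPD": 3.0}[group]


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a long-format cohort table, one row per subject-year.

    Columns: ``subject_id, group, year, age, medication, updrs_gait`` and one
    column per feature in ``params.features``.  Every subject has a year-0
    row; later years are thinned by the monotone retention schedule.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    feats = list(params.features)
    ret = list(params.retention_by_year) + [params.retention_by_year[-1]] * max(
        0, params.n_years - len(params.retention_by_year)
    )

    rows = []
    for group in GROUPS:
        n_sub = params.n_per_group.get(group, 0)
        for i in range(n_sub):
            sid = f"{group}_{i:03d}"
            age0 = rng.normal(params.age_mean, params.age_sd)
            u_drop = rng.uniform()
            intercepts = {f: rng.normal(0.0, params.between_subject_sd.get(f, 0.0)) for f in feats}
            sev_offset = rng.normal(0.0, 0.3) if group != "HC" else 0.0
            for year in range(params.n_years):
                if year > 0 and u_drop > ret[year]:
                    break  # monotone dropout
                med = int(rng.uniform() < params.p_on_medication) if group != "HC" else 0
                age = age0 + year
                severity = _baseline_severity(group) + sev_offset
                if group != "HC":
                    severity += 0.4 * year
                row: dict[str, object] = {
                    "subject_id": sid,
                    "group": group,
                    "year": year,
                    "age": age,
                    "medication": med,
                }
                # trial duration first: it confounds the other features
                values: dict[str, float] = {}
                for f in feats:
                    base = params.baseline_mean.get(f, {}).get(group, 0.0)
                    slope = params.annual_slope.get(f, {}).get(group, 0.0)
                    v = base + slope * year + intercepts[f]
                    v += params.severity_loading.get(f, 0.0) * severity
                    v += rng.normal(0.0, params.residual_sd.get(f, 0.0))
                    values[f] = v
                dur_ref = params.baseline_mean.get("total_duration", {}).get("HC", 0.0)
                dur = values.get("total_duration", dur_ref)
                for f in feats:
                    ce = params.confounder_effects.get(f, {})
                    if f != "total_duration":
                        values[f] += ce.get("total_duration", 0.0) * (dur - dur_ref)
                    values[f] += ce.get("age", 0.0) * (age - params.age_mean)
                    values[f] += ce.get("medication", 0.0) * med
                if group == "HC":
                    # zero-inflated clinical gait rating in controls
                    updrs = 0.0 if rng.uniform() < 0.8 else float(rng.integers(1, 3))
                else:
                    updrs = float(np.round(params.updrs_loading * severity + rng.normal(0.0, 1.0)))
                row["updrs_gait"] = float(np.clip(updrs, 0.0, 20.0))
                row.update(values)
                rows.append(row)
    cols = ["subject_id", "group", "year", "age", "medication", "updrs_gait"] + feats
    return pd.DataFrame(rows, columns=cols)


def split_to_biannual_visits(
    annual: pd.DataFrame,
    visit_noise_sd: float = 0.0,
    p_single_miss: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand an annual cohort table into biannual visit rows (visit 1..2n).

    Each year-``y`` row becomes visits ``2y+1`` and ``2y+2`` whose feature
    values scatter around the annual value; single visits go missing with
    probability ``p_single_miss`` (never both, so annualisation over the
    remaining visit reproduces the year).  Used to exercise the annual
    averaging step.
    """
    rng = np.random.default_rng(seed)
    feats = [c for c in annual.columns if c in FEATURE_NAMES]
    rows = []
    for _, r in annual.iterrows():
        miss = rng.integers(0, 2) if rng.uniform() < p_single_miss else -1
        for half in (0, 1):
            if half == miss:
                continue
            row = r.to_dict()
            row["visit"] = int(2 * r["year"] + half + 1)
            for f in feats:
                row[f] = r[f] + rng.normal(0.0, visit_noise_sd)
            rows.append(row)
    out = pd.DataFrame(rows)
    return out.drop(columns=["year"])


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------

def write_trial_csv(path, trial: AccelTrial, onsets: np.ndarray | None = None) -> None:
    """Write a trial to CSV (`time_s,acc_vt,acc_ml,acc_ap`) with metadata
    comment lines; ground-truth onsets, when given, go to a sidecar file."""
    header = [
        f"# direction={trial.direction}",
        f"# medication={trial.medication}",
        f"# bounds={trial.trial_bounds[0]},{trial.trial_bounds[1]}",
    ]
    df = pd.DataFrame(
        {"time_s": trial.time, "acc_vt": trial.acc_vt, "acc_ml": trial.acc_ml, "acc_ap": trial.acc_ap}
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.9g")
    if onsets is not None:
        side = str(path).rsplit(".", 1)[0] + "_onsets.csv"
        pd.DataFrame({"onset_time_s": onsets}).to_csv(side, index=False, float_format="%.9g")


def write_cohort_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.9g")
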