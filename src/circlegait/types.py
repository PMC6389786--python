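"""Core containers shared across the pipeline.

The pipeline operates on three kinds of objects: a single walking trial
recorded by a tri-axial accelerometer on the lower back (:class:`AccelTrial`),
the step-cycle segmentation derived from it (:class:`StepSegmentation`), and
the per-visit vector of 24 gait characteristics (:class:`GaitFeatureVector`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

G = 9.81  # gravitational acceleration, m/s^2

SAMPLE_RATE = 100.0  # Hz, fixed by the recording device

#: The locked names of the 24 gait features, in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "n_steps",
    "total_duration",
    "step_time_asymmetry",
    "median_stride_time",
    "stride_time_variability",
    "sd_vt",
    "sd_ml",
    "sd_ap",
    "step_regularity_vt",
    "step_regularity_ap",
    "stride_regularity_vt",
    "stride_regularity_ap",
    "harmonic_ratio_vt",
    "harmonic_ratio_ml",
    "harmonic_ratio_ap",
    "index_harmonicity_vt",
    "index_harmonicity_ml",
    "index_harmonicity_ap",
    "norm_peak_power_vt",
    "norm_peak_power_ml",
    "norm_peak_power_ap",
    "width_peak_power_vt",
    "width_peak_power_ml",
    "width_peak_power_ap",
)

GROUPS: tuple[str, ...] = ("HC", "EarlyPD", "MidPD")

#: Cohort-table columns that precede the 24 feature columns.
COHORT_META_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "year",
    "age",
    "medication",
    "updrs_gait",
)


@dataclass
class AccelTrial:
    """One circular-walking trial: tri-axial acceleration at 100 Hz.

    Axes follow the body frame after realignment: VT (vertical, gravity
    pointing along +VT before offset removal), ML (medio-lateral) and AP
    (anterior-posterior).  ``trial_bounds`` delimits the walking portion as
    half-open sample indices ``[start, end)``; samples before ``start`` are
    the quiet-standing prefix used for realignment and offset removal.
    """

    time: np.ndarray
    acc_vt: np.ndarray
    acc_ml: np.ndarray
    acc_ap: np.ndarray
    direction: str = "clockwise"  # or "counter_clockwise"
    medication: str = "NA"  # "ON", "OFF" or "NA"
    trial_bounds: tuple[int, int] = (0, 0)
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc_vt = np.asarray(self.acc_vt, dtype=float)
        self.acc_ml = np.asarray(self.acc_ml, dtype=float)
        self.acc_ap = np.asarray(self.acc_ap, dtype=float)
        n = self.time.size
        if not (self.acc_vt.size == self.acc_ml.size == self.acc_ap.size == n):
            raise ValueError("time and acceleration series must have equal length")
        if n < 100:
            raise ValueError(f"trial too short: {n} samples (< 100)")
        dt = np.diff(self.time)
        if dt.size and (np.abs(dt - 1.0 / self.sample_rate) > 1e-6).any():
            raise ValueError("timestamps are not uniform at the stated sample rate")
        start, end = self.trial_bounds
        if self.trial_bounds == (0, 0):
            self.trial_bounds = (0, n)
        elif not (0 <= start < end <= n):
            raise ValueError(f"trial_bounds {self.trial_bounds} outside series of length {n}")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def axes(self) -> np.ndarray:
        """Stack the three axes as an (n, 3) array ordered VT, ML, AP."""
        return np.column_stack([self.acc_vt, self.acc_ml, self.acc_ap])

    def walking(self, axis: str) -> np.ndarray:
        """Return one axis restricted to the walking portion."""
        start, end = self.trial_bounds
        return getattr(self, f"acc_{axis}")[start:end]

    def with_axes(self, vt: np.ndarray, ml: np.ndarray, ap: np.ndarray) -> "AccelTrial":
        return replace(self, acc_vt=vt, acc_ml=ml, acc_ap=ap)


@dataclass
class StepSegmentation:
    """Step onsets detected on the AP axis and the durations they imply.

    ``stride_durations`` are differences between alternate onsets (two
    accumulated steps), pooled over even- and odd-indexed starting onsets.
    """

    step_onsets: np.ndarray  # sample indices, strictly increasing
    sample_rate: float = SAMPLE_RATE
    failed: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        self.step_onsets = np.asarray(self.step_onsets, dtype=int)
        if self.step_onsets.size and (np.diff(self.step_onsets) <= 0).any():
            raise ValueError("step onsets must be strictly increasing")

    @property
    def onset_times(self) -> np.ndarray:
        return self.step_onsets / self.sample_rate

    @property
    def step_durations(self) -> np.ndarray:
        return np.diff(self.step_onsets) / self.sample_rate

    @property
    def stride_durations(self) -> np.ndarray:
        o = self.step_onsets
        if o.size < 3:
            return np.empty(0)
        return (o[2:] - o[:-2]) / self.sample_rate

    @property
    def n_steps(self) -> int:
        return max(self.step_onsets.size - 1, 0)

    @property
    def plausible(self) -> bool:
        """True when every step duration lies in the physiological band."""
        d = self.step_durations
        return bool(d.size) and bool(((d > 0.2) & (d < 2.0)).all())


@dataclass
class GaitFeatureVector:
    """The 24 gait characteristics of one visit, with per-feature quality flags."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature vector must carry exactly the 24 locked names; missing={sorted(missing)}, extra={sorted(extra)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray, flags: dict[str, str] | None = None) -> "GaitFeatureVector":
        return cls(dict(zip(FEATURE_NAMES, map(float, arr))), flags or {})
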