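"""Pipeline configuration: every tunable in one flat, validated namespace.

Defaults follow the fixed analysis settings: 900-sample Hanning window with
50% overlap and a 9000-point FFT for spectral features, per-criterion alpha
0.10, confounder alpha 0.05, years coded 0-4.  The YAML form round-trips
exactly and unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # cohort scale
    n_per_group: dict[str, int] = field(default_factory=lambda: {"HC": 25, "EarlyPD": 22, "MidPD": 27})
    n_years: int = 5
    p_on_medication: float = 0.164
    retention_by_year: list[float] = field(default_factory=lambda: [1.0, 0.823, 0.770, 0.635, 0.514])
    # signal generation
    n_strides: int = 18
    mean_stride_time: float = 1.05
    stride_time_sd: float = 0.02
    noise_sd: float = 0.15
    standing_duration: float = 2.0
    tilt_deg: float = 0.0
    # spectral settings
    welch_window: int = 900
    welch_overlap: float = 0.5
    welch_nfft: int = 9000
    # segmentation
    ncc_threshold: float = 0.3
    max_template_iter: int = 5
    # statistics
    alpha_criterion: float = 0.10
    alpha_confounder: float = 0.05
    skew_threshold: float = 1.0
    trim_fraction: float = 0.05
    candidate_confounders: list[str] = field(default_factory=lambda: ["total_duration", "age", "medication"])

    def validate(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not 0 < self.alpha_criterion < 1 or not 0 < self.alpha_confounder < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.welch_window < 2 or self.welch_nfft < self.welch_window:
            raise ValueError("invalid Welch settings")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
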