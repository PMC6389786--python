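"""Multi-criterion screening of gait features as progression markers.

A feature qualifies as an early-stage marker when it meets four conjunctive
criteria, each at a per-criterion alpha of 0.10 with a direction gate:

* E1 - the Group x Time interaction of the early-PD vs HC model shows a
  faster decline of gait quality in early PD;
* E2 - the early-PD group's annual change (percent of first-year mean) is
  significant and in the worsening direction;
* E3 - the feature is associated with the clinical gait rating
  (gait-UPDRS III) in the worsening direction;
* E4 - the mid-PD vs HC model shows a baseline Group difference in the
  worsening direction (a symptom progressing early should still be present,
  possibly at ceiling, in the middle stage).

Middle-stage markers must meet the three analogous criteria M1-M3 (there is
no M-analogue of E4 because no more advanced group exists).  With
independent criteria the implied per-feature alpha is 0.10^4 = 1e-4 (early)
and 0.10^3 = 1e-3 (mid); criteria computed on the same data are positively
dependent, so these bounds are conservative.  For context, a Bonferroni
correction over the 24 features at family-wise 0.05 would demand ~0.002.

Direction gates use two-sided p-values plus a sign check, equivalent to a
one-sided test at half the nominal level.  The expected worsening direction
of each feature is shipped as data (:data:`DEFAULT_DIRECTIONS`) so the
clinical convention is auditable and overridable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .longitudinal import (
    AnnualChange,
    GeeFit,
    apply_transforms,
    fit_progression_gee,
    percent_annual_change,
    regress_on_updrs,
)
from .types import FEATURE_NAMES

__all__ = [
    "DEFAULT_DIRECTIONS",
    "CriterionOutcome",
    "MarkerReport",
    "FeatureModelBundle",
    "fit_feature_models",
    "evaluate_early_criteria",
    "evaluate_mid_criteria",
    "combined_alpha",
    "bonferroni_alpha",
    "compile_marker_report",
    "read_marker_report",
    "screen_cohort",
]

CRITERION_ALPHA = 0.10

#: Worsening direction per feature: "increase" means larger values reflect
#: worse gait (more steps, longer trials, more asymmetry/variability, more
#: frequency dispersion, higher index of harmonicity); "decrease" means
#: smaller values do (slower cadence-adjusted stride time, less movement
#: intensity, lower regularity, lower harmonic ratios, weaker dominant peak).
DEFAULT_DIRECTIONS: dict[str, str] = {
    "n_steps": "increase",
    "total_duration": "increase",
    "step_time_asymmetry": "increase",
    "median_stride_time": "decrease",
    "stride_time_variability": "increase",
    "sd_vt": "decrease",
    "sd_ml": "decrease",
    "sd_ap": "decrease",
    "step_regularity_vt": "decrease",
    "step_regularity_ap": "decrease",
    "stride_regularity_vt": "decrease",
    "stride_regularity_ap": "decrease",
    "harmonic_ratio_vt": "decrease",
    "harmonic_ratio_ml": "decrease",
    "harmonic_ratio_ap": "decrease",
    "index_harmonicity_vt": "increase",
    "index_harmonicity_ml": "increase",
    "index_harmonicity_ap": "increase",
    "norm_peak_power_vt": "decrease",
    "norm_peak_power_ml": "decrease",
    "norm_peak_power_ap": "decrease",
    "width_peak_power_vt": "increase",
    "width_peak_power_ml": "increase",
    "width_peak_power_ap": "increase",
}


@dataclass
class CriterionOutcome:
    """Outcome of one criterion for one feature."""

    criterion: str  # E1..E4 or M1..M3
    feature: str
    estimate: float
    p: float
    direction_ok: bool
    met: bool


@dataclass
class MarkerReport:
    """Per-feature criterion outcomes and the final marker flags."""

    early: dict[str, list[CriterionOutcome]] = field(default_factory=dict)
    mid: dict[str, list[CriterionOutcome]] = field(default_factory=dict)
    early_markers: list[str] = field(default_factory=list)
    mid_markers: list[str] = field(default_factory=list)
    combined_alpha_early: float = 0.0
    combined_alpha_mid: float = 0.0
    bonferroni_reference: float = 0.0
    gaps: list[str] = field(default_factory=list)
    updrs_reference: dict[str, float] = field(default_factory=dict)


def combined_alpha(n_criteria: int, per_criterion_alpha: float = CRITERION_ALPHA) -> float:
    """Joint false-positive level of n independent criteria each at alpha."""
    if n_criteria < 1:
        raise ValueError("need at least one criterion")
    if not 0.0 < per_criterion_alpha < 1.0:
        raise ValueError("per-criterion alpha must lie in (0, 1)")
    return per_criterion_alpha**n_criteria


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test level of a Bonferroni correction at the given family level."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return family_alpha / n_tests


def _sign_matches(estimate: float, direction: str) -> bool:
    return estimate > 0 if direction == "increase" else estimate < 0


def _outcome(criterion: str, feature: str, estimate: float, p: float,
             direction: str, alpha: float, sign_value: float | None = None) -> CriterionOutcome:
    """``sign_value`` overrides the quantity whose sign is gated (used for
    annual change, where the reported percent divides by a baseline whose own
    sign would otherwise cancel out of the check)."""
    estimate, p = float(estimate), float(p)
    gate = estimate if sign_value is None else float(sign_value)
    ok = bool(np.isfinite(gate) and _sign_matches(gate, direction))
    met = bool(np.isfinite(p) and p < alpha and ok)
    return CriterionOutcome(criterion, feature, estimate, p, ok, met)


@dataclass
class FeatureModelBundle:
    """All fitted models needed to judge one feature against the criteria."""

    feature: str
    early_fit: GeeFit | None = None  # early-PD vs HC progression model
    mid_fit: GeeFit | None = None  # mid-PD vs HC progression model
    early_change: AnnualChange | None = None
    mid_change: AnnualChange | None = None
    updrs_fit: GeeFit | None = None

    def complete_for_early(self) -> bool:
        return None not in (self.early_fit, self.early_change, self.updrs_fit, self.mid_fit)

    def complete_for_mid(self) -> bool:
        return None not in (self.mid_fit, self.mid_change, self.updrs_fit)


def fit_feature_models(table: pd.DataFrame, features: list[str] | None = None,
                       alpha_confounder: float = 0.05,
                       skew_threshold: float = 1.0,
                       reselect_change_confounders: bool = False) -> dict[str, FeatureModelBundle]:
    """Fit every model the screening criteria need, for every feature.

    ``table`` is the annualised raw cohort table.  Transforms are applied
    per comparison (over the two groups entering each model) with the raw
    trial duration retained as the gait-speed confounder.  Annual-change
    models run on raw data within each PD group, reusing the confounders
    retained by the corresponding two-group model (re-selection is
    available as an option).
    """
    feats = list(features) if features is not None else [f for f in FEATURE_NAMES if f in table.columns]
    bundles = {f: FeatureModelBundle(f) for f in feats}

    def _transformed(sub: pd.DataFrame) -> pd.DataFrame:
        zt, _ = apply_transforms(sub, feats, skew_threshold=skew_threshold)
        if "total_duration" in zt.columns:
            dur_z = zt["total_duration"].copy()
            zt["total_duration"] = sub["total_duration"]  # raw, for confounding
            zt["_duration_z"] = dur_z
        return zt

    for comparison, fit_attr, change_attr, group in (
        ("early", "early_fit", "early_change", "EarlyPD"),
        ("mid", "mid_fit", "mid_change", "MidPD"),
    ):
        pd_group = {"early": "EarlyPD", "mid": "MidPD"}[comparison]
        sub = table[table["group"].isin(["HC", pd_group])]
        if sub["group"].nunique() < 2:
            continue
        zt = _transformed(sub)
        for f in feats:
            frame = zt
            if f == "total_duration" and "_duration_z" in zt.columns:
                frame = zt.copy()
                frame["total_duration"] = zt["_duration_z"]
            try:
                fit = fit_progression_gee(frame, comparison, f, alpha=alpha_confounder)
            except ValueError:
                fit = None
            setattr(bundles[f], fit_attr, fit)
            try:
                conf = () if (fit is None or reselect_change_confounders) else fit.retained_confounders
                change = percent_annual_change(table, group, f, confounders=conf,
                                               alpha=alpha_confounder)
            except ValueError:
                change = None
            setattr(bundles[f], change_attr, change)

    zt_all = _transformed(table)
    for f in feats:
        frame = zt_all
        if f == "total_duration" and "_duration_z" in zt_all.columns:
            frame = zt_all.copy()
            frame["total_duration"] = zt_all["_duration_z"]
        try:
            bundles[f].updrs_fit = regress_on_updrs(frame, f, alpha=alpha_confounder)
        except ValueError:
            bundles[f].updrs_fit = None
    return bundles


def evaluate_early_criteria(bundles: dict[str, FeatureModelBundle],
                            directions: dict[str, str] | None = None,
                            alpha: float = CRITERION_ALPHA) -> dict[str, list[CriterionOutcome]]:
    """Judge each feature against E1-E4; features with missing fits are skipped."""
    directions = directions or DEFAULT_DIRECTIONS
    out: dict[str, list[CriterionOutcome]] = {}
    for f, b in bundles.items():
        if not b.complete_for_early():
            continue
        d = directions[f]
        e1_est, _, e1_p = b.early_fit.term("group_time")
        e4_est, _, e4_p = b.mid_fit.term("group_ind")
        out[f] = [
            _outcome("E1", f, e1_est, e1_p, d, alpha),
            _outcome("E2", f, b.early_change.percent_per_year, b.early_change.p_value, d, alpha,
                     sign_value=b.early_change.coefficient),
            _outcome("E3", f, *b.updrs_fit.term("updrs_gait")[0::2], d, alpha),
            _outcome("E4", f, e4_est, e4_p, d, alpha),
        ]
    return out


def evaluate_mid_criteria(bundles: dict[str, FeatureModelBundle],
                          directions: dict[str, str] | None = None,
                          alpha: float = CRITERION_ALPHA) -> dict[str, list[CriterionOutcome]]:
    """Judge each feature against M1-M3."""
    directions = directions or DEFAULT_DIRECTIONS
    out: dict[str, list[CriterionOutcome]] = {}
    for f, b in bundles.items():
        if not b.complete_for_mid():
            continue
        d = directions[f]
        m1_est, _, m1_p = b.mid_fit.term("group_time")
        out[f] = [
            _outcome("M1", f, m1_est, m1_p, d, alpha),
            _outcome("M2", f, b.mid_change.percent_per_year, b.mid_change.p_value, d, alpha,
                     sign_value=b.mid_change.coefficient),
            _outcome("M3", f, *b.updrs_fit.term("updrs_gait")[0::2], d, alpha),
        ]
    return out


def compile_marker_report(early: dict[str, list[CriterionOutcome]],
                          mid: dict[str, list[CriterionOutcome]],
                          expected_features: tuple[str, ...] = FEATURE_NAMES,
                          per_criterion_alpha: float = CRITERION_ALPHA,
                          updrs_reference: dict[str, float] | None = None) -> MarkerReport:
    """Assemble the machine-readable marker report.

    Features with missing outcomes are listed under ``gaps`` rather than
    silently dropped.  A feature is a marker for a stage when all of that
    stage's criteria are met.
    """
    gaps = sorted(set(expected_features) - set(early)) + sorted(set(expected_features) - set(mid))
    report = MarkerReport(
        early=early,
        mid=mid,
        early_markers=sorted(f for f, ocs in early.items() if all(o.met for o in ocs)),
        mid_markers=sorted(f for f, ocs in mid.items() if all(o.met for o in ocs)),
        combined_alpha_early=combined_alpha(4, per_criterion_alpha),
        combined_alpha_mid=combined_alpha(3, per_criterion_alpha),
        bonferroni_reference=bonferroni_alpha(len(expected_features)),
        gaps=sorted(set(gaps)),
        updrs_reference=updrs_reference or {},
    )
    return report


def report_to_json(report: MarkerReport) -> str:
    return json.dumps(asdict(report), indent=2, sort_keys=True)


def read_marker_report(text: str) -> MarkerReport:
    """Inverse of :func:`report_to_json`."""
    raw = json.loads(text)
    for stage in ("early", "mid"):
        raw[stage] = {
            f: [CriterionOutcome(**o) for o in ocs] for f, ocs in raw[stage].items()
        }
    return MarkerReport(**raw)


def report_summary_table(report: MarkerReport) -> str:
    """Plain-text summary, one line per feature per stage."""
    lines = [f"{'feature':28s} {'stage':6s} {'criteria':24s} marker"]
    for stage, outcomes, markers in (("early", report.early, report.early_markers),
                                     ("mid", report.mid, report.mid_markers)):
        for f in sorted(outcomes):
            cs = " ".join(f"{o.criterion}:{'+' if o.met else '-'}" for o in outcomes[f])
            lines.append(f"{f:28s} {stage:6s} {cs:24s} {'*' if f in markers else ''}")
    if report.gaps:
        lines.append("missing outcomes: " + ", ".join(report.gaps))
    return "\n".join(lines)


def screen_cohort(table: pd.DataFrame, features: list[str] | None = None,
                  directions: dict[str, str] | None = None,
                  alpha: float = CRITERION_ALPHA,
                  alpha_confounder: float = 0.05,
                  skew_threshold: float = 1.0) -> MarkerReport:
    """End-to-end screen: fit all models on an annualised cohort table and
    compile the marker report."""
    feats = list(features) if features is not None else [f for f in FEATURE_NAMES if f in table.columns]
    bundles = fit_feature_models(table, feats, alpha_confounder=alpha_confounder,
                                 skew_threshold=skew_threshold)
    early = evaluate_early_criteria(bundles, directions, alpha)
    mid = evaluate_mid_criteria(bundles, directions, alpha)
    updrs_ref = {}
    try:
        ref = fit_progression_gee(table, "early", "updrs_gait", alpha=alpha_confounder)
        updrs_ref["early_group_time"] = ref.params["group_time"]
    except (ValueError, KeyError):
        pass
    return compile_marker_report(early, mid, tuple(feats), alpha, updrs_ref)
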