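"""Longitudinal modelling: annualisation, transforms and GEE progression fits.

The cohort design is up to ten biannual visits per subject over five years.
Analysis proceeds in four steps:

1. :func:`annualize` averages the two visits of each year (a single missed
   visit leaves the remaining one as that year's value).
2. :func:`apply_transforms` log-transforms skewed features (with a
   positivity offset when needed) and z-scores each feature using the
   between-subject SD over the groups entering the comparison, so model
   coefficients are comparable across features.
3. :func:`fit_progression_gee` fits an identity-link, normal-family GEE
   with exchangeable working correlation and robust (sandwich) errors on
   Group, Time (years, baseline = 0) and Group x Time, with backward
   elimination of non-significant confounders (trial duration as a gait
   speed proxy, age, medication state).
4. :func:`percent_annual_change` re-fits Time within one group on the raw
   scale and scales the coefficient by the group's first-year mean;
   :func:`regress_on_updrs` regresses each transformed feature on the
   clinical gait rating over the pooled groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.tools.sm_exceptions import IterationLimitWarning
from statsmodels.genmod.generalized_estimating_equations import GEE

__all__ = [
    "TransformSpec",
    "GeeFit",
    "AnnualChange",
    "annualize",
    "apply_transforms",
    "fit_progression_gee",
    "percent_annual_change",
    "regress_on_updrs",
]

CONFOUNDER_ALPHA = 0.05
#: Fixed candidate order; ties in elimination drop the later candidate.
CONFOUNDER_ORDER = ("total_duration", "age", "medication")
#: Outcomes for which gait speed (total_duration) is not a valid confounder.
SPEED_EXEMPT_OUTCOMES = ("total_duration", "updrs_gait")
SKEWNESS_THRESHOLD = 1.0


@dataclass
class TransformSpec:
    """Per-feature record of the log/z transform actually applied."""

    log_applied: dict[str, bool] = field(default_factory=dict)
    log_offset: dict[str, float] = field(default_factory=dict)
    z_mean: dict[str, float] = field(default_factory=dict)
    z_sd: dict[str, float] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


@dataclass
class GeeFit:
    """Coefficients, robust errors and p-values of one GEE fit."""

    outcome: str
    params: dict[str, float]
    robust_se: dict[str, float]
    pvalues: dict[str, float]
    retained_confounders: tuple[str, ...]
    working_corr: float
    n_subjects: int
    n_obs: int
    converged: bool = True

    def term(self, name: str) -> tuple[float, float, float]:
        return self.params[name], self.robust_se[name], self.pvalues[name]


@dataclass
class AnnualChange:
    """Within-group annual change as a percentage of the first-year mean."""

    feature: str
    group: str
    percent_per_year: float
    se_percent: float
    p_value: float
    coefficient: float = 0.0  # raw Time coefficient (feature units / year)


def annualize(visits: pd.DataFrame, value_columns: list[str] | None = None) -> pd.DataFrame:
    """Average biannual visits into annual records.

    ``visits`` must carry ``subject_id`` and ``visit`` (1..10); visits 2y+1
    and 2y+2 form year y.  With a single missed visit the remaining value
    stands for the year; a year with no visits yields no row.  Duplicate
    visit numbers within a subject are an error.  Already-annual data (one
    visit per bucket) passes through unchanged, so the operation is
    idempotent.
    """
    if visits.duplicated(subset=["subject_id", "visit"]).any():
        raise ValueError("duplicate visit numbers within a subject")
    df = visits.copy()
    df["year"] = (df["visit"].astype(int) - 1) // 2
    if value_columns is None:
        value_columns = [c for c in df.columns
                         if c not in ("subject_id", "visit", "year", "group") and pd.api.types.is_numeric_dtype(df[c])]
    keys = ["subject_id", "year"]
    meta = [c for c in df.columns if c not in value_columns + keys + ["visit"]]
    agg = {c: "mean" for c in value_columns}
    agg.update({c: "first" for c in meta})
    out = df.groupby(keys, as_index=False, sort=True).agg(agg)
    ordered = ["subject_id", "year"] + [c for c in visits.columns if c in out.columns and c not in ("subject_id", "visit", "year")]
    return out[ordered]


def between_subject_sd(values: pd.Series, subjects: pd.Series) -> float:
    """SD of per-subject mean values (the between-subject spread estimator)."""
    means = values.groupby(subjects.values).mean()
    return float(means.std(ddof=1))


def apply_transforms(table: pd.DataFrame, features: list[str],
                     skew_threshold: float = SKEWNESS_THRESHOLD) -> tuple[pd.DataFrame, TransformSpec]:
    """Log-transform skewed features, then z-score on the between-subject scale.

    A feature is log-transformed when its pooled skewness exceeds
    ``skew_threshold``; an offset ``1 - min(x)`` enforces strict positivity
    when the minimum is non-positive.  Centring uses the mean of per-subject
    means and scaling the SD of per-subject means over all rows given (the
    caller subsets to the two groups entering a comparison).  A feature with
    zero between-subject variance is left untouched and recorded as skipped.
    """
    if table.empty:
        raise ValueError("cannot transform an empty table")
    out = table.copy()
    spec = TransformSpec()
    for f in features:
        x = out[f].astype(float)
        if x.isna().all():
            spec.skipped[f] = "all values missing"
            continue
        skew = float(stats.skew(x.dropna()))
        apply_log = skew > skew_threshold
        offset = 0.0
        if apply_log:
            mn = float(x.min())
            offset = 1.0 - mn if mn <= 0 else 0.0
            x = np.log(x + offset)
        mu = float(x.groupby(out["subject_id"].values).mean().mean())
        sd = between_subject_sd(x, out["subject_id"])
        if not np.isfinite(sd) or sd <= 0:
            spec.skipped[f] = "zero between-subject variance"
            continue
        out[f] = (x - mu) / sd
        spec.log_applied[f] = apply_log
        spec.log_offset[f] = offset
        spec.z_mean[f] = mu
        spec.z_sd[f] = sd
    return out, spec


class _BoundedExchangeable(Exchangeable):
    """Exchangeable working correlation with the moment estimate clipped
    below 1: strong between-subject heterogeneity can push the raw estimate
    past 1, which makes the working covariance indefinite and corrupts the
    coefficients."""

    def update(self, params) -> None:
        super().update(params)
        self.dep_params = float(np.clip(self.dep_params, -0.95, 0.95))


def _fit_gee(data: pd.DataFrame, outcome: str, terms: list[str],
             exchangeable: bool = True) -> tuple[GeeFit, object]:
    design = sm.add_constant(data[terms].astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        raise ValueError(f"singular design for outcome {outcome!r} with terms {terms}")
    cov = _BoundedExchangeable() if exchangeable else Independence()
    model = GEE(data[outcome].astype(float), design, groups=data["subject_id"],
                family=sm.families.Gaussian(), cov_struct=cov)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(cov_type="bias_reduced")
    for w in caught:
        if issubclass(w.category, IterationLimitWarning):
            converged = False
    # Mancl-DeRouen bias-reduced sandwich with a t reference on
    # (clusters - parameters) df: plain sandwich errors are anti-conservative
    # with cohort-sized cluster counts
    se = pd.Series(np.asarray(res.standard_errors(cov_type="bias_reduced")),
                   index=res.params.index)
    df_t = max(int(data["subject_id"].nunique()) - design.shape[1], 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2.0 * stats.t.sf(np.abs(res.params / se), df_t)
    dep = cov.dep_params
    fit = GeeFit(
        outcome=outcome,
        params=dict(res.params),
        robust_se=dict(se),
        pvalues=dict(pd.Series(pvals, index=res.params.index)),
        retained_confounders=(),
        working_corr=float(np.atleast_1d(dep)[0]) if dep is not None and np.size(dep) else 0.0,
        n_subjects=int(data["subject_id"].nunique()),
        n_obs=int(len(data)),
        converged=converged,
    )
    return fit, res


def _eliminate_confounders(data: pd.DataFrame, outcome: str, base_terms: list[str],
                           candidates: list[str], alpha: float = CONFOUNDER_ALPHA,
                           exchangeable: bool = True) -> GeeFit:
    """Backward elimination: drop the least-significant confounder until all
    retained ones are significant.  Ties break by dropping the later
    candidate in the fixed order."""
    kept = [c for c in CONFOUNDER_ORDER if c in candidates]
    while True:
        fit, _ = _fit_gee(data, outcome, base_terms + kept, exchangeable)
        if not kept:
            fit.retained_confounders = ()
            return fit
        pvals = [(fit.pvalues[c], i) for i, c in enumerate(kept)]
        worst_p = max(p for p, _ in pvals)
        if worst_p < alpha:
            fit.retained_confounders = tuple(kept)
            return fit
        worst_idx = max(i for p, i in pvals if p == worst_p)
        kept.pop(worst_idx)


def _comparison_subset(table: pd.DataFrame, comparison: str) -> pd.DataFrame:
    pd_group = {"early": "EarlyPD", "mid": "MidPD"}[comparison]
    sub = table[table["group"].isin(["HC", pd_group])].copy()
    if sub["group"].nunique() < 2:
        raise ValueError(f"both groups must be present for the {comparison} comparison")
    sub["group_ind"] = (sub["group"] == pd_group).astype(float)
    sub["group_time"] = sub["group_ind"] * sub["year"].astype(float)
    return sub


def fit_progression_gee(table: pd.DataFrame, comparison: str, outcome: str,
                        alpha: float = CONFOUNDER_ALPHA,
                        exchangeable: bool = True) -> GeeFit:
    """Two-group progression GEE: Group + Time + Group x Time + confounders.

    ``comparison`` is ``"early"`` (early-PD vs HC) or ``"mid"`` (mid-PD vs
    HC); the PD group is coded 1, HC 0, and Time runs in years from 0.
    Candidate confounders are trial duration, age and medication, except
    that trial duration is excluded when it (or a clinical rating) is itself
    the outcome.  Robust sandwich errors throughout.
    """
    sub = _comparison_subset(table, comparison)
    sub = sub.rename(columns={"year": "time"})
    candidates = [c for c in CONFOUNDER_ORDER if c != outcome]
    if outcome in SPEED_EXEMPT_OUTCOMES:
        candidates = [c for c in candidates if c != "total_duration"]
    candidates = [c for c in candidates if c in sub.columns]
    sub = sub.dropna(subset=[outcome])
    fit = _eliminate_confounders(sub, outcome, ["group_ind", "time", "group_time"],
                                 candidates, alpha, exchangeable)
    return fit


def percent_annual_change(table: pd.DataFrame, group: str, feature: str,
                          confounders: tuple[str, ...] = (),
                          alpha: float = CONFOUNDER_ALPHA) -> AnnualChange:
    """Annual change of the raw (untransformed) feature within one group.

    The Time coefficient and its robust SE from a within-group GEE
    (including the confounders retained by the preceding two-group model)
    are divided by the mean first-year value of the group, times 100.
    """
    sub = table[table["group"] == group].copy().rename(columns={"year": "time"})
    sub = sub.dropna(subset=[feature])
    base_mean = float(sub.loc[sub["time"] == 0, feature].mean())
    if not np.isfinite(base_mean) or base_mean == 0.0:
        raise ValueError(f"first-year mean of {feature!r} in {group} is zero or undefined")
    kept = [c for c in confounders if c in sub.columns and c != feature
            and sub[c].astype(float).nunique() > 1]
    try:
        fit, _ = _fit_gee(sub, feature, ["time"] + kept)
        coef, se, p = fit.term("time")
    except ValueError:
        coef = float("nan")
    if not np.isfinite(coef):
        # zero residual variance (noise-free trajectories) breaks the GEE
        # scale estimate; the slope is then known exactly from least squares
        X = np.column_stack([np.ones(len(sub))] + [sub[c].astype(float) for c in ["time"] + kept])
        beta, *_ = np.linalg.lstsq(X, sub[feature].astype(float).values, rcond=None)
        coef, se, p = float(beta[1]), 0.0, float("nan")
    if se == 0.0 or not np.isfinite(p):
        # degenerate fit: the slope is exact, so the test is decisive
        p = 1.0 if abs(coef) < 1e-12 else 0.0
    return AnnualChange(feature, group, coef / base_mean * 100.0,
                        abs(se / base_mean) * 100.0, p, float(coef))


def regress_on_updrs(table: pd.DataFrame, feature: str,
                     alpha: float = CONFOUNDER_ALPHA) -> GeeFit:
    """GEE of a transformed feature on the clinical gait rating (pooled groups),
    with the same confounder elimination as the progression models."""
    sub = table.dropna(subset=[feature, "updrs_gait"]).copy()
    if sub["updrs_gait"].astype(float).nunique() < 2:
        raise ValueError("constant clinical rating: singular design")
    candidates = [c for c in CONFOUNDER_ORDER if c in sub.columns and c != feature]
    fit = _eliminate_confounders(sub, feature, ["updrs_gait"], candidates, alpha)
    return fit
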