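"""Per-dataset univariate models and effect-size conversion.

Each case-control dataset is analyzed separately with ordinary least
squares: the primary model regresses a regional asymmetry index on
diagnosis (control=0, case=1) with sex and age as covariates, plus n-1
scanner dummy covariates in multi-scanner datasets.  The diagnosis
t-statistic is converted to a Cohen's d with standard error and 95% CI:

    d    = t (n1 + n2) / (sqrt(n1 n2) sqrt(df))
    se_d = sqrt( ((n1+n2-1)/(n1+n2-3)) * (4/(n1+n2)) * (1 + d^2/8) )
    CI95 = d -/+ 1.96 se_d

with n1 controls, n2 cases and df the residual degrees of freedom.  A
dataset is skipped for a given model when its total usable sample is
below ten plus the number of scanner dummies, or when either diagnostic
group has fewer than five individuals.  Collinearity is screened by
variance inflation factors; VIF > 5 flags (but does not drop) a fit.

Model variants follow the sensitivity/secondary scheme: handedness
and/or intracranial volume or squared (centered) age as extra covariates,
a case-only medication-class contrast, diagnosis-by-age and
diagnosis-by-sex interaction models, and post-hoc unilateral fits of the
same model on the left and right measures separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "ModelSpec",
    "SiteEffect",
    "MODEL_IDS",
    "check_eligibility",
    "compute_vif",
    "t_to_cohens_d",
    "d_standard_error",
    "ci95",
    "fit_site_model",
    "fit_all_sites",
    "SITE_SUMMARY_COLUMNS",
]

MODEL_IDS = (
    "m1",
    "m2_hand",
    "m3_icv",
    "m4_hand_icv",
    "m5_age2",
    "m6_medication",
    "m8_dx_by_age",
    "m9_dx_by_sex",
    "unilateral_posthoc",
)

_EXTRA_COVARIATES = {
    "m1": [],
    "m2_hand": ["handedness"],
    "m3_icv": ["icv"],
    "m4_hand_icv": ["handedness", "icv"],
    "m5_age2": ["age2"],
    "m8_dx_by_age": [],
    "m9_dx_by_sex": [],
    "unilateral_posthoc": [],
}

SITE_SUMMARY_COLUMNS = [
    "dataset_id",
    "measure_id",
    "model_id",
    "t",
    "df",
    "n1",
    "n2",
    "d",
    "se_d",
    "ci_low",
    "ci_high",
    "max_vif",
    "vif_flag",
    "skipped",
    "skip_reason",
]


@dataclass(frozen=True)
class ModelSpec:
    """A univariate model: which response, which covariates, which term.

    ``response`` is an AI column, or an ``_L``/``_R`` column for the
    unilateral post-hoc model.  The term of interest is ``diagnosis``
    except for interaction models (the interaction term) and the
    medication model (first- vs second-generation contrast among cases).
    """

    model_id: str
    response: str
    min_total_base: int = 10
    min_group: int = 5
    vif_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")


@dataclass
class SiteEffect:
    """Diagnosis (or contrast) effect of one model in one dataset."""

    dataset_id: str
    measure_id: str
    model_id: str
    t: float = math.nan
    df: float = math.nan
    n1: int = 0
    n2: int = 0
    d: float = math.nan
    se_d: float = math.nan
    ci95: tuple[float, float] = (math.nan, math.nan)
    max_vif: float = math.nan
    vif_flag: bool = False
    skipped: bool = False
    skip_reason: str = ""
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "measure_id": self.measure_id,
            "model_id": self.model_id,
            "t": self.t,
            "df": self.df,
            "n1": self.n1,
            "n2": self.n2,
            "d": self.d,
            "se_d": self.se_d,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "max_vif": self.max_vif,
            "vif_flag": self.vif_flag,
            "skipped": self.skipped,
            "skip_reason": self.skip_reason,
        }


def check_eligibility(
    n1: int, n2: int, n_scanner_dummies: int, min_total_base: int = 10, min_group: int = 5
) -> tuple[bool, str]:
    """Dataset eligibility for one model fit.

    Skip when total N is below ``min_total_base`` plus the number of
    scanner dummy covariates, or when either diagnostic group is smaller
    than ``min_group``.  Returns ``(passed, reason)``; skipping is a
    value, not an error.
    """
    total = n1 + n2
    if min(n1, n2) < min_group:
        return False, f"group size {min(n1, n2)} < {min_group}"
    if total < min_total_base + n_scanner_dummies:
        return False, (
            f"total N {total} < {min_total_base} + {n_scanner_dummies} scanner dummies"
        )
    return True, ""


def compute_vif(design: np.ndarray) -> np.ndarray:
    """Variance inflation factors for the non-intercept design columns.

    VIF_j = 1/(1 - R^2_j) from regressing column j on the remaining
    columns (with intercept).  A perfectly collinear column yields +inf.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("design must be a 2-D matrix with at least one column")
    Xi = np.column_stack([np.ones(X.shape[0]), X])
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        with np.errstate(divide="ignore", invalid="ignore"):
            v = variance_inflation_factor(Xi, j + 1)
        out[j] = np.inf if (not np.isfinite(v) or v < 0) else v
    return out


def t_to_cohens_d(t: float, n1: int, n2: int, df: float) -> float:
    """Cohen's d from a regression t-statistic.

    With diagnosis coded control=0/case=1, negative d means lower AI
    (less leftward / more rightward asymmetry) in cases.
    """
    if df <= 0 or n1 <= 0 or n2 <= 0:
        raise ValueError("t_to_cohens_d requires positive group sizes and df")
    return t * (n1 + n2) / (math.sqrt(n1 * n2) * math.sqrt(df))


def d_standard_error(d: float, n1: int, n2: int) -> float:
    """Standard error of Cohen's d."""
    n = n1 + n2
    if n <= 3:
        raise ValueError("d_standard_error requires n1 + n2 > 3")
    return math.sqrt(((n - 1) / (n - 3)) * (4.0 / n) * (1.0 + d * d / 8.0))


def ci95(d: float, se_d: float) -> tuple[float, float]:
    return (d - 1.96 * se_d, d + 1.96 * se_d)


def _scanner_dummies(scanner: pd.Series) -> pd.DataFrame:
    """n-1 binary dummies; reference level = lexicographically first id."""
    levels = sorted(scanner.astype(str).unique())
    cols = {}
    for lev in levels[1:]:
        cols[f"scanner[{lev}]"] = (scanner.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=scanner.index)


def _design_for_model(rows: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, str] | str:
    """Build the (non-intercept) design frame; returns an error string on failure."""
    model_id = spec.model_id
    if model_id == "m6_medication":
        rows = rows[rows["diagnosis"] == 1]
        med = rows["medication_class"].astype("string")
        rows = rows[med.notna() & (med != "unknown")]
        if rows.empty:
            return "no medication data"
        med = rows["medication_class"].astype(str)
        X = pd.DataFrame(index=rows.index)
        # second_gen is the reference; the first_gen dummy is the contrast
        for lev in ("first_gen", "both", "none"):
            X[f"med[{lev}]"] = (med == lev).astype(float)
        term = "med[first_gen]"
    else:
        X = pd.DataFrame(index=rows.index)
        X["diagnosis"] = rows["diagnosis"].astype(float)
        term = "diagnosis"
    X["sex"] = rows["sex"].astype(float)
    X["age"] = rows["age"].astype(float)
    for cov in _EXTRA_COVARIATES.get(model_id, []):
        if cov == "handedness":
            X["handedness"] = (rows["handedness"].astype(str) == "L").astype(float)
        elif cov == "icv":
            X["icv"] = rows["icv"].astype(float)
        elif cov == "age2":
            age_c = rows["age"].astype(float) - rows["age"].astype(float).mean()
            X["age2"] = age_c**2  # centered before squaring for conditioning
    if model_id == "m8_dx_by_age":
        age_c = rows["age"].astype(float) - rows["age"].astype(float).mean()
        X["dx_by_age"] = rows["diagnosis"].astype(float) * age_c
        term = "dx_by_age"
    elif model_id == "m9_dx_by_sex":
        X["dx_by_sex"] = rows["diagnosis"].astype(float) * rows["sex"].astype(float)
        term = "dx_by_sex"
    dummies = _scanner_dummies(rows["scanner_id"])
    X = pd.concat([X, dummies], axis=1)
    return X, term


def fit_site_model(rows: pd.DataFrame, spec: ModelSpec) -> SiteEffect:
    """Fit one model for one response in one dataset.

    ``rows`` are the dataset's individuals with covariate columns and the
    response column.  Complete-case rows (response + predictors) are used
    for this model only.  Returns a skipped :class:`SiteEffect` (with
    reason) rather than raising when the dataset is ineligible or the
    design is degenerate.
    """
    dataset_id = str(rows["dataset_id"].iloc[0]) if len(rows) else "?"
    # unilateral responses keep their _L/_R suffix so left and right pool separately
    eff = SiteEffect(dataset_id=dataset_id, measure_id=spec.response, model_id=spec.model_id)

    built = _design_for_model(rows, spec)
    if isinstance(built, str):
        eff.skipped, eff.skip_reason = True, built
        return eff
    X, term = built

    y = rows.loc[X.index, spec.response].astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    sub = rows.loc[y.index]

    n_dummies = sum(c.startswith("scanner[") for c in X.columns)
    if spec.model_id == "m6_medication":
        med = sub["medication_class"].astype(str)
        n1 = int((med == "second_gen").sum())  # reference group
        n2 = int((med == "first_gen").sum())
    else:
        n1 = int((sub["diagnosis"] == 0).sum())
        n2 = int((sub["diagnosis"] == 1).sum())
    eff.n1, eff.n2 = n1, n2

    ok, reason = check_eligibility(n1, n2, n_dummies, spec.min_total_base, spec.min_group)
    if not ok:
        eff.skipped, eff.skip_reason = True, reason
        return eff

    # drop constant columns (e.g. single-sex dataset); the term itself must vary
    variable = [c for c in X.columns if X[c].nunique() > 1]
    if term not in variable:
        eff.skipped, eff.skip_reason = True, f"term {term} constant"
        return eff
    X = X[variable]

    Xmat = sm.add_constant(X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        eff.skipped, eff.skip_reason = True, "rank-deficient design"
        return eff

    vifs = compute_vif(X.to_numpy())
    eff.max_vif = float(np.max(vifs))
    eff.vif_flag = bool(eff.max_vif > spec.vif_threshold)

    fit = sm.OLS(y.to_numpy(), Xmat).fit()
    j = 1 + list(X.columns).index(term)  # past the intercept
    t = float(fit.tvalues[j])
    df = float(fit.df_resid)
    if df <= 0:
        eff.skipped, eff.skip_reason = True, "no residual degrees of freedom"
        return eff
    d = t_to_cohens_d(t, n1, n2, df)
    se = d_standard_error(d, n1, n2)
    eff.t, eff.df, eff.d, eff.se_d, eff.ci95 = t, df, d, se, ci95(d, se)
    return eff


def fit_all_sites(
    ai_data: pd.DataFrame,
    responses: list[str],
    model_id: str = "m1",
    **spec_kwargs,
) -> pd.DataFrame:
    """Fit one model for every (dataset, response) pair.

    Returns the per-site summary-statistics table that the central
    meta-analysis consumes: one row per (dataset, measure, model) with t,
    df, group sizes, d, se, CI and flags.  Case-only datasets come back
    as skipped rows.
    """
    records = []
    for _, site_rows in ai_data.groupby("dataset_id", sort=True):
        for resp in responses:
            spec = ModelSpec(model_id=model_id, response=resp, **spec_kwargs)
            records.append(fit_site_model(site_rows, spec).to_row())
    return pd.DataFrame.from_records(records, columns=SITE_SUMMARY_COLUMNS)
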