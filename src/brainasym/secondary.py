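"""Secondary and interaction analyses, meta-analyzed across datasets.

Diagnosis-by-age and diagnosis-by-sex interaction scans reuse the
per-dataset model machinery unchanged (the interaction term's t-statistic
goes through the same Cohen's d conversion) and are pooled with the same
REML engine; FDR for each scan spans all AIs tested in that scan.
Medication contrasts (first- vs second-generation antipsychotics) are
case-only model fits.  Within-case clinical correlations and within-group
age trends are partial correlations (adjusting sex, or age and sex)
pooled on the Fisher-z scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .meta import MetaResult, bh_fdr, meta_analyze_sites, pool_correlations
from .sitewise import fit_all_sites

__all__ = [
    "run_interaction_scan",
    "medication_contrast",
    "within_group_age_trends",
    "clinical_correlation_scan",
    "partial_correlation",
]

logger = logging.getLogger(__name__)


def run_interaction_scan(
    ai_data: pd.DataFrame,
    responses: list[str],
    which: str,
) -> pd.DataFrame:
    """Meta-analyzed diagnosis-by-age or diagnosis-by-sex interaction scan.

    Fits the primary model augmented with the requested interaction term
    in every dataset, converts the interaction t to Cohen's d, pools with
    REML, and BH-adjusts over all AIs tested in the scan.
    """
    model_id = {"dx_by_age": "m8_dx_by_age", "dx_by_sex": "m9_dx_by_sex"}.get(which)
    if model_id is None:
        raise ValueError("which must be 'dx_by_age' or 'dx_by_sex'")
    summary = fit_all_sites(ai_data, responses, model_id=model_id)
    n_skipped = int(summary["skipped"].sum())
    if n_skipped:
        logger.info("%s scan: %d site fits skipped", which, n_skipped)
    return meta_analyze_sites(summary, fdr_families=None)


def medication_contrast(ai_data: pd.DataFrame, responses: list[str]) -> pd.DataFrame:
    """First- vs second-generation antipsychotic contrast among cases.

    Case-only per-dataset models with medication class, age, sex (and
    scanner dummies); the first-generation dummy's t is converted to d
    and REML-pooled; BH-FDR across the tested AIs.  Datasets without
    medication data, or with fewer than five users in either generation
    group, come back skipped.
    """
    summary = fit_all_sites(ai_data, responses, model_id="m6_medication")
    return meta_analyze_sites(summary, fdr_families=None)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, confounds: np.ndarray | None
) -> float:
    """Pearson correlation of x and y after residualizing both on confounds."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if confounds is not None:
        Z = np.column_stack([np.ones(len(x)), np.asarray(confounds, dtype=float)])
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _pool_dataset_correlations(
    rows: list[tuple[float, int]],
    n_adjust: int,
    measure_id: str,
    model_id: str,
) -> MetaResult | None:
    rows = [(r, n) for r, n in rows if np.isfinite(r) and abs(r) < 1 and n > 3 + n_adjust]
    if not rows:
        return None
    r, n = zip(*rows)
    return pool_correlations(
        np.array(r), np.array(n), n_adjust=n_adjust, measure_id=measure_id, model_id=model_id
    )


def within_group_age_trends(
    data: pd.DataFrame,
    response: str,
    min_n: int = 10,
) -> dict[str, MetaResult | None]:
    """Age association of one response, separately for cases and controls.

    Per dataset and diagnostic group, the partial correlation of the
    response with age (adjusting sex) is computed when at least ``min_n``
    individuals have complete data; per-group correlations are pooled by
    Fisher-z REML.  Run with an AI column or a unilateral ``_L``/``_R``
    column to describe which hemisphere drives a trend.
    """
    out: dict[str, MetaResult | None] = {}
    for group, label in ((0, "controls"), (1, "cases")):
        rows = []
        for ds, grp in data[data["diagnosis"] == group].groupby("dataset_id"):
            sub = grp[[response, "age", "sex"]].dropna()
            if len(sub) < min_n or sub[response].std() == 0:
                continue
            r = partial_correlation(
                sub[response].to_numpy(), sub["age"].to_numpy(), sub[["sex"]].to_numpy()
            )
            rows.append((r, len(sub)))
        out[label] = _pool_dataset_correlations(
            rows, n_adjust=1, measure_id=response, model_id=f"age_trend_{label}"
        )
    return out


def clinical_correlation_scan(
    ai_data: pd.DataFrame,
    responses: list[str],
    variables: list[str],
    min_n: int = 10,
) -> pd.DataFrame:
    """Within-case correlations of AIs with clinical variables.

    For each (AI, variable) pair: per-dataset partial correlation among
    cases (adjusting age and sex, at least ``min_n`` complete cases),
    Fisher-z REML pooling, then BH-FDR over the whole grid tested.
    Variables available in no dataset simply yield no rows.
    """
    cases = ai_data[ai_data["diagnosis"] == 1]
    records = []
    for variable in variables:
        if variable not in cases.columns:
            logger.info("clinical variable %s absent; skipped", variable)
            continue
        for response in responses:
            rows = []
            for ds, grp in cases.groupby("dataset_id"):
                sub = grp[[response, variable, "age", "sex"]].dropna()
                if len(sub) < min_n:
                    continue
                if sub[variable].std() == 0 or sub[response].std() == 0:
                    continue
                r = partial_correlation(
                    sub[response].to_numpy(),
                    sub[variable].to_numpy(dtype=float),
                    sub[["age", "sex"]].to_numpy(),
                )
                rows.append((r, len(sub)))
            pooled = _pool_dataset_correlations(
                rows, n_adjust=2, measure_id=response, model_id="clinical"
            )
            if pooled is None:
                continue
            records.append(
                {
                    "measure_id": response,
                    "variable": variable,
                    "k": pooled.k,
                    "r": pooled.d,
                    "z": pooled.z,
                    "p": pooled.p,
                }
            )
    out = pd.DataFrame.from_records(
        records, columns=["measure_id", "variable", "k", "r", "z", "p"]
    )
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out
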