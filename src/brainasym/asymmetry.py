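"""Asymmetry index computation and assembly into testing families.

For a bilaterally paired measure with left (L) and right (R) values the
asymmetry index is

    AI = (L - R) / ((L + R) / 2)

where the denominator corrects for automatic scaling of the index with
the magnitude of the bilateral measure.  Positive AI means leftward
(L > R) asymmetry.  For positive measures AI is bounded in (-2, 2).

Cleaning rules applied before AI computation: a hemispheric value equal
to 0 is treated as a data-entry error and set to missing, and whenever
one hemisphere is missing the opposite hemisphere is set to missing too,
so an AI is either computed from two positive values or missing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import RegionCatalog
from .simulate import CLINICAL_COLUMNS, COVARIATE_COLUMNS

__all__ = ["clean_pair", "compute_ai", "build_ai_table", "AITable", "check_orientation"]

logger = logging.getLogger(__name__)


def clean_pair(L: float | None, R: float | None) -> tuple[float, float]:
    """Apply the zero-to-missing and pairwise-missing rules to one L/R pair.

    Returns the cleaned ``(L, R)`` with ``nan`` for missing.  Negative
    inputs are physically impossible measures and are rejected rather
    than silently set missing.
    """
    l = math.nan if L is None else float(L)
    r = math.nan if R is None else float(R)
    if (not math.isnan(l) and l < 0) or (not math.isnan(r) and r < 0):
        raise ValueError(f"negative hemispheric measure in pair ({L!r}, {R!r})")
    if l == 0.0:
        l = math.nan
    if r == 0.0:
        r = math.nan
    if math.isnan(l) or math.isnan(r):
        return (math.nan, math.nan)
    return (l, r)


def compute_ai(L: float, R: float) -> float:
    """AI = (L - R) / ((L + R)/2) for positive L and R.

    Antisymmetric under hemisphere swap and invariant under rescaling of
    both sides by the same positive constant.
    """
    if not (L > 0 and R > 0):
        raise ValueError("compute_ai requires positive L and R; clean the pair first")
    return (L - R) / ((L + R) / 2.0)


@dataclass
class AITable:
    """Per-individual asymmetry indices plus carried-over covariates.

    ``data`` holds the covariate/clinical columns followed by one AI
    column per paired measure; ``families`` maps measure_id to its FDR
    family (thickness / area / subcortical); ``multivariate_ids`` lists
    the 76 regional measures eligible for the multivariate arm.
    """

    data: pd.DataFrame
    families: dict[str, str]
    multivariate_ids: list[str]

    @property
    def measure_ids(self) -> list[str]:
        return list(self.families)

    def family_members(self, family: str) -> list[str]:
        return [m for m, f in self.families.items() if f == family]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False, float_format="%.10g")
        meta = {"families": self.families, "multivariate_ids": self.multivariate_ids}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "AITable":
        path = Path(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(
            data=pd.read_csv(path),
            families=meta["families"],
            multivariate_ids=meta["multivariate_ids"],
        )


def _clean_lr_arrays(L: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized clean_pair over aligned L/R arrays."""
    if np.nanmin(L, initial=0.0) < 0 or np.nanmin(R, initial=0.0) < 0:
        raise ValueError("negative hemispheric measures present; corrupted input")
    L = np.where(L == 0.0, np.nan, L)
    R = np.where(R == 0.0, np.nan, R)
    either = np.isnan(L) | np.isnan(R)
    return np.where(either, np.nan, L), np.where(either, np.nan, R)


def build_ai_table(table: pd.DataFrame, catalog: RegionCatalog) -> AITable:
    """Compute all 78 AI columns from a wide bilateral table.

    The input must carry one ``<measure>_L`` / ``<measure>_R`` column pair
    for every catalog entry.  Covariate and clinical columns present in
    the input are carried over unchanged.  Per-column missingness counts
    are logged.
    """
    if table["individual_id"].duplicated().any():
        dup = table.loc[table["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"duplicated individual_id {dup!r}")

    expected = {f"{m}_{h}" for m in catalog.measure_ids for h in ("L", "R")}
    known = set(COVARIATE_COLUMNS) | set(CLINICAL_COLUMNS) | expected
    paired_like = {c for c in table.columns if c.endswith(("_L", "_R"))}
    unknown = paired_like - known
    if unknown:
        raise ValueError(f"unknown measure columns: {sorted(unknown)[:5]}")
    missing_cols = expected - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing measure columns: {sorted(missing_cols)[:5]}")

    carried = [c for c in table.columns if c not in paired_like]
    out = table[carried].copy()
    for m in catalog.measure_ids:
        L = table[f"{m}_L"].to_numpy(dtype=float)
        R = table[f"{m}_R"].to_numpy(dtype=float)
        Lc, Rc = _clean_lr_arrays(L, R)
        with np.errstate(invalid="ignore"):
            ai = (Lc - Rc) / ((Lc + Rc) / 2.0)
        out[m] = ai
        n_missing = int(np.isnan(ai).sum())
        if n_missing:
            logger.info("AI column %s: %d missing of %d", m, n_missing, len(ai))

    return AITable(
        data=out,
        families=dict(catalog.families),
        multivariate_ids=list(catalog.multivariate_ids),
    )


def check_orientation(
    ai_table: AITable, reference_measure: str | None = None
) -> list[str]:
    """Heuristic flag for possible left/right image-orientation flips.

    For a strongly lateralized reference measure (by default the measure
    with the largest |cohort mean AI|), any dataset whose mean AI has the
    opposite sign to the cohort consensus is flagged with a warning.  The
    flag never triggers an automatic flip; it only names datasets whose
    hemisphere labelling deserves manual review.
    """
    df = ai_table.data
    if reference_measure is None:
        means = df[ai_table.measure_ids].mean()
        reference_measure = means.abs().idxmax()
    consensus = df[reference_measure].mean()
    flagged = []
    for ds, grp in df.groupby("dataset_id"):
        m = grp[reference_measure].mean()
        if np.isfinite(m) and np.isfinite(consensus) and m * consensus < 0:
            flagged.append(str(ds))
            logger.warning(
                "dataset %s: mean AI of %s (%.4f) opposes cohort consensus (%.4f); "
                "check image orientation",
                ds,
                reference_measure,
                m,
                consensus,
            )
    return flagged
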