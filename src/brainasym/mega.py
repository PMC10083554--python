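"""Pooled individual-level (mega-analysis) arm.

Left and right hemispheric measures from datasets with individual-level
data are harmonized with parametric ComBat -- an empirical-Bayes
location/scale model that removes batch (dataset x scanner) effects
while preserving diagnosis, age, and sex covariate structure.  Asymmetry
indices are then recomputed from the harmonized measures, and the 76
regional AIs are tested jointly against case-control status with a
MANCOVA (age and sex as covariates): Wilks' Lambda = det(E)/det(E + H)
with Rao's F approximation, which is exact in form for this single-df
hypothesis,

    F = ((1 - Lambda)/Lambda) * (df2/df1),  df1 = p,
    df2 = N - rank(design) - p + 1.

Significance is additionally assessed by a stratified label-swapping
permutation test: diagnosis labels are shuffled only within dataset
(and scanner) strata, preserving each stratum's case/control counts, and
the permutation p-value is the count of permuted F >= observed F divided
by the number of permutations.  Univariate ANCOVA follow-ups rank the
per-AI contributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asymmetry import _clean_lr_arrays
from .catalog import RegionCatalog

__all__ = [
    "MancovaResult",
    "permutation_p",
    "combat_fit_apply",
    "post_harmonization_qc",
    "correlation_screen",
    "mancova_wilks",
    "rao_f",
    "stratified_permutation_test",
    "univariate_followup",
    "run_mega",
]

logger = logging.getLogger(__name__)


@dataclass
class MancovaResult:
    """MANCOVA summary: Wilks' Lambda, Rao's F, and permutation inference."""

    Lambda: float
    F: float
    df1: int
    df2: int
    p_nominal: float
    p_perm: float = math.nan
    n_perm: int = 0
    n_exceed: int = -1
    seed: int | None = None

    @property
    def variance_explained(self) -> float:
        return 1.0 - self.Lambda

    def to_dict(self) -> dict:
        return {
            "lambda": self.Lambda,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p_nominal": self.p_nominal,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "n_exceed": self.n_exceed,
            "seed": self.seed,
            "variance_explained": self.variance_explained,
        }


def permutation_p(n_exceed: int, n_perm: int) -> float:
    """Permutation p-value, count of exceedances over permutation count.

    Uses the plain count/n convention (not the (count+1)/(n+1)
    bias-corrected form), so a zero count reports p = 0; callers log a
    caveat in that case.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 <= n_exceed <= n_perm:
        raise ValueError("n_exceed must lie in [0, n_perm]")
    return n_exceed / n_perm


# ---------------------------------------------------------------------------
# ComBat harmonization (parametric empirical Bayes)
# ---------------------------------------------------------------------------

def _delta_priors(delta_hat: np.ndarray) -> tuple[float, float]:
    """Inverse-gamma prior moments (lambda, theta) for one batch's scales."""
    m = float(delta_hat.mean())
    s2 = float(delta_hat.var(ddof=1)) if delta_hat.size > 1 else 0.0
    if s2 <= 0:
        # degenerate prior: fully shrink to the common scale
        return 2.0, m
    lam = (2.0 * s2 + m * m) / s2
    theta = (m * s2 + m**3) / s2
    return lam, theta


def _eb_batch_solution(
    Zb: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2_bar: float,
    lam: float,
    theta: float,
    conv: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional modes for one batch's shrunk (gamma*, delta2*)."""
    n_b = Zb.shape[0]
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau2_bar * gamma_hat + delta_star * gamma_bar) / (
            n_b * tau2_bar + delta_star
        )
        ss = ((Zb - g_new) ** 2).sum(axis=0)
        d_new = (theta + 0.5 * ss) / (n_b / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(g_new - gamma_star) / (np.abs(gamma_star) + 1e-12)),
            np.max(np.abs(d_new - delta_star) / (np.abs(delta_star) + 1e-12)),
        )
        gamma_star, delta_star = g_new, d_new
        if change < conv:
            break
    return gamma_star, delta_star


def combat_fit_apply(
    data: np.ndarray,
    batch: np.ndarray | pd.Series | list,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Parametric empirical-Bayes batch harmonization of a measure matrix.

    ``data`` is individuals x measures; ``batch`` assigns each individual
    to a dataset/scanner batch; ``covariates`` (individuals x q, no
    intercept) holds the biological structure to preserve (diagnosis,
    age, sex).  Features are standardized against the batch + covariate
    least-squares fit, per-batch location (gamma) and scale (delta^2)
    estimates are shrunk toward batch-level normal / inverse-gamma
    priors by iterative conditional modes, batch effects are removed,
    and covariate structure is restored.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be individuals x measures")
    if np.isnan(X).any():
        raise ValueError("harmonization requires complete data")
    batch = pd.Series(batch).astype(str).reset_index(drop=True)
    n, p = X.shape
    if len(batch) != n:
        raise ValueError("batch length must match the number of individuals")
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 batches")
    counts = batch.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"singleton batches not allowed: {list(singletons.index)}")

    B = np.zeros((n, len(levels)))
    for j, lev in enumerate(levels):
        B[batch.to_numpy() == lev, j] = 1.0
    design = B
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        full = np.column_stack([B, C])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValueError("batch + covariate design is rank deficient")
        design = full
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)

    n_b = counts.reindex(levels).to_numpy(dtype=float)
    grand_mean = (n_b / n) @ beta[: len(levels)]
    stand_mean = np.tile(grand_mean, (n, 1))
    if covariates is not None:
        stand_mean = stand_mean + design[:, len(levels):] @ beta[len(levels):]

    resid = X - design @ beta
    var_pooled = (resid**2).mean(axis=0)
    if np.any(var_pooled <= 0):
        bad = int(np.argmin(var_pooled))
        raise ValueError(f"zero-variance feature at column {bad}")
    scale = np.sqrt(var_pooled)
    Z = (X - stand_mean) / scale

    adjusted = np.empty_like(Z)
    for j, lev in enumerate(levels):
        idx = batch.to_numpy() == lev
        Zb = Z[idx]
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)
        if np.any(delta_hat <= 1e-10):  # standardized scale: this means constant
            bad = int(np.argmin(delta_hat))
            raise ValueError(
                f"zero within-batch variance in batch {lev!r}, column {bad}"
            )
        gamma_bar = float(gamma_hat.mean())
        tau2_bar = float(gamma_hat.var(ddof=1))
        lam, theta = _delta_priors(delta_hat)
        gamma_star, delta_star = _eb_batch_solution(
            Zb, gamma_hat, delta_hat, gamma_bar, tau2_bar, lam, theta
        )
        adjusted[idx] = (Zb - gamma_star) / np.sqrt(delta_star)

    return adjusted * scale + stand_mean


# ---------------------------------------------------------------------------
# Post-harmonization QC and screens
# ---------------------------------------------------------------------------

def post_harmonization_qc(
    adjusted_L: pd.DataFrame,
    adjusted_R: pd.DataFrame,
    volume_measures: list[str],
) -> pd.Index:
    """Individuals retained after harmonization sanity checks.

    Drops anyone assigned a non-positive adjusted value on any
    volume-family measure in either hemisphere (a harmonization artifact,
    not an anatomical possibility), and anyone with incomplete data on
    any paired measure.  Returns the retained index; drops are logged.
    """
    complete = adjusted_L.notna().all(axis=1) & adjusted_R.notna().all(axis=1)
    vol_ok = pd.Series(True, index=adjusted_L.index)
    vols = [m for m in volume_measures if m in adjusted_L.columns]
    if vols:
        vol_ok = (adjusted_L[vols] > 0).all(axis=1) & (adjusted_R[vols] > 0).all(axis=1)
    keep = complete & vol_ok
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "post-harmonization QC dropped %d individuals "
            "(%d incomplete, %d non-positive volumes)",
            n_dropped,
            int((~complete).sum()),
            int((complete & ~vol_ok).sum()),
        )
    return adjusted_L.index[keep]


def correlation_screen(ai_matrix: pd.DataFrame, warn_threshold: float = 0.5):
    """Pairwise Pearson correlations among AIs with a collinearity warning.

    Returns ``(max_abs_r, correlation matrix)``.  Constant columns yield
    undefined (missing) correlations and a warning; a maximum absolute
    off-diagonal correlation above ``warn_threshold`` warns but never
    fails.
    """
    if ai_matrix.shape[1] < 2:
        raise ValueError("correlation screen needs at least 2 columns")
    constant = ai_matrix.columns[ai_matrix.std(ddof=0) == 0].tolist()
    if constant:
        logger.warning("constant AI columns, correlations undefined: %s", constant)
    corr = ai_matrix.corr()
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, np.nan)
    max_abs = float(np.nanmax(np.abs(off)))
    if max_abs > warn_threshold:
        logger.warning("max |pairwise AI correlation| %.3f exceeds %.2f", max_abs, warn_threshold)
    return max_abs, corr


# ---------------------------------------------------------------------------
# MANCOVA with Wilks' Lambda and stratified permutations
# ---------------------------------------------------------------------------

def rao_f(Lambda: float, p: int, N: int, design_rank: int) -> tuple[float, int, int, float]:
    """Rao's F approximation for a single-df Wilks' Lambda.

    Returns ``(F, df1, df2, p_nominal)`` with df1 = p and
    df2 = N - design_rank - p + 1.
    """
    df1 = p
    df2 = N - design_rank - p + 1
    if df2 <= 0:
        raise ValueError("non-positive error degrees of freedom")
    F = ((1.0 - Lambda) / Lambda) * (df2 / df1)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def _residualize(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    return Y - Z @ beta


def _check_response_rank(Y: np.ndarray, columns) -> None:
    if np.linalg.matrix_rank(Y) >= Y.shape[1]:
        return
    # name the offending columns: those that do not raise the rank
    offending = []
    rank = 0
    for j in range(Y.shape[1]):
        r = np.linalg.matrix_rank(Y[:, : j + 1])
        if r == rank:
            offending.append(str(columns[j]))
        rank = r
    raise ValueError(f"rank-deficient response set; offending columns: {offending}")


def mancova_wilks(
    ai_matrix: pd.DataFrame,
    diagnosis: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> MancovaResult:
    """MANCOVA of all AIs against diagnosis, adjusting age and sex.

    Wilks' Lambda = det(E)/det(E + H) for the diagnosis hypothesis, with
    E the residual SSCP of the full design [1, diagnosis, age, sex] and
    H the diagnosis hypothesis SSCP.  For this single-df hypothesis H has
    rank 1, so Lambda reduces to 1 - h' (E+H)^{-1} h / s with h the
    covariate-residualized cross-product and s the residual sum of
    squares of diagnosis -- the two routes agree to machine precision.
    """
    Y = ai_matrix.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("MANCOVA requires complete data")
    N, p = Y.shape
    dx = np.asarray(diagnosis, dtype=float)
    Z = np.column_stack([np.ones(N), np.asarray(age, float), np.asarray(sex, float)])
    design_rank = int(np.linalg.matrix_rank(np.column_stack([Z, dx])))
    if N <= p + design_rank:
        raise ValueError("sample too small for the number of responses")

    Yt = _residualize(Y, Z)
    _check_response_rank(Yt, ai_matrix.columns)
    dt = _residualize(dx[:, None], Z)[:, 0]
    s = float(dt @ dt)
    if s <= 0:
        raise ValueError("diagnosis is collinear with the covariates")
    h = Yt.T @ dt
    T = Yt.T @ Yt  # = E + H
    E = T - np.outer(h, h) / s
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_e <= 0 or sign_t <= 0:
        raise ValueError("singular SSCP matrix")
    Lambda = float(np.exp(logdet_e - logdet_t))
    F, df1, df2, p_nom = rao_f(Lambda, p, N, design_rank)
    return MancovaResult(Lambda=Lambda, F=F, df1=df1, df2=df2, p_nominal=p_nom)


def _perm_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based stream for one permutation: key = (seed, index)."""
    return np.random.Generator(np.random.Philox(key=(int(seed) << 64) + index))


def stratified_permutation_test(
    ai_matrix: pd.DataFrame,
    diagnosis: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    strata: np.ndarray | pd.Series | list,
    n_perm: int = 10_000,
    seed: int = 0,
    chunk_size: int = 1000,
) -> MancovaResult:
    """Label-swapping permutation test of the MANCOVA F, stratified.

    Diagnosis labels are permuted only within each stratum (dataset, or
    dataset x scanner), conserving every stratum's case/control counts;
    the MANCOVA F is recomputed for each permutation and

        p_perm = #(F_perm >= F_obs) / n_perm

    exactly as stated, so a zero count reports p_perm = 0 (logged).
    Permutation streams are counter-based on (seed, permutation index):
    the same seed and n_perm give an identical p-value regardless of
    chunking or execution order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = mancova_wilks(ai_matrix, diagnosis, age, sex)

    Y = ai_matrix.to_numpy(dtype=float)
    N, p = Y.shape
    dx = np.asarray(diagnosis, dtype=float)
    strata = pd.Series(strata).astype(str).reset_index(drop=True)
    groups = [np.flatnonzero(strata.to_numpy() == g) for g in strata.unique()]
    for g, idx in zip(strata.unique(), groups):
        if len(np.unique(dx[idx])) < 2:
            logger.info("stratum %s has a single diagnosis class; labels fixed", g)

    Z = np.column_stack([np.ones(N), np.asarray(age, float), np.asarray(sex, float)])
    Zpinv = np.linalg.pinv(Z)
    Yt = Y - Z @ (Zpinv @ Y)
    T = Yt.T @ Yt
    Tinv = np.linalg.inv(T)
    df1, df2 = obs.df1, obs.df2
    f_const = df2 / df1

    n_exceed = 0
    done = 0
    while done < n_perm:
        b = min(chunk_size, n_perm - done)
        D = np.empty((N, b))
        for jj in range(b):
            rng = _perm_rng(seed, done + jj)
            lab = dx.copy()
            for idx in groups:
                lab[idx] = lab[idx][rng.permutation(len(idx))]
            D[:, jj] = lab
        Dt = D - Z @ (Zpinv @ D)
        H = Yt.T @ Dt  # p x b
        qf = np.einsum("ij,ij->j", H, Tinv @ H)
        ssq = np.einsum("ij,ij->j", Dt, Dt)
        lam = 1.0 - qf / ssq
        F = (1.0 - lam) / lam * f_const
        n_exceed += int(np.sum(F >= obs.F))
        done += b

    obs.n_perm = n_perm
    obs.n_exceed = n_exceed
    obs.p_perm = permutation_p(n_exceed, n_perm)
    obs.seed = seed
    if n_exceed == 0:
        logger.warning(
            "no permuted F reached the observed F; p_perm = 0 under the "
            "count/n convention (resolution limit 1/%d)",
            n_perm,
        )
    return obs


def univariate_followup(
    ai_matrix: pd.DataFrame,
    diagnosis: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> pd.DataFrame:
    """Per-AI ANCOVA F tests for diagnosis, adjusting age and sex.

    Returns a table ranked by nominal p (no FDR here; these describe the
    contributions to the multivariate association).
    """
    Y = ai_matrix.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("ANCOVA follow-up requires complete data")
    N = Y.shape[0]
    dx = np.asarray(diagnosis, dtype=float)
    Z = np.column_stack([np.ones(N), np.asarray(age, float), np.asarray(sex, float)])
    rank_full = int(np.linalg.matrix_rank(np.column_stack([Z, dx])))
    Yt = _residualize(Y, Z)
    dt = _residualize(dx[:, None], Z)[:, 0]
    s = float(dt @ dt)
    h = Yt.T @ dt
    ss_total = np.einsum("ij,ij->j", Yt, Yt)
    ss_hyp = h**2 / s
    df_resid = N - rank_full
    F = ss_hyp / ((ss_total - ss_hyp) / df_resid)
    pvals = stats.f.sf(F, 1, df_resid)
    out = pd.DataFrame({"measure_id": ai_matrix.columns, "F": F, "p": pvals})
    return out.sort_values("p", ignore_index=True)


# ---------------------------------------------------------------------------
# End-to-end mega-analysis driver
# ---------------------------------------------------------------------------

def run_mega(
    table: pd.DataFrame,
    catalog: RegionCatalog,
    n_perm: int = 10_000,
    seed: int = 0,
    harmonize: bool = True,
) -> dict:
    """Run the pooled individual-level arm on a bilateral table.

    Steps: clean L/R pairs (zero -> missing, pairwise missingness),
    retain individuals with complete data on all 76 regional pairs,
    ComBat-harmonize left and right matrices separately (batch =
    dataset x scanner; diagnosis/age/sex preserved), drop individuals
    with non-positive adjusted volumes, recompute AIs from harmonized
    measures, screen correlations, and run the MANCOVA with stratified
    permutations plus univariate follow-ups.
    """
    measures = catalog.multivariate_ids
    volume_measures = [m for m in measures if catalog.entry(m).family == "subcortical"]

    L = {}
    R = {}
    for m in measures:
        Lc, Rc = _clean_lr_arrays(
            table[f"{m}_L"].to_numpy(dtype=float), table[f"{m}_R"].to_numpy(dtype=float)
        )
        L[m], R[m] = Lc, Rc
    Ldf = pd.DataFrame(L, index=table.index)
    Rdf = pd.DataFrame(R, index=table.index)

    complete = Ldf.notna().all(axis=1) & Rdf.notna().all(axis=1)
    n_incomplete = int((~complete).sum())
    Ldf, Rdf = Ldf[complete], Rdf[complete]
    meta_cols = table.loc[complete, ["dataset_id", "scanner_id", "diagnosis", "age", "sex"]]
    strata = meta_cols["dataset_id"].astype(str) + "/" + meta_cols["scanner_id"].astype(str)

    if harmonize:
        cov = meta_cols[["diagnosis", "age", "sex"]].to_numpy(dtype=float)
        Ladj = pd.DataFrame(
            combat_fit_apply(Ldf.to_numpy(), strata, cov), index=Ldf.index, columns=measures
        )
        Radj = pd.DataFrame(
            combat_fit_apply(Rdf.to_numpy(), strata, cov), index=Rdf.index, columns=measures
        )
    else:
        Ladj, Radj = Ldf, Rdf

    keep = post_harmonization_qc(Ladj, Radj, volume_measures)
    Ladj, Radj = Ladj.loc[keep], Radj.loc[keep]
    meta_cols, strata = meta_cols.loc[keep], strata.loc[keep]

    ai = (Ladj - Radj) / ((Ladj + Radj) / 2.0)
    max_abs_r, _ = correlation_screen(ai)

    dx = meta_cols["diagnosis"].to_numpy(dtype=float)
    age = meta_cols["age"].to_numpy(dtype=float)
    sex = meta_cols["sex"].to_numpy(dtype=float)
    result = stratified_permutation_test(ai, dx, age, sex, strata, n_perm=n_perm, seed=seed)
    followup = univariate_followup(ai, dx, age, sex)

    report = result.to_dict()
    report.update(
        {
            "n_individuals": int(len(ai)),
            "n_cases": int(dx.sum()),
            "n_controls": int((1 - dx).sum()),
            "n_dropped_incomplete": n_incomplete,
            "n_dropped_qc": int(complete.sum() - len(keep)),
            "max_abs_pairwise_ai_correlation": max_abs_r,
        }
    )
    return {"mancova": report, "univariate": followup}
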