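"""Random-effects meta-analysis with REML, FDR control, and sensitivity tools.

Per-dataset effects ``d_i`` with standard errors ``se_i`` follow the
normal-normal random-effects model ``d_i ~ N(mu, se_i^2 + tau^2)``.  The
between-dataset variance tau^2 is estimated by restricted maximum
likelihood (Fisher scoring, floored at zero, DerSimonian-Laird fallback
on non-convergence), the pooled effect is the inverse-variance weighted
mean at the REML weights, and inference uses the Wald z statistic.
Cochran's Q and I^2 are computed at fixed-effect weights.  Multiplicity
is controlled with Benjamini-Hochberg FDR within measure families
(35 thickness, 35 surface area, 8 subcortical AIs for the primary
analysis).  Moderator (meta-regression) and leave-one-out outlier
sensitivity analyses reuse the same machinery, as does pooling of
per-dataset correlations on the Fisher-z scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaResult",
    "reml_pool",
    "z_to_p_two_sided",
    "bh_fdr",
    "meta_regress",
    "outlier_sensitivity",
    "pool_correlations",
    "meta_analyze_sites",
]

logger = logging.getLogger(__name__)


@dataclass
class MetaResult:
    """Pooled effect for one measure under one model."""

    measure_id: str
    model_id: str
    k: int
    d: float
    se: float
    z: float
    p: float
    tau2: float
    Q: float
    I2: float
    q: float = math.nan  # BH-adjusted p, filled in per family
    converged: bool = True

    def to_row(self) -> dict:
        return {
            "measure_id": self.measure_id,
            "model_id": self.model_id,
            "k": self.k,
            "d": self.d,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "q": self.q,
            "tau2": self.tau2,
            "Q": self.Q,
            "I2": self.I2,
            "converged": self.converged,
        }


def z_to_p_two_sided(z: float) -> float:
    """Two-sided normal p-value, p = 2 Phi(-|z|)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * stats.norm.sf(abs(z)))


def _dersimonian_laird(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (Q - (len(y) - 1)) / denom)


def _reml_tau2(
    y: np.ndarray, v: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[float, bool]:
    """REML tau^2 by Fisher scoring on the restricted log-likelihood."""
    tau2 = max(_dersimonian_laird(y, v), 0.0)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        sw, sw2, sw3 = np.sum(w), np.sum(w**2), np.sum(w**3)
        score = 0.5 * (np.sum(w**2 * (y - mu) ** 2) - sw + sw2 / sw)
        info = 0.5 * (sw2 - 2.0 * sw3 / sw + (sw2 / sw) ** 2)
        if info <= 0:
            break
        step = score / info
        new = max(tau2 + step, 0.0)
        if abs(new - tau2) < tol * (1.0 + tau2):
            return new, True
        tau2 = new
    logger.warning("REML did not converge; falling back to DerSimonian-Laird")
    return _dersimonian_laird(y, v), False


def reml_pool(
    d: np.ndarray | list[float],
    se: np.ndarray | list[float],
    measure_id: str = "",
    model_id: str = "",
) -> MetaResult:
    """Pool per-dataset effects with the REML random-effects model."""
    y = np.asarray(d, dtype=float)
    s = np.asarray(se, dtype=float)
    if y.size == 0:
        raise ValueError("no effects to pool")
    if y.shape != s.shape:
        raise ValueError("d and se must have the same length")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite effect or standard error")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")

    k = y.size
    v = s**2
    if k == 1:
        tau2, converged = 0.0, True
        Q, I2 = 0.0, 0.0
    else:
        tau2, converged = _reml_tau2(y, v)
        wf = 1.0 / v
        mu_f = np.sum(wf * y) / np.sum(wf)
        Q = float(np.sum(wf * (y - mu_f) ** 2))
        I2 = float(max(0.0, (Q - (k - 1)) / Q) * 100.0) if Q > 0 else 0.0

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(1.0 / math.sqrt(np.sum(w)))
    z = mu / se_mu
    return MetaResult(
        measure_id=measure_id,
        model_id=model_id,
        k=k,
        d=mu,
        se=se_mu,
        z=z,
        p=z_to_p_two_sided(z),
        tau2=float(tau2),
        Q=Q,
        I2=I2,
        converged=converged,
    )


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    XtW = X.T * w
    XtWX = XtW @ X
    beta = np.linalg.solve(XtWX, XtW @ y)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return float(-0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r**2)))


def meta_regress(
    d: np.ndarray | list[float],
    se: np.ndarray | list[float],
    moderator: pd.Series | np.ndarray | list,
) -> dict | None:
    """Mixed-effects meta-regression with a Wald omnibus moderator test.

    Categorical moderators are dummy-coded against their first level;
    numeric moderators enter linearly.  tau^2 is estimated by REML
    (bounded scalar maximization of the restricted log-likelihood) and
    the omnibus test asks whether all moderator coefficients are zero
    (chi-square with one df per coefficient).  Returns ``None`` (skip)
    when the moderator is constant across datasets.
    """
    y = np.asarray(d, dtype=float)
    s = np.asarray(se, dtype=float)
    mod = pd.Series(moderator).reset_index(drop=True)
    if mod.nunique(dropna=True) < 2:
        logger.info("moderator constant across datasets; meta-regression skipped")
        return None
    if pd.api.types.is_numeric_dtype(mod):
        Xmod = mod.to_numpy(dtype=float)[:, None]
        q = 1
    else:
        dummies = pd.get_dummies(mod.astype(str), drop_first=True, dtype=float)
        Xmod = dummies.to_numpy()
        q = Xmod.shape[1]
    if y.size <= q + 1:
        raise ValueError("need more datasets than moderator levels")
    X = np.column_stack([np.ones(y.size), Xmod])
    v = s**2

    upper = max(10.0 * float(np.max(v)), 10.0 * float(np.var(y)) + 1e-12)
    res = optimize.minimize_scalar(
        lambda t2: -_restricted_loglik(t2, y, v, X),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(max(res.x, 0.0))
    if -_restricted_loglik(0.0, y, v, X) < res.fun:
        tau2 = 0.0

    w = 1.0 / (v + tau2)
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    b = beta[1:]
    cov_b = cov[1:, 1:]
    QM = float(b @ np.linalg.solve(cov_b, b))
    p = float(stats.chi2.sf(QM, q))
    return {"QM": QM, "df": q, "p": p, "tau2": tau2, "beta": beta}


def outlier_sensitivity(
    effects: pd.DataFrame,
    threshold: float = 2.5,
    model_id: str = "m1",
    measure_id: str = "",
) -> tuple[list[str], MetaResult, MetaResult]:
    """Leave-one-out outlier screen and re-pooled meta-analysis.

    A dataset is flagged when its externally studentized deleted residual
    -- the deviation of its effect from the estimate pooled without it,
    scaled by the combined sampling, between-dataset, and estimation
    variance -- exceeds ``threshold`` in absolute value.  Returns the
    flagged dataset ids, the meta-analysis excluding them, and the full
    meta-analysis.
    """
    if len(effects) < 3:
        raise ValueError("outlier screen needs at least 3 datasets")
    y = effects["d"].to_numpy(dtype=float)
    s = effects["se_d" if "se_d" in effects else "se"].to_numpy(dtype=float)
    ids = effects["dataset_id"].astype(str).to_list()

    full = reml_pool(y, s, measure_id=measure_id, model_id=model_id)
    flagged = []
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        loo = reml_pool(y[mask], s[mask])
        resid = y[i] - loo.d
        var = s[i] ** 2 + loo.tau2 + loo.se**2
        if abs(resid) / math.sqrt(var) > threshold:
            flagged.append(ids[i])

    keep = [i for i, ds in enumerate(ids) if ds not in flagged]
    repooled = reml_pool(y[keep], s[keep], measure_id=measure_id, model_id=model_id)
    return flagged, repooled, full


def pool_correlations(
    r: np.ndarray | list[float],
    n: np.ndarray | list[int],
    n_adjust: int = 0,
    measure_id: str = "",
    model_id: str = "correlation",
) -> MetaResult:
    """REML-pool per-dataset (partial) correlations on the Fisher-z scale.

    ``n_adjust`` is the number of conditioning covariates of a partial
    correlation; the Fisher-z sampling variance is 1/(n - 3 - n_adjust).
    The pooled result is back-transformed to the r scale (``d`` holds the
    pooled r); z and p are from the Fisher-z scale Wald test.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1")
    usable = n > 3 + n_adjust
    if not usable.any():
        raise ValueError("no dataset has enough individuals for Fisher-z pooling")
    z = np.arctanh(r[usable])
    se = 1.0 / np.sqrt(n[usable] - 3 - n_adjust)
    pooled = reml_pool(z, se, measure_id=measure_id, model_id=model_id)
    pooled.d = float(np.tanh(pooled.d))  # back-transform the estimate only
    return pooled


def meta_analyze_sites(
    site_summary: pd.DataFrame,
    fdr_families: dict[str, str] | None = None,
    model_id: str | None = None,
    min_k: int = 1,
) -> pd.DataFrame:
    """Pool a per-site summary table measure by measure, then apply BH-FDR.

    ``fdr_families`` maps measure_id to its FDR family; measures sharing
    a family are adjusted together (thickness / area / subcortical for
    the primary analysis).  With ``None``, all measures in the table form
    a single family, the convention used for the secondary scans.
    Skipped site rows are excluded before pooling.
    """
    df = site_summary
    if model_id is not None:
        df = df[df["model_id"] == model_id]
    usable = df[(~df["skipped"].astype(bool)) & df["d"].notna() & (df["se_d"] > 0)]

    results: list[MetaResult] = []
    for measure, grp in usable.groupby("measure_id", sort=True):
        if len(grp) < min_k:
            continue
        results.append(
            reml_pool(
                grp["d"].to_numpy(),
                grp["se_d"].to_numpy(),
                measure_id=str(measure),
                model_id=str(grp["model_id"].iloc[0]),
            )
        )
    out = pd.DataFrame.from_records([m.to_row() for m in results])
    if out.empty:
        return out

    if fdr_families is None:
        fam = pd.Series("all", index=out.index)
    else:
        fam = out["measure_id"].map(fdr_families)
    for _, idx in out.groupby(fam).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out
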