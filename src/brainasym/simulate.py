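"""Synthetic multi-site case-control cohort generator with known ground truth.

Each individual gets, for every paired measure, a latent bilateral size
``M ~ Normal(baseline_mean * site_scale, baseline_sd * noise_inflation)``
(truncated positive) and a latent asymmetry

    A = baseline_mean_AI + site_shift + age_c * age_slope + sex * sex_effect
        + dx * (d_true * ai_sd) + dx * age_c * interaction + Normal(0, ai_sd)

from which the hemispheric measures are constructed as ``L = M (1 + A/2)``
and ``R = M (1 - A/2)``.  This construction makes the asymmetry index
``(L - R) / ((L + R)/2)`` recover ``A`` exactly, so every downstream stage
has an analytic oracle.  Diagnosis effects are specified on the Cohen's d
scale and converted to AI units via the region's AI noise standard
deviation, so ``d_true`` is recoverable as a d.  Missing values and
exact-zero data-entry artifacts are injected after construction.

Codings used throughout the package: sex female=0 / male=1, diagnosis
control=0 / case=1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import RegionCatalog, default_catalog

__all__ = [
    "SiteSpec",
    "EffectSpec",
    "generate_cohort",
    "default_sites",
    "paper_scale_sites",
    "write_bilateral_csv",
    "read_bilateral_csv",
    "write_ground_truth",
    "COVARIATE_COLUMNS",
    "CLINICAL_COLUMNS",
]

COVARIATE_COLUMNS = [
    "individual_id",
    "dataset_id",
    "scanner_id",
    "diagnosis",
    "age",
    "sex",
    "handedness",
    "icv",
]

CLINICAL_COLUMNS = [
    "medication_class",
    "cpz_equivalent_dose",
    "age_at_onset",
    "duration_of_illness",
    "sans_total",
    "saps_total",
    "panss_total",
    "panss_positive",
    "panss_negative",
]

_MED_CLASSES = ("first_gen", "second_gen", "both", "none", "unknown")
_MED_PROBS = (0.25, 0.45, 0.10, 0.10, 0.10)

_AGE_CENTER = 33.0  # cohort-typical mean age; age slopes act on age - center


@dataclass(frozen=True)
class SiteSpec:
    """One simulated acquisition site / dataset."""

    dataset_id: str
    n_cases: int
    n_controls: int
    scanners: tuple[tuple[str, float], ...] = (("s1", 1.0),)
    age_mean: float = 33.0
    age_sd: float = 10.0
    male_fraction_cases: float = 0.67
    male_fraction_controls: float = 0.52
    site_offset_mean_scale: float = 1.0
    site_offset_ai_shift: float = 0.0
    noise_inflation: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")
        if abs(sum(p for _, p in self.scanners) - 1.0) > 1e-9:
            raise ValueError(f"{self.dataset_id}: scanner proportions must sum to 1")
        if self.noise_inflation < 1.0:
            raise ValueError("noise_inflation must be >= 1")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effects injected into the cohort.

    Diagnosis effects (``d_true``), diagnosis-by-age interactions and
    medication contrasts are in Cohen's d units; age slopes are AI units
    per year; sex effects are AI units.  ``clinical_assoc`` maps a measure
    to ``(clinical_variable, r_true)``, a within-case partial correlation
    target.
    """

    d_true: dict[str, float] = field(default_factory=dict)
    dx_by_age: dict[str, float] = field(default_factory=dict)  # AI units per year
    age_slope: dict[str, float] = field(default_factory=dict)
    sex_effect: dict[str, float] = field(default_factory=dict)
    medication_effect: dict[str, float] = field(default_factory=dict)
    clinical_assoc: dict[str, tuple[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    zero_artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "zero_artifact_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def null(cls, **kwargs) -> "EffectSpec":
        """All-zero effects (global null)."""
        return cls(**kwargs)


def default_sites(
    n_sites: int = 14,
    cases_per_site: int = 75,
    controls_per_site: int = 75,
    include_case_only: bool = False,
) -> list[SiteSpec]:
    """Desk-scale site list: 14 sites x ~150 individuals by default.

    Sites get mildly varying demographics, multiplicative offsets on the
    bilateral means and small additive AI shifts; every third site uses
    two scanners. Optionally appends one case-only site, which
    case-control stages must skip.
    """
    sites = []
    for i in range(n_sites):
        scanners: tuple[tuple[str, float], ...]
        if i % 3 == 2:
            scanners = ((f"site{i:02d}_a", 0.6), (f"site{i:02d}_b", 0.4))
        else:
            scanners = ((f"site{i:02d}_a", 1.0),)
        sites.append(
            SiteSpec(
                dataset_id=f"site{i:02d}",
                n_cases=cases_per_site,
                n_controls=controls_per_site,
                scanners=scanners,
                age_mean=28.0 + 1.0 * (i % 10),
                age_sd=8.0 + 0.5 * (i % 4),
                site_offset_mean_scale=1.0 + 0.02 * ((i % 7) - 3),
                site_offset_ai_shift=0.002 * ((i % 5) - 2),
                noise_inflation=1.0 + 0.05 * (i % 3),
            )
        )
    if include_case_only:
        sites.append(
            SiteSpec(
                dataset_id="caseonly",
                n_cases=60,
                n_controls=0,
                scanners=(("caseonly_a", 1.0),),
            )
        )
    return sites


def paper_scale_sites(n_sites: int = 45) -> list[SiteSpec]:
    """45 case-control sites totalling roughly 5,000 cases / 6,000 controls."""
    sites = []
    for i in range(n_sites):
        n_cases = 60 + 12 * (i % 9)  # ~110 mean
        n_controls = 80 + 12 * (i % 10)  # ~134 mean
        scanners: tuple[tuple[str, float], ...]
        if i % 5 == 4:
            scanners = ((f"ds{i:02d}_a", 0.5), (f"ds{i:02d}_b", 0.5))
        else:
            scanners = ((f"ds{i:02d}_a", 1.0),)
        sites.append(
            SiteSpec(
                dataset_id=f"ds{i:02d}",
                n_cases=n_cases,
                n_controls=n_controls,
                scanners=scanners,
                age_mean=26.0 + 1.2 * (i % 15),
                age_sd=7.0 + 0.4 * (i % 6),
                site_offset_mean_scale=1.0 + 0.015 * ((i % 9) - 4),
                site_offset_ai_shift=0.0015 * ((i % 7) - 3),
                noise_inflation=1.0 + 0.04 * (i % 4),
            )
        )
    return sites


def _positive_normal(rng: np.random.Generator, mean, sd, shape) -> np.ndarray:
    """Normal draws truncated positive by redrawing offending cells."""
    x = rng.normal(mean, sd, shape)
    for _ in range(100):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(np.broadcast_to(mean, shape)[bad], np.broadcast_to(sd, shape)[bad])
    # pathological spec; clip the stragglers just above zero
    return np.where(x > 0, x, np.finfo(float).tiny)


def _clinical_frame(rng: np.random.Generator, n: int, ages: np.ndarray) -> pd.DataFrame:
    med = rng.choice(len(_MED_CLASSES), size=n, p=_MED_PROBS)
    onset = np.clip(rng.normal(23.0, 5.0, n), 12.0, ages - 0.5)
    duration = np.maximum(ages - onset, 0.0)
    cpz = np.round(np.exp(rng.normal(5.8, 0.6, n)), 1)  # ~330 mg/day median
    sans = np.clip(np.round(rng.normal(28.0, 14.0, n), 1), 0, 125)
    saps = np.clip(np.round(rng.normal(25.0, 14.0, n), 1), 0, 175)
    pos = np.clip(np.round(rng.normal(15.0, 5.0, n), 1), 7, 49)
    neg = np.clip(np.round(rng.normal(16.0, 5.5, n), 1), 7, 49)
    total = np.clip(pos + neg + np.round(rng.normal(30.0, 8.0, n), 1), 30, 210)
    return pd.DataFrame(
        {
            "medication_class": [_MED_CLASSES[i] for i in med],
            "cpz_equivalent_dose": cpz,
            "age_at_onset": np.round(onset, 1),
            "duration_of_illness": np.round(duration, 1),
            "sans_total": sans,
            "saps_total": saps,
            "panss_total": total,
            "panss_positive": pos,
            "panss_negative": neg,
        }
    )


def generate_cohort(
    catalog: RegionCatalog | None = None,
    sites: list[SiteSpec] | None = None,
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, EffectSpec]:
    """Simulate a multi-site bilateral ROI table.

    Returns the wide-format per-individual table (covariates, clinical
    columns for cases, then ``<measure>_L`` / ``<measure>_R`` pairs) and
    the ground-truth :class:`EffectSpec`, echoed unchanged.  Identical
    arguments and seed give an identical table.
    """
    catalog = catalog if catalog is not None else default_catalog()
    sites = sites if sites is not None else default_sites()
    effects = effects if effects is not None else EffectSpec.null()
    if not sites:
        raise ValueError("at least one site is required")

    rng = np.random.default_rng(seed)
    measures = catalog.measure_ids
    p = len(measures)
    base_mean = np.array([catalog.entry(m).baseline_bilateral_mean for m in measures])
    base_sd = np.array([catalog.entry(m).baseline_bilateral_sd for m in measures])
    base_ai = np.array([catalog.entry(m).baseline_mean_ai for m in measures])
    ai_sd = np.array([catalog.entry(m).baseline_ai_sd for m in measures])

    def vec(mapping: dict[str, float]) -> np.ndarray:
        unknown = set(mapping) - set(measures)
        if unknown:
            raise ValueError(f"unknown measure ids in effect spec: {sorted(unknown)}")
        return np.array([mapping.get(m, 0.0) for m in measures])

    d_true = vec(effects.d_true)
    dx_age = vec(effects.dx_by_age)
    age_slope = vec(effects.age_slope)
    sex_eff = vec(effects.sex_effect)
    med_eff = vec(effects.medication_effect)

    frames = []
    for site in sites:
        n = site.n_cases + site.n_controls
        if n == 0:
            continue
        dx = np.concatenate([np.zeros(site.n_controls), np.ones(site.n_cases)])
        male_frac = np.where(dx == 1, site.male_fraction_cases, site.male_fraction_controls)
        sex = (rng.random(n) < male_frac).astype(float)
        ages = np.clip(rng.normal(site.age_mean, site.age_sd, n), 16.0, 70.0)
        age_c = ages - _AGE_CENTER
        scanner_ids, props = zip(*site.scanners)
        scanner = rng.choice(len(scanner_ids), size=n, p=np.asarray(props))
        handed = np.where(rng.random(n) < 0.9, "R", "L")
        icv = rng.normal(1.45e6, 1.4e5, n)

        noise = site.noise_inflation
        M = _positive_normal(
            rng, base_mean * site.site_offset_mean_scale, base_sd * noise, (n, p)
        )
        A = (
            base_ai
            + site.site_offset_ai_shift
            + np.outer(age_c, age_slope)
            + np.outer(sex, sex_eff)
            + np.outer(dx, d_true * ai_sd)
            + np.outer(dx * age_c, dx_age)
        )

        clin = _clinical_frame(rng, n, ages)
        is_case = dx == 1
        first_gen = (clin["medication_class"].to_numpy() == "first_gen") & is_case
        A = A + np.outer(first_gen.astype(float), med_eff * ai_sd)
        for measure_id, (variable, r_true) in effects.clinical_assoc.items():
            j = measures.index(measure_id)
            v = clin[variable].to_numpy(dtype=float)
            z = np.where(is_case, (v - v[is_case].mean()) / max(v[is_case].std(), 1e-12), 0.0)
            coef = ai_sd[j] * r_true / np.sqrt(1.0 - r_true**2)
            A[:, j] += coef * z

        A = A + rng.normal(0.0, 1.0, (n, p)) * (ai_sd * noise)

        L = M * (1.0 + A / 2.0)
        R = M * (1.0 - A / 2.0)

        # data-entry artifacts: independent per hemispheric cell
        values = np.empty((n, 2 * p))
        values[:, 0::2] = L
        values[:, 1::2] = R
        u = rng.random((n, 2 * p))
        values[u < effects.zero_artifact_rate] = 0.0
        u2 = rng.random((n, 2 * p))
        values[u2 < effects.missing_rate] = np.nan

        cols = {}
        for j, m in enumerate(measures):
            cols[f"{m}_L"] = values[:, 2 * j]
            cols[f"{m}_R"] = values[:, 2 * j + 1]

        df = pd.DataFrame(
            {
                "individual_id": [f"{site.dataset_id}_{i:05d}" for i in range(n)],
                "dataset_id": site.dataset_id,
                "scanner_id": [scanner_ids[s] for s in scanner],
                "diagnosis": dx.astype(int),
                "age": np.round(ages, 2),
                "sex": sex.astype(int),
                "handedness": handed,
                "icv": np.round(icv, 1),
            }
        )
        clin = clin.where(pd.Series(is_case, index=clin.index), other=pd.NA)
        df = pd.concat([df, clin, pd.DataFrame(cols)], axis=1)
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)
    return table, effects


def write_bilateral_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_bilateral_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(effects: EffectSpec, path: str | Path) -> None:
    """Ground truth sidecar JSON next to the cohort CSV."""
    payload = dataclasses.asdict(effects)
    payload["clinical_assoc"] = {
        k: list(v) for k, v in payload["clinical_assoc"].items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
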