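"""Configuration-driven orchestration of the full analysis.

Stages mirror the distributed study design: ``simulate`` builds a
synthetic multi-site cohort (or an input CSV is supplied), ``ai``
computes asymmetry indices, ``sitewise`` fits the per-dataset models
(what each site would run locally), ``meta`` pools the per-site summary
statistics centrally, and ``mega`` runs the harmonized individual-level
multivariate arm.  Every stage output is a pure function of (inputs,
config, seed); a JSON manifest records versions, seed, config hash and
per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import AITable, build_ai_table, check_orientation
from .catalog import default_catalog
from .mega import run_mega
from .meta import meta_analyze_sites
from .simulate import (
    EffectSpec,
    default_sites,
    generate_cohort,
    read_bilateral_csv,
    write_bilateral_csv,
    write_ground_truth,
)
from .sitewise import fit_all_sites

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "ai", "sitewise", "meta", "mega")


@dataclass
class RunConfig:
    """Validated run configuration (see module docstring for stages)."""

    out_dir: str = "results"
    input_csv: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    models: tuple[str, ...] = ("m1",)
    seed: int = 0
    n_perm: int = 10_000
    fdr_alpha: float = 0.05
    vif_threshold: float = 5.0
    min_total_base: int = 10
    min_group: int = 5
    outlier_threshold: float = 2.5
    n_sites: int = 14
    cases_per_site: int = 75
    controls_per_site: int = 75
    include_case_only: bool = False
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for name in ("vif_threshold", "outlier_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _effect_spec(config: RunConfig) -> EffectSpec:
    eff = dict(config.effects)
    if "clinical_assoc" in eff:
        eff["clinical_assoc"] = {k: tuple(v) for k, v in eff["clinical_assoc"].items()}
    return EffectSpec(**eff)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog()
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    table = None
    if "simulate" in config.stages and config.input_csv is None:
        sites = default_sites(
            n_sites=config.n_sites,
            cases_per_site=config.cases_per_site,
            controls_per_site=config.controls_per_site,
            include_case_only=config.include_case_only,
        )
        table, effects = generate_cohort(catalog, sites, _effect_spec(config), config.seed)
        write_bilateral_csv(table, out / "cohort.csv")
        write_ground_truth(effects, out / "ground_truth.json")
        manifest["stages"]["simulate"] = {"rows": int(len(table))}
    elif config.input_csv is not None:
        table = read_bilateral_csv(config.input_csv)
        manifest["stages"]["input"] = {"rows": int(len(table)), "path": config.input_csv}
    if table is None:
        raise ValueError("no input: enable the simulate stage or provide input_csv")

    ai_table: AITable | None = None
    if {"ai", "sitewise", "meta", "mega"} & set(config.stages):
        ai_table = build_ai_table(table, catalog)
        flagged = check_orientation(ai_table)
        ai_table.write(out / "ai_table.csv")
        manifest["stages"]["ai"] = {
            "rows": int(len(ai_table.data)),
            "measures": len(ai_table.measure_ids),
            "orientation_flags": flagged,
        }

    site_summary = None
    if {"sitewise", "meta"} & set(config.stages):
        parts = []
        for model_id in config.models:
            parts.append(
                fit_all_sites(
                    ai_table.data,
                    ai_table.measure_ids,
                    model_id=model_id,
                    min_total_base=config.min_total_base,
                    min_group=config.min_group,
                    vif_threshold=config.vif_threshold,
                )
            )
        site_summary = pd.concat(parts, ignore_index=True)
        site_summary.to_csv(out / "site_effects.csv", index=False)
        manifest["stages"]["sitewise"] = {
            "rows": int(len(site_summary)),
            "skipped": int(site_summary["skipped"].sum()),
        }

    if "meta" in config.stages:
        parts = []
        for model_id in config.models:
            families = ai_table.families if model_id == "m1" else None
            parts.append(meta_analyze_sites(site_summary, families, model_id=model_id))
        meta_results = pd.concat(parts, ignore_index=True)
        meta_results.to_csv(out / "meta_results.csv", index=False)
        n_sig = int((meta_results["q"] < config.fdr_alpha).sum())
        manifest["stages"]["meta"] = {"rows": int(len(meta_results)), "fdr_significant": n_sig}

    if "mega" in config.stages:
        cc = table
        if "diagnosis" in cc.columns:  # mega arm needs case-control datasets only
            counts = cc.groupby("dataset_id")["diagnosis"].nunique()
            cc = cc[cc["dataset_id"].isin(counts[counts == 2].index)]
        mega = run_mega(cc, catalog, n_perm=config.n_perm, seed=config.seed)
        (out / "mega_report.json").write_text(json.dumps(mega["mancova"], indent=2))
        mega["univariate"].to_csv(out / "mega_univariate.csv", index=False)
        manifest["stages"]["mega"] = {
            "n_individuals": mega["mancova"]["n_individuals"],
            "p_perm": mega["mancova"]["p_perm"],
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
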