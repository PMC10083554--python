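"""Per-dataset models, effect-size conversion, and REML meta-analysis.

Each dataset is analyzed separately (AI ~ diagnosis + sex + age, plus
scanner dummies), the diagnosis t is converted to Cohen's d with SE and
CI, and effects are pooled across datasets with a random-effects REML
model; Benjamini-Hochberg FDR is applied within each measure family.
"""

from brainasym import (
    EffectSpec,
    build_ai_table,
    default_catalog,
    default_sites,
    fit_all_sites,
    generate_cohort,
    meta_analyze_sites,
    outlier_sensitivity,
)

catalog = default_catalog()
sites = default_sites(n_sites=10, cases_per_site=120, controls_per_site=120)
effects = EffectSpec(d_true={"thick_rostralanteriorcingulate": -0.2})
table, _ = generate_cohort(catalog, sites, effects, seed=6)
ai = build_ai_table(table, catalog)

thickness = ai.family_members("thickness")
summary = fit_all_sites(ai.data, thickness, "m1")
print(f"site-level fits: {len(summary)} rows "
      f"({int(summary['skipped'].sum())} skipped by eligibility rules)")

meta = meta_analyze_sites(summary, ai.families).sort_values("p")
top = meta.head(3)[["measure_id", "k", "d", "se", "z", "p", "q", "tau2", "I2"]]
print("\nsmallest-p thickness asymmetries (pooled over datasets):")
print(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
# d is the pooled case-control difference in SD units of the AI (negative
# = less leftward in cases); q is the BH-FDR-adjusted p within the
# 35-member thickness family; tau2 and I2 quantify between-site heterogeneity.

hit = summary[summary["measure_id"] == "thick_rostralanteriorcingulate"]
flagged, repooled, full = outlier_sensitivity(hit[~hit["skipped"]])
print(f"\noutlier screen on the top region: {len(flagged)} dataset(s) flagged; "
      f"d = {full.d:+.3f} (all) vs {repooled.d:+.3f} (outliers removed)")
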