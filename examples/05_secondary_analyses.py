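"""Interaction scans, medication contrasts, and clinical correlations.

Secondary analyses reuse the sitewise + meta machinery: interaction-term
t statistics go through the same Cohen's d conversion and REML pooling,
and within-case clinical correlations are pooled on the Fisher-z scale.
"""

from brainasym import EffectSpec, build_ai_table, default_catalog, default_sites, generate_cohort
from brainasym.secondary import (
    clinical_correlation_scan,
    medication_contrast,
    run_interaction_scan,
    within_group_age_trends,
)

catalog = default_catalog()
sites = default_sites(n_sites=10, cases_per_site=120, controls_per_site=120)
effects = EffectSpec(
    dx_by_age={"vol_pallidum": 0.004},  # AI units per year, cases only
    medication_effect={"thick_middletemporal": -0.5},
    clinical_assoc={"thick_rostralanteriorcingulate": ("sans_total", 0.2)},
)
table, _ = generate_cohort(catalog, sites, effects, seed=5)
ai = build_ai_table(table, catalog)

scan = run_interaction_scan(ai.data, ai.family_members("subcortical"), "dx_by_age")
hit = scan.set_index("measure_id").loc["vol_pallidum"]
print(f"diagnosis-by-age interaction, pallidum volume AI: "
      f"d = {hit['d']:+.3f}, z = {hit['z']:.2f}, q = {hit['q']:.2g}")

trends = within_group_age_trends(ai.data, "vol_pallidum")
for group, r in trends.items():
    print(f"  pallidum AI-age partial correlation, {group}: r = {r.d:+.3f} (p = {r.p:.2g})")

med = medication_contrast(ai.data, ["thick_middletemporal", "thick_cuneus"])
row = med.set_index("measure_id").loc["thick_middletemporal"]
print(f"first- vs second-generation antipsychotics, middle temporal AI: "
      f"d = {row['d']:+.3f} [{row['d'] - 1.96 * row['se']:+.3f}, "
      f"{row['d'] + 1.96 * row['se']:+.3f}]")

clin = clinical_correlation_scan(
    ai.data, ["thick_rostralanteriorcingulate"], ["sans_total", "panss_total"]
)
print("\nwithin-case clinical correlations (Fisher-z pooled):")
print(clin.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
# A positive r here means higher negative-symptom scores go with a more
# leftward (or less rightward) asymmetry.
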