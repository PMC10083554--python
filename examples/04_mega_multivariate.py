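"""Harmonized multivariate mega-analysis on pooled individual-level data.

Left and right measures are ComBat-harmonized per batch (dataset x
scanner, preserving diagnosis/age/sex), AIs are recomputed, and the 76
regional AIs are tested jointly against diagnosis with a MANCOVA
(Wilks' Lambda, Rao's F) plus a stratified label-swapping permutation
test that conserves case/control counts within every batch.
"""

from brainasym import EffectSpec, default_catalog, default_sites, generate_cohort, run_mega

catalog = default_catalog()
sites = default_sites(n_sites=8, cases_per_site=100, controls_per_site=100)
effects = EffectSpec(d_true={"vol_pallidum": 0.2, "thick_middletemporal": -0.15})
table, _ = generate_cohort(catalog, sites, effects, seed=4)

res = run_mega(table, catalog, n_perm=2000, seed=4)
rep = res["mancova"]
print(f"N = {rep['n_individuals']} ({rep['n_cases']} cases, {rep['n_controls']} controls)")
print(f"Wilks' Lambda = {rep['lambda']:.4f}  ->  "
      f"F({rep['df1']}, {rep['df2']}) = {rep['F']:.3f}")
print(f"variance in asymmetry linked to diagnosis: {100 * rep['variance_explained']:.1f}%")
print(f"nominal p = {rep['p_nominal']:.2e}; permutation p = {rep['p_perm']:.4g} "
      f"({rep['n_exceed']} of {rep['n_perm']} permuted F >= observed)")
print(f"max |pairwise AI correlation| = {rep['max_abs_pairwise_ai_correlation']:.3f}")
print("\ntop univariate ANCOVA contributions:")
print(res["univariate"].head(4).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
# The injected pallidum and middle-temporal effects should top this
# ranking; the permutation p agrees with the nominal p when the model
# assumptions hold.
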