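# Methods

This note documents the statistical models implemented in `brainasym`, the
choices made where the design was genuinely open, and what the synthetic-data
suite does and does not demonstrate.

## Asymmetry indices

For paired left/right measures the asymmetry index AI = (L − R)/((L + R)/2)
is used throughout; the denominator removes the automatic scaling of a raw
difference with overall structure size, making AIs comparable across regions
and individuals and bounded in (−2, 2) for positive measures. Cleaning
precedes AI computation: a hemispheric value of exactly 0 is interpreted as a
data-entry error and set to missing, and a missing hemisphere blanks its
partner, so every AI is computed from two positive measurements or not at
all. Negative raw measures are rejected loudly rather than blanked — zeros
are a known entry-error mode, negatives indicate corrupted input and should
stop a pipeline, not be silently imputed.

Orientation QC: left/right flips at acquisition or conversion manifest as a
sign-reversed dataset-mean AI on strongly lateralized measures. The package
implements a conservative heuristic — a dataset whose mean AI on a reference
measure (by default the measure with the largest cohort-mean |AI|) opposes
the cohort consensus sign is flagged with a warning, never auto-flipped.
This is a stand-in for manual orientation review, not a validated detector.

## Per-dataset models and effect-size conversion

Each dataset is modeled separately by OLS (primary model: AI ~ diagnosis +
sex + age, with n−1 scanner dummies in multi-scanner datasets). Eligibility:
total usable N ≥ 10 + #scanner dummies and both diagnostic groups ≥ 5;
ineligible fits are returned as skipped values with reasons, not errors.
Complete-case handling is per model: rows missing a covariate used by one
model variant are dropped for that variant only. VIF (on the non-intercept
design columns, dummies included) > 5 flags a fit but never drops terms.

Open choices fixed here: scanner-dummy reference level is the
lexicographically first scanner id; diagnosis is coded control = 0 / case = 1
so negative d means less leftward (more rightward) asymmetry in cases; the
age² covariate of model 5 uses centered age before squaring (conditioning);
interaction models (8, 9) center age within dataset, which leaves the
interaction t invariant while improving conditioning; the medication model
(6) is fit among cases only with medication class (first/second generation,
both, none) dummy-coded against second-generation, and the
first-vs-second-generation dummy's t is the extracted contrast.

The t → d conversion is d = t(n₁+n₂)/(√(n₁n₂)√df) with df the residual
degrees of freedom. Algebraically this equals the group mean difference
divided by the pooled SD computed with denominator N (residual SS over N),
which is the oracle the tests check exactly; with covariates present it is
the standard approximation that inflates slightly as df falls below N. The
standard error and CI follow the usual large-sample d formulas (se grows
with |d| through the 1 + d²/8 term).

## Random-effects meta-analysis

Per-measure pooling uses the normal–normal model d_i ~ N(μ, se_i² + τ²). τ²
is estimated by restricted maximum likelihood via Fisher scoring on the
restricted log-likelihood (tolerance 1e-8 on the τ² step, max 100
iterations, floored at 0), initialized at the DerSimonian–Laird estimate and
falling back to it with a logged warning if scoring fails to converge —
this matches the named estimator while guaranteeing termination. Inference
is Wald z on the pooled effect (no Knapp–Hartung adjustment, since z
statistics are the reporting convention here); Q and I² use fixed-effect
weights. The implementation is verified against a restricted-likelihood
grid search and against `metafor::rma` (REML) to that package's own
convergence tolerance.

Meta-regression estimates τ² by bounded scalar maximization of the
restricted log-likelihood (Brent; upper bound 10·max(se²) ∨ 10·var(d)) —
more robust than scoring for arbitrary moderator designs — and tests all
moderator coefficients jointly with a Wald chi-square. A constant moderator
is a skip, not an error.

Outlier sensitivity: the exact published screening rule is not public, so
the package uses a declared, configurable stand-in — a dataset is flagged
when its externally studentized deleted residual (effect minus the
leave-one-out pooled estimate, scaled by sampling + between-dataset +
estimation variance) exceeds 2.5 in absolute value; the meta-analysis is
reported both with and without flagged datasets.

Multiplicity: Benjamini–Hochberg step-up within measure families — 35
thickness, 35 area, 8 subcortical for the primary analysis; each secondary
scan adjusts over all AIs it tested. BH is delegated to
`statsmodels.stats.multitest`, with the brute-force step-up definition kept
as the test oracle.

Correlations (within-case clinical associations, within-group age trends)
are computed per dataset as partial correlations — residualizing both
variables on age and sex (clinical) or sex (age trends) — then pooled on
the Fisher-z scale with variance 1/(n − 3 − k) for k conditioning
covariates, using the same REML engine, and back-transformed. Raw Pearson
is available by passing no confounds; partial correlation is the default
interpretation because pooled r alongside covariate-adjusted models is the
reporting convention being mirrored.

## Harmonized multivariate arm

ComBat: parametric empirical-Bayes location/scale harmonization. Features
are standardized against the batch + covariate least-squares fit, per-batch
location (γ) and scale (δ²) estimates are shrunk toward batch-level normal
and inverse-gamma priors by iterative conditional modes (relative-change
tolerance 1e-4), batch effects are removed and covariate structure
(diagnosis, age, sex) restored. Left- and right-hemisphere matrices are
harmonized in separate calls, and AIs are recomputed from harmonized
measures — AIs are never harmonized directly. Singleton batches and
within-batch constant features are rejected. The implementation matches
Bioconductor `sva::ComBat` to ~1e-4 relative on shared inputs.

A note on idempotence: empirical-Bayes shrinkage leaves a residual batch
offset of the order of the shrinkage bias, so re-applying harmonization
changes the data slightly (~5e-4 relative RMS; the reference implementation
behaves identically). The tests therefore assert that re-application is a
strong contraction (< 1e-3 relative RMS and ≥ 50× smaller than the first
pass) rather than exact idempotence, which is not a property of the method.

Post-harmonization QC drops individuals assigned a non-positive adjusted
value on any subcortical volume (a harmonization artifact) and enforces
complete data across all 76 paired regional measures. A correlation screen
reports the maximum absolute pairwise AI correlation and warns above 0.5.

MANCOVA: the 76 regional AIs (hemispheric averages excluded) are tested
jointly against diagnosis with age and sex as covariates. Wilks'
Λ = det(E)/det(E+H); for this single-df hypothesis H has rank 1 and
Λ = 1 − hᵀ(E+H)⁻¹h/s with h the covariate-residualized cross-product and s
the residualized diagnosis sum of squares — the determinant and rank-one
routes agree to machine precision and the latter powers the permutation
loop. Rao's F = ((1−Λ)/Λ)(df₂/df₁), df₁ = p = 76,
df₂ = N − rank(design) − p + 1, is exact in form for a one-df hypothesis;
1 − Λ is reported as the variance in asymmetry linked to diagnosis.

Permutation test: diagnosis labels are permuted only within dataset ×
scanner strata, conserving each stratum's case/control counts on every
draw; single-class strata are no-ops (logged). The permutation p is the
plain count of permuted F ≥ observed F over n_perm — a zero count reports
p = 0 with a logged caveat about the 1/n_perm resolution, by deliberate
fidelity to the count/n convention rather than the (count+1)/(n+1) form.
Permutation streams are counter-based (Philox keyed on seed and permutation
index), so the same seed and n_perm give an identical p-value regardless of
chunking or execution order; the default n_perm is 10,000 for desk-scale
runs, with 10⁶ a configuration value.

## Synthetic cohorts and what the tests show

The generator draws, per individual and region, a latent bilateral size
M ~ N(baseline_mean × site_scale, baseline_sd × noise_inflation) truncated
positive, and a latent asymmetry A = baseline mean AI + site shift + age and
sex terms + diagnosis term + diagnosis × age term + noise, then sets
L = M(1 + A/2), R = M(1 − A/2), so the AI formula returns A exactly and
every downstream stage has an analytic oracle. Diagnosis effects are
specified in Cohen's d units and converted via the region's nominal AI
noise SD; because site noise inflation and covariate terms add variance,
realized pooled d̂ is mildly attenuated (~10% at default settings), which
the recovery checks absorb within their CI-coverage criterion. Missing
values and exact-zero artifacts are injected per hemispheric cell at stated
rates after construction. Age slopes act on age − 33 (a cohort-typical mean
age), interaction slopes are AI units per year among cases, clinical
associations are injected to hit a target within-case correlation, and the
medication contrast shifts first-generation users by a stated d.

Default scales: 14 sites × ~150 individuals for desk-scale suites
(mirroring the individual-level subsample), 45 sites totalling ~10,700 for
consortium-scale recovery runs; baseline AI magnitudes are
order-of-magnitude (|AI| ≤ 0.05 thickness, ≤ 0.1 area/volume, SDs
0.05–0.1) since per-region values are not published numerically, and all
are configurable through the region catalog.

What passing tests do not show: the generator draws independent Gaussian
regions (no spatial covariance between AIs, no heavy tails, no site-specific
segmentation failure modes beyond zeros/missingness), sites differ only by
affine offsets and noise inflation, and clinical variables are synthetic
instruments. Calibration and recovery on these cohorts validate the
statistical machinery, not the behavior of real multi-scanner MRI data.

## Problem sizes used by the standard runs

Null calibration uses 200 cohorts (14 sites, ~2,000 individuals) × 1,000
stratified permutations, with AIs taken directly from the cohort (no ComBat
pass — the stratified permutation is valid under site offsets, and the
check targets the permutation test's calibration, not harmonization).
Recovery uses 20 replicates of 45 sites (~10,700 individuals) with
d = −0.08 on two thickness AIs, fitting the full 35-member thickness family
so within-family FDR ranking is meaningful. Oracle-equivalence checks use
100 random 10-study meta-analyses (τ² grid resolution ≈ 2×10⁻⁴), 1,000
random p-vectors, and 50 simulated two-group fits.

## Known limitations

No Knapp–Hartung small-k adjustment; no publication-bias machinery; the
non-parametric ComBat variant is out of scope; MANCOVA requires N > p +
rank(design) (no regularized covariance for p > N); the outlier rule and
orientation flag are declared stand-ins, configurable but not validated
against the original procedures; and the univariate and multivariate arms
share individuals when run on the same cohort, as in the design being
mirrored.
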