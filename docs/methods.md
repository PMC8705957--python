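# Methods

`hepiron` re-implements, as a tested pipeline, a sex-stratified analysis of
MRI-derived hepatic iron content (HIC) in a population-based imaging cohort:
descriptive contrasts, threshold classifications, bootstrap-LASSO stability
selection of associated factors, a weighted genetic risk score, and
unpenalized follow-up regressions.  Because the underlying participant-level
data are access-restricted, the package ships a calibrated synthetic-data
generator that reproduces the *statistical structure* the analysis assumes;
everything downstream is exercised against it.

## Outcome and units

HIC is the transverse relaxation rate R2* = 1/T2* in s⁻¹, averaged over the
right and left hepatic lobe; higher values mean more stored iron.  Hepatic
fat fraction (HFF) is a percentage in [0, 100].  The outcome is never
standardized anywhere in the pipeline, so every coefficient is reported in
s⁻¹ per exposure unit.

## Synthetic cohort generator (`hepiron.simulate`)

**Marginals.** Each covariate of the descriptive panel has a per-sex
marginal: Normal(µ, σ) for symmetric variables, lognormal parameterised by
(median, IQR) for skewed ones (σ_log = asinh(IQR/2·median)/z₀.₇₅),
Bernoulli for binary flags, and categorical for diabetes and smoking
status.  Default parameters are the published per-sex descriptive values.
Physiologically impossible tails are truncated (e.g. HFF at 100 %, alcohol
at 150 g/day — a lognormal matched to a median of 3.1 and IQR of 12.8 g/day
otherwise produces >300 g/day draws).

**Dependence.** A Gaussian copula on latent normals induces Spearman rank
correlations between covariates; targets are translated to latent Pearson
correlations by r = 2·sin(πρ_S/6) and the target matrix is repaired to the
nearest positive semi-definite correlation matrix by eigenvalue clipping
(targets requiring a repair beyond eigenvalue −0.25 are rejected as
inconsistent).  Only a sparse block structure of physiologically motivated
pairs is specified (body-composition cluster, lipids, liver enzymes,
glucose metabolism, blood pressure, renal markers, blood count); all other
pairs are independent.  These are free parameters of the emulation, not
fitted quantities.

**Outcome model.** HIC = intercept + Σ β_k·x_k + ε with ε Gaussian, where
x_k is on the analysis scale (natural log for log-flagged variables).
Default ground-truth effects are the published age-adjusted follow-up
coefficients — men: log-HFF 1.46, alcohol 0.02 s⁻¹ per g/day, HbA1c −1.44;
women: log-HFF 2.08, alcohol 0.05, plus a direct age effect of
0.22 s⁻¹/year (= 0.48·4.1/9.0) so that the female age–HIC rank correlation
emerges at its reported value of ≈0.48.  All other covariates are null,
which makes the "true" signal set explicit for recovery experiments.  In
the default *calibrated* mode the generator centres the linear predictor on
the target mean (41.8 s⁻¹ men, 39.2 s⁻¹ women) and fills the residual
variance up to the target SD (4.7 / 4.1 s⁻¹); coefficients are never
rescaled, so OLS on generated data recovers them.  An *explicit* mode
(intercept + residual SD) exists for controlled experiments.  Lobe values
are disaggregated as value ± d/2 with Gaussian d, so the lobe mean is exact.

**Emergent (not imposed) calibration checks** at the default configuration:
steatosis prevalence ≈59 % men / ≈30 % women (printed: 62.6 / 29.9), mild
iron overload ≈47 % overall (printed: 44.5), HFF–HIC rank correlation ≈0.30
men / ≈0.43 women (printed: 0.32 / 0.51).  The male age–HIC correlation is
≈0 by construction (the published value, 0.11, was not significant).

**Genotypes.** Allele dosages are Hardy–Weinberg Binomial(2, f) hard calls
(optionally with bounded imputation noise), independent across SNPs — no
linkage disequilibrium is simulated.  The default panel carries the four
named iron-metabolism variants (HFE rs1799945, rs1800562; TMPRSS6 rs855791,
rs4820268) at European allele frequencies with per-sex effects chosen so the
published strongest-in-men / strongest-in-women pattern holds.  When a panel
is configured, centred SNP effects enter the outcome's linear predictor.

**Missingness.** `inject_missingness` blanks the iron measurement (40 % of
cases) or one random candidate covariate (60 %) for exactly n uniformly
chosen participants, emulating the published participant flow
(400 scanned − 47 excluded = 353 analysed).

**What the generator does *not* emulate** — and hence what passing tests do
not establish about real data: measurement error in MRI quantification,
non-Gaussian residual structure of HIC, LD between variants, informative
(non-random) missingness, selection effects of the imaging sub-study, and
any inter-covariate dependence beyond the specified rank-correlation pairs.

## Descriptive layer (`hepiron.descriptives`)

Mean ± SD with Welch's t-test for symmetric continuous variables, median
(IQR, type-7 quantiles) with the Mann–Whitney U test for skewed ones
(auto-routing threshold |skew| > 1, or the catalog's log flag), counts and
χ² without continuity correction for categoricals.  `welch_t_from_summary`
reproduces the Welch statistic from printed summaries alone (Satterthwaite
df), which is what makes the headline sex contrast verifiable without data.
All p-values are two-sided and uncorrected for multiple testing, matching
the exploratory character of the original analysis.  The published t-tests
do not state an equal-variance assumption; Welch is used throughout because
it is the safer default and is forced anyway on the summary-statistic route.

## Threshold classifications (`hepiron.classify`)

Iron overload grades: none ≤ 41 < mild < 62.5 ≤ moderate < 70.1 ≤ severe
(s⁻¹).  Only the 41 s⁻¹ boundary's direction (strict ">") is printed; the
two upper cutoffs are treated as inclusive lower bounds of their grade.
Steatosis: HFF ≥ 5.6 % (inclusive).  Glycemic status: physician-diagnosed
diabetes dominates; otherwise configurable ADA-style bands (fasting ≥ 126
or 2h ≥ 200 mg/dL or HbA1c ≥ 6.5 % → diabetes; 100–125 / 140–199 / 5.7–6.4
→ prediabetes), since the source analysis cites status without defining the
operational rule.  The exclusion filter is a complete-case filter over the
iron outcome and all candidate covariates, with a per-participant reason
log; it is idempotent.

## Stability selection (`hepiron.lasso`)

**Design.** Candidate variables are dummy-coded against the reference level
(largest group), log-flagged variables natural-log transformed (exact zeros
shifted by half the minimum positive value), and every column standardized.
Zero-variance columns are rejected by name.  Dummies are penalized
individually — no group penalty — so a single level (e.g. prediabetes) can
be selected on its own.  No variables are forced in by default (per-column
penalty weights support it when wanted).

**Solver.** The LASSO objective (1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁ with an
unpenalized intercept is minimized by cyclic coordinate descent with
soft-thresholding in a covariance-update (Gram) formulation; convergence is
declared when no coefficient moves more than 1e-8 in a full sweep.  Along a
penalty path the sequential strong rule screens coordinates (with exact KKT
back-checking), and an active-set Newton step — solving the stationarity
system on the current active set with sign-flip dropping — accelerates the
dense end of the path.  Neither device changes the solution: every solve is
confirmed by ordinary sweeps at the stated tolerance, and the test suite
checks the solver against the orthonormal-design closed form, brute-force
objective minimization, KKT conditions, and an independent reference
implementation.

**Penalty tuning.** The grid has 100 log-spaced points from
λ_max = max_j |x_jᵀ(y − ȳ)|/n down to 10⁻³·λ_max.  λ is tuned per bootstrap
resample by 10-fold cross-validation (seeded random permutation folds,
fold-level centring) under the CV-minimum rule; the conservative
one-standard-error rule is available as `lambda_rule="1se"`.  CV-min is the
default because "optimized" reads as argmin and because the resulting
liberal selection matches the scale of the published output (15–16
variables per sex above the 20 % threshold).  Note that cross-validating
*inside* a bootstrap resample lets duplicated rows leak between folds,
biasing λ low; this is a property of the published procedure that the
package reproduces deliberately.

**Bootstrap inclusion.** For b = 1…B (default 1000): resample n rows with
replacement (seed stream (seed, b)), re-standardize within the resample
(selection is scale-dependent otherwise; columns degenerating to zero
variance are dropped for that resample, logged, and counted as not
included), cross-validate λ, fit at λ*, and mark variables with |β_j| >
1e-12 (coordinate descent produces exact zeros; the tolerance is a guard).
The inclusion frequency π_j is the fraction of resamples with a nonzero
coefficient; variables with π_j strictly above 0.20 are deemed relevant and
reported in descending π.  The whole procedure is bitwise-reproducible
under a fixed seed and independent of the parallelism level.

**A caveat on ranking.** In a fixed cohort of ~200 with ~50 candidates,
null covariates acquire chance correlations with the outcome of up to
|r| ≈ 0.2 — comparable to the weakest true effects (alcohol in men
contributes ≈0.13 SD).  Inclusion frequencies therefore cannot reliably
rank every true signal above every null at these effect sizes and sample
sizes; the recovery suite documents the achieved separation rate rather
than hiding it.

## Genetic risk score (`hepiron.grs`)

Per-SNP weights are slopes of sex-stratified univariate OLS regressions of
HIC on allele dosage (intercept, no covariates); monomorphic SNPs get
weight 0 with a warning.  The score is Σ_j w_j(sex)·dosage_ij, so it is in
s⁻¹.  As in the source analysis, weights are by default estimated on the
same cohort they score; `fit(weight_cohort=...)` provides a split-sample
mode.  Quartiles are computed within sex by midrank with stable-id
tie-breaking, so group sizes differ by at most one even under heavy ties;
the Q1-vs-Q4 contrast is a Welch t-test.  `append_to` adds the continuous
score as one candidate column for the selection stage.

## Follow-up regressions (`hepiron.regression`)

For every selected variable, plain OLS of HIC on the exposure, adjusted for
age and for age + log-HFF (HFF itself: age only; age itself: no own row —
it is in every adjustment set).  Reported: unstandardized β, 95 % t-interval,
two-sided p, and the full model's adjusted R² (not the exposure's partial
R²).  Log transforms are natural log with the same zero-shift rule as the
design stage; sodium's transform is taken as natural log as well.  No
robust standard errors.

## Pipeline and reproducibility (`hepiron.pipeline`, `hepiron.cli`)

`run_pipeline` executes generate/load → exclude → classify → descriptives →
per-sex stability selection (per analysis variant: main, exclude-HFF,
with-GRS, OGTT subsample) → GRS → follow-up tables, writing
publication-shaped CSVs and a manifest (config hash, seed, versions — no
timestamp, so identical config + seed yields byte-identical run
directories).  All randomness derives from one seed, split per stage and
per bootstrap, so results are independent of `--jobs`.  The CLI verbs are
`generate`, `run`, `report`; plotting is out of scope — the run directory
contains plot-ready tables instead of images.

## Problem sizes used in the test suite

The recovery experiments are desk-scaled by design: stability recovery uses
B = 200 bootstraps over 20 replicate cohorts at the study's n = 353;
the GRS selection check uses B = 100; weight recovery uses n = 5000 with a
small residual SD (0.25 s⁻¹), because at the full outcome noise the
univariate slope's sampling error alone (SE ≈ 0.02 s⁻¹ for a 6 %-frequency
variant) exceeds the 5 % recovery band around 0.65 s⁻¹ — the check is a
consistency check of the estimator, not a power claim.  CI coverage is
assessed over 1000 replicates at n = 150.

## Known limitations

- The published candidate list and SNP panel (appendix material) are not
  reproduced; the catalog defaults to the full descriptive panel and the
  four named variants, both user-overridable.
- Cohort-dependent published numbers (inclusion frequencies, exact
  regression tables) are not reproducible without the restricted data; the
  package validates structure, calibration and recovery instead.
- The generator's independence assumptions (no LD, sparse covariate
  dependence, random missingness) are idealisations; see above.
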