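# hepiron

Sex-stratified analysis of MRI-derived hepatic iron content (HIC) for
population-based imaging cohorts: calibrated synthetic cohort generation,
descriptive statistics, iron-overload/steatosis classification,
bootstrap-LASSO stability selection of associated factors, a weighted
genetic risk score, and unpenalized follow-up regressions.

## The problem

Hepatic iron overload damages the liver long before symptoms appear, and
biopsy-based assessment is infeasible at population scale.  Multi-echo MRI
measures the transverse relaxation rate R2\* = 1/T2\* (s⁻¹), a validated
surrogate for stored liver iron, alongside the hepatic fat fraction (HFF,
%).  Given a cohort table of R2\* outcomes and a broad covariate panel
(body composition, lipids, glucose markers, renal markers, blood count,
electrolytes, blood pressure, liver enzymes, behaviour, medication), the
question is: *which factors are robustly associated with hepatic iron, and
do the associations differ between men and women?*

Because single unpenalized regressions over ~50 correlated candidates are
unstable, relevance is assessed by **stability selection**: the LASSO

&nbsp;&nbsp; minimize&nbsp; (1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁

is refitted on B bootstrap resamples of each sex stratum, with the penalty
λ tuned per resample by 10-fold cross-validation.  Each variable j is
scored by its **inclusion frequency** π_j — the fraction of resamples in
which β̂_j ≠ 0 — and variables with π_j > 20 % are deemed relevant.  A
continuous **genetic risk score** GRS_i = Σ_j w_j·d_ij (sex-specific
univariate regression weights w_j times allele dosages d_ij ∈ [0,2]) enters
the same selection.  Selected variables are then quantified by plain OLS
adjusted for age and for age + log-HFF, reported as unstandardized β with
95 % CI, p, and adjusted R².

Participant-level data of this kind are access-restricted, so the package
includes a first-class synthetic generator (Gaussian copula over per-sex
marginals, linear outcome model with published effect sizes as ground
truth) that makes every stage testable end-to-end.  See
`docs/methods.md` for the full model description.

## Worked example

```python
import hepiron
from hepiron.cohort import VariablePanel
from hepiron.lasso import StabilitySelection, LassoConfig

cohort = hepiron.generate_cohort(hepiron.default_study_config(), seed=1)
male, female = cohort.stratify_by_sex()
print(f"male HIC:   {male.data['hic'].mean():.1f} ± {male.data['hic'].std():.1f} s^-1  (n={male.n})")
print(f"female HIC: {female.data['hic'].mean():.1f} ± {female.data['hic'].std():.1f} s^-1  (n={female.n})")

t = hepiron.welch_t_from_summary(41.8, 4.7, 206, 39.2, 4.1, 147)
print(f"printed-summary Welch test: t={t.statistic:.2f}, df={t.df:.0f}, p={t.p:.1e}")

sel = StabilitySelection.from_cohort(
    female, VariablePanel.default(cohort.catalog),
    config=LassoConfig(n_bootstrap=200, seed=1)).fit()
print(sel.summary())
```

prints

```
male HIC:   41.9 ± 5.0 s^-1  (n=206)
female HIC: 39.0 ± 4.1 s^-1  (n=147)
printed-summary Welch test: t=5.52, df=337, p=6.7e-08
Bootstrap stability selection (B=200, threshold>20%)
...
age                                    1.000  *
log(hff)                               1.000  *
alcohol                                0.885  *
lipid_lowering                         0.740  *
...
```

The generated strata match their calibration targets (41.8 ± 4.7 and
39.2 ± 4.1 s⁻¹); the Welch test reproduces the headline sex contrast from
printed summaries alone (p < 0.001); and the female stability run ranks the
generator's true signals — age, log hepatic fat and alcohol — at the top,
alongside liberally co-selected null covariates, which is the expected
behaviour of per-bootstrap CV-tuned LASSO at these effect sizes.

The whole pipeline (exclusions, Table-1-style descriptives, per-sex
selection with analysis variants, GRS, follow-up tables, manifest) runs
from a single config:

```bash
hepiron run --outdir runs/demo --seed 1 --bootstrap 200
hepiron report --rundir runs/demo
```

## Layout

| path                | contents                                            |
|---------------------|-----------------------------------------------------|
| `hepiron.cohort`    | participant table, variable catalog, stratification |
| `hepiron.simulate`  | copula cohort generator, genotypes, missingness     |
| `hepiron.descriptives` | summaries, two-group tests, Spearman, Table 1    |
| `hepiron.classify`  | overload grades, steatosis, glycemia, exclusions    |
| `hepiron.lasso`     | design building, coordinate descent, CV, stability  |
| `hepiron.grs`       | dosage matrix, weights, scores, quartile contrasts  |
| `hepiron.regression`| adjusted OLS follow-up models                       |
| `hepiron.pipeline` / `hepiron.cli` | orchestration and shell interface    |
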