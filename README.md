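# lungrisk

A two-stage genetic risk score (GRS) pipeline for lung-cancer
case-control studies, built for epidemiologists who want to combine a
panel of published susceptibility SNPs with smoking history into a
single risk-prediction model — and to test, end to end, whether the
genetics adds anything to smoking alone.

The pipeline mirrors the standard two-stage design:

1. **SNP quality control** — imputation INFO ≥ 0.8, control minor
   allele frequency ≥ 0.05, Hardy-Weinberg exact-test p ≥ 0.05 in
   controls, and windowed LD pruning (r² ≥ 0.5 within 200 kb, keeping
   the most significant SNP of each correlated group).
2. **Univariate screening** — per-allele additive logistic regression
   of case status on each SNP's dosage; keep p < 0.05.
3. **LASSO selection** — L1-penalized logistic regression over the
   screened SNPs (coordinate descent, KKT-certified solutions,
   cross-validated λ), yielding a sparse per-allele weight vector β.
4. **Scoring** — each sample's genetic risk score

   GRS = Σᵢ βᵢ · SNPᵢ,

   where SNPᵢ ∈ {0, 1, 2} counts risk alleles; an optional rescaled
   mode maps one score point to roughly one risk allele.
5. **Stratification** — score quartiles (control-based cut points),
   per-stratum odds ratios with 95% CIs, trend tests, and a
   90th-percentile high/low risk split.
6. **Evaluation** — C-statistics with placement-value (DeLong)
   confidence intervals for the *epidemiologic* (smoking only),
   *genetic* (GRS only) and *extended* (smoking + GRS) logistic models,
   paired nonparametric AUC comparison, and Hosmer-Lemeshow
   calibration.

Weights fitted in a training cohort are frozen — structurally immutable
— before scoring a validation cohort, so external validation can never
silently refit.

The package ships a 38-SNP lung-cancer weight table
(`lungrisk.packaged_weight_table()`): rsID, position, alleles, minor
allele frequency, per-allele odds ratio and LASSO weight β per SNP,
oriented so every β is positive for its risk allele. A cohort simulator
(`lungrisk.simulate`) generates case-control data under a logistic
disease model at exactly those frequencies and effect sizes — plus a
binary smoking exposure (52.66% in controls, OR ≈ 3) — so the entire
pipeline is testable without access to any individual-level study data.

## Worked example

Simulate a training-size cohort (2,331 cases / 3,077 controls) at the
packaged frequencies and odds ratios, run screening + LASSO, and
evaluate the three risk models:

```python
from lungrisk import (
    packaged_weight_table, spec_from_weights, simulate_cohort,
    train_weights, evaluate_cohort,
)

weights = packaged_weight_table()
spec = spec_from_weights(weights, seed=7)      # 2,331 cases / 3,077 controls
cohort, truth = simulate_cohort(spec)

trained = train_weights(cohort, skip_qc=True, folds=5, seed=7)
scores, grs_table, comb_table, report, highlow = evaluate_cohort(trained, cohort)
```

This prints (via the obvious `to_string` calls):

```
selected 31 of 31 screened SNPs (lambda = 0.003071)
 category  case_n  case_pct  control_n   or
        0     234     10.04        769 1.00
        1     398     17.07        769 1.70
        2     591     25.35        769 2.53
        3    1108     47.53        770 4.73
p_trend = 2.58e-82
        model   auc  ci_low  ci_high  p_vs_epidemiologic
epidemiologic 0.617   0.605    0.629                 NaN
      genetic 0.668   0.653    0.682               0.000
     extended 0.714   0.701    0.728               0.000
Hosmer-Lemeshow p = 0.86
90th-percentile split: 71.35% cases in the high-risk group vs 39.96% in the low-risk group
```

Reading the output: 31 of the 38 true signals survive the p < 0.05
screen at this sample size (the weakest published ORs of 1.08 sit near
50% power, so a handful always drop) and all survivors keep nonzero
LASSO weights. Control counts are flat across score quartiles by
construction (cut points come from the control distribution) while the
case share climbs from 10% to 48% — a top-vs-bottom odds ratio of 4.7
with an overwhelming trend. Adding the GRS to smoking lifts the
C-statistic from 0.617 to 0.714, and the Hosmer-Lemeshow p of 0.86
says the extended model's predicted risks are well calibrated.

The same steps are available from the shell:

```
lungrisk simulate --seed 7 --out-prefix cohort
lungrisk select   --genotypes cohort.vcf --phenotypes cohort.pheno.tsv \
                  --skip-qc --seed 7 --out weights.tsv
lungrisk score    --genotypes cohort.vcf --phenotypes cohort.pheno.tsv \
                  --weights weights.tsv --out scores.tsv
lungrisk stratify --scores scores.tsv --phenotypes cohort.pheno.tsv --out strata.tsv
lungrisk evaluate --scores scores.tsv --phenotypes cohort.pheno.tsv --out eval.tsv
```

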