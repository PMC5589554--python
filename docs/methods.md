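# Methods

## The model

The package implements a two-stage case-control risk-modelling design.
A panel of candidate SNPs is reduced to a sparse weight vector in a
training cohort, the weights are frozen, and both cohorts are scored
and evaluated. Disease risk is modelled throughout by logistic
regression; the three reported models are

- *epidemiologic*: logit P(case) = α + γ·smoking
- *genetic*: logit P(case) = α + δ·GRS
- *extended*: logit P(case) = α + γ·smoking + δ·GRS

with GRS = Σᵢ βᵢ·gᵢ, gᵢ the count (0, 1, 2) of risk alleles at SNP i
and βᵢ the selected per-allele weight. All βᵢ are non-negative because
every SNP is oriented to its risk allele first: a published protective
association (OR < 1 for the listed allele) is re-oriented to the other
allele, with the flip recorded in a provenance column.

### Score scale

Two score modes exist. `weighted_sum` is the raw Σβᵢgᵢ;
`allele_count_rescaled` multiplies by k/Σβᵢ so a score point
corresponds to roughly one risk allele. The packaged 38-SNP weight set
has an expected raw weighted sum of Σ2pᵢβᵢ = 0.915 under
Hardy-Weinberg proportions at its own frequencies, which matches the
scale on which published mean scores near 1.0 are reported; the raw
sum is therefore the default, and the two modes induce identical
rankings (they differ by a positive constant), so every stratification
result is mode-invariant.

## Stage contracts

**QC** applies, in order: INFO ≥ `min_info` (variants without an INFO
value are treated as typed and pass), control-MAF ≥ `min_maf`,
control-HWE exact p ≥ `min_hwe_p`, then greedy LD pruning. The HWE
test is the exact conditional test (heterozygote counts enumerated at
fixed allele totals, plain non-mid p); a chi-square variant exists for
cross-checking. LD is the composite dosage correlation r² — the
unphased-genotype measure — and pruning processes variants in
ascending association p so the most significant member of each
correlated group survives; ties break deterministically by
(p, chromosome, position, rsID), which makes the kept set independent
of input order. Window semantics: same chromosome, pairwise distance
≤ `ld_window_bp`, both endpoints inclusive. HWE counts come from
dosages rounded to hard calls; QC on genuinely fractional dosages
should rely on the MAF and INFO rules.

**Screening** is per-allele additive logistic regression, unadjusted
by default (covariate adjustment is available), keeping p strictly
below α = 0.05. No multiple-testing correction is applied: every
candidate enters with prior published evidence, so the screen is a
replication filter, not a discovery scan — a design choice to be aware
of when the candidate panel is not pre-vetted.

**LASSO.** The solver minimizes mean negative log-likelihood +
λΣ|βⱼ| by coordinate descent inside an IRLS outer loop with
covariance updating (the glmnet strategy), intercept and masked
columns never penalized. Solutions satisfy the subgradient
stationarity conditions to ≤ 1e-5 (`kkt_violation` certifies this;
the test suite checks it on every fit, and cross-checks fixed-λ
solutions against an independent proximal-gradient solver and
scikit-learn's saga, and λ = 0 against the statsmodels MLE).
Predictors stay on the allele-count scale by default so coefficients
are per-allele log-odds usable directly as GRS weights; a standardized
mode back-transforms. λ is chosen by stratified k-fold (default 10)
cross-validated deviance on a log-spaced path from λ_max down four
decades; the default `cv_1se` rule takes the largest λ within one
standard error of the minimum — sparser and more reproducible than
`cv_min`, both available, fold assignment a pure function of the seed.

**Stratification** cuts scores at type-7 (linear-interpolation)
quantiles of the *control* distribution by default — this is what makes
control counts near-equal per stratum — with intervals [lower, upper)
and the top bin closed above, so a score exactly at a cut point lands
in the higher stratum. Odds ratios per stratum are crude
cross-products with Woolf CIs (Haldane-Anscombe 0.5 correction on zero
cells, flagged) or covariate-adjusted indicator-coded logistic fits;
the trend test enters the stratum index 0..3 as one linear term
(median-score coding available). Printed percentages are column
percentages rounded half-up to two decimals.

**Evaluation.** The C-statistic is the Mann-Whitney concordance
probability (ties ½). Its variance, CI and the paired comparison of
two models' AUCs all come from per-sample placement values (the
DeLong/structural-components construction); identical rankings give a
zero-variance difference reported as p = 1 with a degenerate flag.
Calibration is Hosmer-Lemeshow over deciles of predicted risk
(group count configurable; groups with zero expected events merge into
a neighbour; with g groups the reference distribution is χ² on g − 2
df, so a 2-group statistic carries no p-value).

## The simulator

`lungrisk.simulate` generates the data structure the analysis assumes:
genotypes as Binomial(2, p) per variant (HWE), optional LD blocks via
a shared-uniform copula (block members reuse one latent uniform with
per-site re-randomization; the feasible haplotype correlation is
bounded by the frequency mismatch and the generator errors past the
bound), binary smoking, and disease from the joint logistic model with
the intercept solved numerically (Monte Carlo + Brent) for a target
population prevalence, default 1%. Case-control sampling is rejection
sampling from that population model, so conditional distributions are
exact; quotas below an expected case probability of 1e-6 raise instead
of looping. Identical specs (including seed) reproduce byte-identical
cohorts.

Default conditions emulate the two-cohort lung-cancer study the
packaged weight table comes from: training 2,331 cases / 3,077
controls at the table's frequencies and odds ratios; validation
1,937 / 1,984 with Beta-jittered frequencies (concentration 80)
standing in for a second ancestry; control smoking prevalence 52.66%
with smoking OR ≈ 2.98, the value implied by a 76.85% case smoking
rate at low prevalence.

Published per-SNP ORs are univariate (marginal) estimates, while the
simulator uses them as joint-model coefficients. At 1% prevalence this
distinction is immaterial: the logistic is nearly log-linear there, so
the implied marginal OR of a conditional-1.37 SNP is 1.369 —
within a fraction of a percent — and simulated univariate estimates
centre on the published values (verified in the test suite). At common
prevalences the two would diverge (logistic non-collapsibility) and
the inputs should then be read as conditional effects.

What the simulator deliberately omits: genome-wide LD structure,
population stratification, relatedness, genotyping/imputation error,
dose-response smoking, gene-environment interaction. Passing tests
therefore demonstrate that the *methods* behave correctly under their
own assumptions, not that real cohorts satisfy those assumptions.

## Numerical and policy choices

- Missing genotypes are mean-imputed per variant from the control
  effect-allele frequency (2p̂), keeping scores defined for all
  samples; a drop policy is available at the call sites that accept
  masks. Missing genotypes are never silently zeroed at parse time.
- Perfect separation or monomorphism in a univariate fit yields a
  flagged result (never retained by screening), not an exception.
- Logistic fits use statsmodels; Wald CIs use z = 1.96.
- LASSO convergence: max coefficient change < 1e-7 per sweep;
  λ path 60 points over 4 decades.
- The quantile rule everywhere is numpy's default type 7; boundary
  membership is pinned by the "≥ cut point ⇒ upper bin" convention.
- Problem sizes in the test suite are chosen to keep the full run a
  few minutes: calibration suites use 300–500 replicates, the 38-SNP
  recovery suite 20 seeds with 5-fold CV, the permutation oracle 4,000
  draws per instance. The acceptance script runs the full two-stage
  pipeline at the complete study dimensions (5,408 + 3,921 samples).

## Known limitations

- The HWE exact test enumerates heterozygote counts; for extremely
  large samples (millions) the chi-square flag is faster.
- Adjusted stratum ORs depend on the covariate set supplied; published
  adjusted ORs from any given study are reproducible only to the
  extent the same covariates are available.
- The paired AUC test is asymptotic; below n ≈ 50 per group prefer the
  permutation approach used as its oracle in the tests.
- The weight-table interface is the package's own TSV shape; external
  scoring-file formats are out of scope.
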