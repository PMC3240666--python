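# hccstrat

Two-stage stratified prognosis modelling for hepatocellular carcinoma
(HCC) cohorts, with the companion enrichment analyses and a synthetic
cohort generator with planted ground truth.

## The problem

After curative surgery, HCC outcome (overall survival, and disease-free
survival = time to recurrence) is partly predicted by routine
clinicopathologic parameters — tumor size, number of tumor nodules
(NOTN), serum AFP and albumin, venous infiltration, pTNM and AJCC stage.
A Cox model over these parameters stratifies patients into *good* and
*poor* prognosis groups, but leaves substantial outcome variation within
each group. The question this package operationalises: does gene
expression — from the tumor or, more provocatively, from adjacent
non-tumor liver tissue — carry additional prognostic information *within*
the clinically defined strata, and are the genes involved linked to
germline variation (cis-eQTLs) that also associates with outcome?

## The method

**Stage 1 — clinical stratification.** Univariate Cox screens pick the
significant clinicopathologic parameters (Wald p < α = 0.05); a
multivariate Cox model over the selected set yields the relative hazard
`h = (x − x̄)ᵀβ̂`. `h` is computed by leave-one-out (LOO): for each
patient, selection and fit are redone on the other n−1 patients and the
held-out patient is scored by that model. Patients are split at the
median of `h` into good (low hazard) and poor groups and the split is
evaluated by log-rank test and Kaplan–Meier curves.

**Stage 2 — within-stratum expression sub-classification.** Inside each
stratum, a nested LOO supervised-PCA Cox predictor: in every fold, (1)
a univariate Cox screen over all genes on the n−1 training patients,
(2) the K = 100 genes with smallest Wald p, (3) covariance PCA of that
panel, (4) a Cox model on the top m = 6 principal components (which
carry ~80% of the panel variance), (5) projection of the held-out
patient's expression onto the fold's PC basis and scoring. The screen,
the panel, the basis and the coefficients of a fold never see the
held-out patient. Variants: combined mode (clinical covariates in both
the screen and the PC Cox model) and dual-tissue mode (independent
screen + PCA per tissue, 12 PCs in one model).

**Preprocessing.** Each expression trait is residualised on age and sex
with a robust linear model (M-estimation, Tukey bisquare weights,
MAD scale), so gross array outliers carry zero weight.

**Enrichment.** Prognosis signatures at tiered Wald-p cutoffs (2e-6,
5e-4, 0.01, 0.05) are compared against external gene lists by fold
enrichment `k·N/(|A|·|B|)` and the one-sided hypergeometric tail.
A cis-eQTL scan (linear regression of expression on allele dosage
within ±1 Mb of the TSS, Benjamini–Hochberg FDR 10%) defines eSNPs;
a clinically adjusted per-SNP Cox scan at α = 0.01 defines cSNPs; eSNP
enrichment among cSNPs is tested hypergeometrically against a
randomized-endpoint permutation null (pseudo-cSNPs).

**Synthetic cohorts.** `hccstrat.simulate` generates cohorts with the
structure above planted and recorded: Weibull proportional-hazards
outcomes with bisection-calibrated censoring (67.8% for survival, 48.9%
for DFS), seven effective clinical covariates, a latent prognostic
frailty that ties stratum-specific 100-gene signature blocks to outcome,
age/sex nuisance effects, rare 6–10 SD outliers, Hardy–Weinberg
genotypes with cis-placed eQTLs and outcome-linked cSNPs.

## Worked example

```python
import pandas as pd
from hccstrat import (SimulationConfig, SignatureBlock, generate_cohort,
                      robust_residualize, loo_clinical_predictor,
                      loo_expression_predictor, dichotomize,
                      evaluate_split)

cfg = SimulationConfig(
    seed=7, n_patients=230, n_genes=2000, n_snps=50, n_eqtl=5, n_csnp=0,
    signature_spec=[SignatureBlock("tumor", "good", 100, 1.0, 0.3)])
cohort = generate_cohort(cfg)

# stage 1: clinical stratification (survival endpoint)
h = loo_clinical_predictor(cohort.clinical, cohort.survival)
strata = dichotomize(h)
lr, _ = evaluate_split(strata, cohort.survival)
print(f"clinical split log-rank p = {lr.pvalue:.2e}")

# stage 2: expression sub-split inside the good stratum
good = strata.group("good")
expr = robust_residualize(cohort.expr_tumor, cohort.clinical)
h2, _ = loo_expression_predictor(expr[good], cohort.survival.loc[good])
lr2, _ = evaluate_split(dichotomize(h2), cohort.survival.loc[good])
print(f"good-stratum expression sub-split p = {lr2.pvalue:.4f}")
```

prints (seed 7):

```
clinical split log-rank p = 6.05e-03
good-stratum expression sub-split p = 0.0001
```

The clinical split separates the cohort strongly; within the good
stratum the planted tumor-tissue signature yields a further significant
sub-split, while a stratum without planted signal stays null — the
qualitative pattern the stratified design is built to expose.

The same pipeline is scriptable from the shell:

```
hccstrat simulate --seed 1 --out cohort/
hccstrat stratify --clinical cohort/clinical.tsv \
    --outcome cohort/survival.tsv --out strata.tsv
hccstrat predict --expr cohort/expr_tumor.tsv \
    --outcome cohort/survival.tsv --strata strata.tsv --stratum good \
    --out report/
hccstrat run-all --seed 1 --out study/
```

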