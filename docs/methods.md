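# Methods

This note documents the statistical models, the numerical choices, the
synthetic-data design and the known limitations of `hccstrat`.

## Survival primitives

**Cox fitting.** The partial likelihood is maximised by Newton–Raphson
with step-halving, batched across many design matrices that share one
outcome (the batch axis is what makes per-gene and per-SNP screening
affordable inside leave-one-out loops). Ties are handled by the Efron
approximation by default (Breslow selectable); patients censored exactly
at an event time count as at risk for that time. Convergence requires
`max|score| < 1e-7` or a relative log-likelihood change `< 1e-9`.
Monotone likelihood (risk perfectly ordered by a covariate, so the MLE
is infinite) is detected two ways: a coefficient excursion past ±20, or
a fitted coefficient exceeding 5 per covariate SD — a hazard ratio above
e⁵ per SD has no interior optimum in any practically meaningful sense.
Such fits are flagged non-converged; in screens they receive the
sentinel p = 1 so result vectors stay aligned. A single-covariate
numba kernel implements the same damped Newton update for the p = 1
screen; the test suite asserts machine-precision agreement with the
generic engine, and the generic engine is cross-checked against
lifelines.

**Wald statistics.** Screens and scans report Wald p-values (coefficient
over the inverse-information SE), matching the statistic quoted for the
published signature tables. Likelihood-ratio statistics would be
slightly better calibrated at small event counts but are threefold more
expensive in batch.

**Log-rank and Kaplan–Meier.** The k-group Mantel–Haenszel statistic is
accumulated over distinct event times with the hypergeometric
mean/variance; the chi-square reference has k−1 degrees of freedom. The
KM estimator is the product-limit form. Both are cross-checked against
lifelines.

**Linear predictors** are centred at training means, `h = (x − x̄)ᵀβ̂`,
so scores are comparable across leave-one-out folds; centring does not
change the ranking within a fold.

## Robust residualisation

Each gene is regressed on (intercept, age in years, male indicator) by
IRLS with Tukey bisquare weights, tuning constant c = 4.685 (95%
Gaussian efficiency), and scale re-estimated each iteration as
`median(|r|)/0.6745`. Convergence is a maximum coefficient change below
1e-8 (50 iterations cap; the last iterate is used with a warning
otherwise). When the MAD collapses to zero (an exact fit for the
majority of points), points on the fit get weight 1 and any remaining
deviants weight 0, which preserves the intended outlier rejection in
the noiseless limit. The residualisation is applied once to the full
cohort before any cross-validation; this mirrors the analysis order the
pipeline models and is a potential mild leakage source (age/sex
coefficients see all patients), noted here deliberately.

## Stage 1: clinical stratification

Candidate parameters are tumor size, NOTN, log-AFP, albumin, venous
infiltration, pTNM and AJCC stage (AFP enters on the log scale; age and
sex are treated as expression nuisance, not candidate predictors).
Selection keeps parameters with univariate Wald p < 0.05, per endpoint.
pTNM and AJCC are strongly collinear; if the information matrix turns
singular the multivariate fit retries with a 1e-6 ridge on the
information matrix only. The LOO linear predictor re-runs selection in
every fold; a fold that selects nothing contributes h = 0 with a
warning. The median split assigns ties to the good group; an all-tied
vector, or a split that leaves the poor group empty, raises a
degenerate-split error rather than fabricating groups.

## Stage 2: supervised-PCA Cox, nested LOO

Per fold: screen on training patients only → top K = 100 genes by Wald
p (ties broken by ascending gene id, so selection is deterministic) →
covariance PCA (genes centred by training means, not rescaled — the
traits are already variance-comparable residuals) → Cox on the top
m = 6 PCs → held-out projection onto the training basis → h. PC loading
signs are fixed so each component's largest-magnitude coordinate is
positive. If the PC Cox fit fails, the fold retries with m−1, …, 1 PCs
and finally the h = 0 sentinel, keeping the h vector complete for the
log-rank evaluation. The combined mode adds the clinical covariates to
both the screen and the PC model; the dual-tissue mode screens and
compresses each tissue independently and enters all 2m = 12 PCs in one
model.

**Null behaviour of the sub-split test (important).** The two-sided
log-rank test applied to the median split of the cross-validated h is
*not* exactly calibrated, even though every fold is strictly nested
(verified by sentinel-perturbation tests: fold objects are bit-identical
under arbitrary changes of the held-out patient's expression). Each
patient's score is honest with respect to their own outcome — the same
h tested against an independently regenerated outcome rejects at the
nominal 5% — but all scores share a fitted direction that was trained
on the outcomes being tested, and that common dependence inflates the
variance of the log-rank statistic. At n = 60, 2000 genes, K = 100,
m = 6 the null rejection rate at nominal 0.05 is about 0.2-0.3, roughly
independent of m, and an unsupervised gene panel shows the same order
of inflation (so gene selection is not the driver). An independent
reimplementation of the loop with lifelines reproduces the effect. By
contrast, screening on all n patients (the leaky variant, available only
in the test suite) rejects essentially always under the same null —
nesting removes the first-order selection bias and leaves this residual,
well-documented anti-conservativeness of significance tests on
cross-validated risk groups. Consumers should read the sub-split
p-values as descriptive ranking evidence, or calibrate them by endpoint
permutation, rather than as exact type-I-error statements.

## Enrichment

Fold enrichment is `k·N/(|A|·|B|)` (defined 0 when k = 0) and the
p-value is the exact upper hypergeometric tail `P(X ≥ k)` (one-sided:
only enrichment is tested). Identifiers outside the declared universe
are dropped with a warning and excluded from all counts. The universe
is the caller's responsibility (typically the intersection of the
study's gene ids and the comparison platform's list). The membership
table has two parts: genes at the genome-wide cutoff 2e-6 (a Bonferroni
scale for ~20k genes), and genes present in at least two external lists,
with the own-study p printed only when ≤ 0.01.

## Genetics

The cis window is ±1 Mb around the TSS (configurable); the per-pair test
is the two-sided t-test on the Pearson correlation between dosage and
expression, which is exactly the simple-regression slope test.
Monomorphic SNPs are skipped and removed from the universe everywhere.
FDR control is Benjamini–Hochberg step-up over all tested cis pairs; the
implied p threshold (largest p(i) ≤ i·q/m) is reported so the discovery
set is reproducible from the threshold alone. The cSNP scan fits one
Cox model per SNP — dosage plus the selected clinicopathologic
covariates — warm-started at the covariates-only optimum. The
pseudo-cSNP null permutes (time, event) pairs jointly across patients,
preserving the censoring marginal while destroying genotype–outcome
links; permutations yielding zero pseudo-cSNPs record fold 0, and the
empirical p is the fraction of null folds at or above the observed fold.

**Attenuation caveat.** Marginal per-SNP hazard effects shrink under
unobserved heterogeneity (Cox models do not collapse over omitted
frailty). In synthetic studies with heavy latent frailty and the ~68%
censoring of the survival endpoint, planted per-allele effects of
realistic size fall below detectability at a few thousand SNPs and a
few hundred patients; the genetics demonstrations therefore use the
higher-event DFS endpoint and a low-frailty hazard, where the designed
eSNP-in-cSNP enrichment is resolvable.

## Synthetic cohort design

Defaults encode the modelled study's printed descriptives: n = 272,
67.8% censoring for survival, 51.1% event rate for DFS, a ~100-month
follow-up window (Weibull baseline, shape 1.2, scale 90 months for
survival and 55 for DFS), and seven predictive clinicopathologic
parameters with heavy-tailed marginals (tumor size and AFP log-normal,
ordinal stages, 85% male). Event times are drawn by inverse-CDF from
the Weibull proportional-hazards model; censoring is Uniform(0, c) with
c found by bisection so the expected censored fraction hits the target
(a simple, reproducible administrative-censoring surrogate). Clinical
log-hazard coefficients are sized so the clinical linear predictor has
SD ≈ 0.8, comparable to the latent frailty (SD 0.8 by default): the
stage-1 split is then clearly significant at cohort scale without
making expression redundant.

Expression: signature blocks load on the latent frailty only within
their configured stratum (defined by the median of the true clinical
linear predictor, mirroring the analysis-side dichotomisation);
non-signature genes are block-equicorrelated noise (blocks of 10,
ρ = 0.2) with gene-specific random age/sex effects and ±(6–10) SD point
contamination at rate 0.2% to exercise the bisquare weights. Planted
cis-eQTL effects are added to the adjacent-normal matrix (the genotyped
tissue). Genotypes are Hardy–Weinberg with MAF ~ U(0.05, 0.5) and no
linkage disequilibrium. A configurable fraction of planted cSNPs
coincides with planted eQTL SNPs (default one half), which is what
gives the eSNP-in-cSNP enrichment a synthetic counterpart.

What the generator does **not** emulate: probe-level microarray noise
and normalisation artifacts, LD structure and population stratification,
batch effects, gene–gene regulatory networks beyond block correlation,
and informative censoring. Passing tests therefore certify the
statistical machinery under the stated generative model, not performance
on real arrays.

## Problem sizes used in the automated checks

The test suite runs the null-calibration comparison at n = 60 with
2000 genes over 200 cohorts, signature recovery at stratum size 115
with 2000 genes over 50 replicates (DFS endpoint, signature effect 1.2,
frailty SD 1.0 — each planted gene shares ~60% of its variance with the
prognostic factor), FDR checks over 50 cohorts of 400 SNPs × 60 genes,
and the permutation null at 1500 SNPs with 20 permutations; the
acceptance script uses the same designs at somewhat smaller replicate
counts. These sizes were chosen so each check resolves its target
property with Monte-Carlo error well inside the asserted band.

## Known limitations

* Sub-split log-rank p-values are anti-conservative under the null (see
  above); the package reports them as the modelled analysis defines
  them.
* The full-cohort residualisation is a mild leakage channel by design
  fidelity.
* Breslow/Efron differences are negligible for the continuous synthetic
  times but matter for heavily tied real data; the ties method is
  recorded on every fitted model.
* `univariate_screen`'s sentinel (p = 1 for degenerate or divergent
  features) biases against such features in ranking; they are also the
  features with no usable inference.
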