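"""Synthetic HCC cohort generator with planted ground truth.

Emulates the statistical structure the two-stage prognosis analysis
assumes, so every downstream stage can be tested against known truth:

* clinicopathologic covariates with heavy-tailed marginals (AFP and tumor
  size log-normal, ordinal stages, mostly-male cohort);
* right-censored survival and disease-free-survival times from a Weibull
  proportional-hazards model, with the censoring scale calibrated by
  bisection to hit a target censored fraction (default 67.8% for
  survival, 48.9% for DFS);
* a latent per-patient prognostic frailty that ties a stratum-specific
  block of signature genes to outcome, plus correlated background genes,
  age/sex nuisance effects and rare gross outliers;
* Hardy-Weinberg genotypes with planted cis-eQTLs (dosage effects on
  expression) and cSNPs (dosage effects on the log-hazard).

The ``PlantedTruth`` record carries every planted id and effect so
recovery and null-calibration tests can score the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import make_outcome

__all__ = [
    "SimulationConfig", "SignatureBlock", "PlantedTruth", "SyntheticCohort",
    "generate_clinical", "generate_survival", "generate_expression",
    "generate_genotypes", "generate_cohort",
    "ConfigurationError", "CalibrationError", "GenerationError",
]


class ConfigurationError(ValueError):
    """An invalid SimulationConfig field; the message names the field."""


class CalibrationError(RuntimeError):
    """Censoring calibration failed to bracket the target."""


class GenerationError(RuntimeError):
    """Inconsistent generated structure (e.g. cis-window violation)."""


@dataclass
class SignatureBlock:
    """A block of prognostic genes planted in one tissue and stratum.

    ``effect`` is the per-gene loading on the latent prognostic frailty
    (expression-SD units per frailty SD); ``rho`` the within-block noise
    correlation.
    """

    tissue: str = "tumor"          # {tumor, normal}
    stratum: str = "good"          # {good, poor}; planted only there
    size: int = 100
    effect: float = 1.0
    rho: float = 0.3


@dataclass
class SimulationConfig:
    """Study-condition knobs for one synthetic cohort.

    Defaults mirror the real cohort's descriptives where the study prints
    them (n = 272, 67.8% survival censoring, 51.1% recurrence rate,
    ~100-month follow-up window, seven predictive clinicopathologic
    parameters) and conventional values elsewhere.
    """

    n_patients: int = 272
    n_genes: int = 5000
    n_snps: int = 2000
    seed: int = 0

    # clinical marginals (means used by tests)
    age_mean: float = 52.0
    age_sd: float = 11.0
    male_frac: float = 0.85
    tumor_size_log_mean: float = 1.7    # cm, log scale (median ~5.5 cm)
    tumor_size_log_sd: float = 0.5
    afp_log_mean: float = 4.0           # ng/mL, log scale
    afp_log_sd: float = 2.5
    albu_mean: float = 41.0             # g/L
    albu_sd: float = 5.0
    venous_frac: float = 0.35
    notn_lambda: float = 0.5            # NOTN = 1 + Poisson(lambda)
    ptnm_probs: tuple = (0.25, 0.3, 0.3, 0.15)   # stages 1..4
    ajcc_probs: tuple = (0.3, 0.3, 0.25, 0.15)   # stages 1..4

    # log-hazard coefficients on (standardised-ish) clinical covariates
    clinical_effects: dict = field(default_factory=lambda: {
        "tumor_size": 0.10,      # per cm
        "log_afp": 0.18,         # per log-unit
        "albu": -0.06,           # per g/L
        "venous_infiltration": 0.60,
        "pTNM": 0.35,
        "AJCC": 0.30,
        "NOTN": 0.30,
    })
    frailty_sd: float = 0.8      # SD of the latent prognostic log-hazard term

    # survival model
    weibull_shape: float = 1.2
    weibull_scale: float = 90.0          # months
    censoring_target: float = 0.678      # survival endpoint
    dfs_weibull_scale: float = 55.0
    dfs_censoring_target: float = 0.489  # 51.1% recurrence

    # expression model
    signature_spec: list = field(default_factory=lambda: [
        SignatureBlock("tumor", "good"), SignatureBlock("normal", "good")])
    bg_block_size: int = 10
    bg_rho: float = 0.2
    nuisance_age_effect: float = 0.15    # SD of per-gene age slopes (per 10 y)
    nuisance_sex_effect: float = 0.3     # SD of per-gene sex offsets
    outlier_rate: float = 0.002          # point contamination probability
    outlier_min_sd: float = 6.0
    outlier_max_sd: float = 10.0

    # genotype model
    maf_min: float = 0.05
    maf_max: float = 0.5
    n_eqtl: int = 50
    eqtl_effect: float = 1.0             # expression SD per minor allele
    eqtl_cis_bp: int = 100_000           # planted SNP-to-TSS distance bound
    n_csnp: int = 10
    csnp_effect: float = 0.3             # log-hazard per minor allele
    csnp_from_eqtl_frac: float = 0.5     # fraction of cSNPs that are also
    #                                      planted eQTL SNPs (gives the
    #                                      eSNP-in-cSNP signal)
    n_chromosomes: int = 22
    gene_spacing_bp: int = 100_000

    def validate(self):
        for name in ("n_patients", "n_genes", "n_snps"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("censoring_target", "dfs_censoring_target"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie strictly in (0,1)")
        for blk in self.signature_spec:
            if not 0.0 <= blk.rho < 1.0:
                raise ConfigurationError("signature_spec rho must be in [0,1)")
            if blk.size > self.n_genes:
                raise ConfigurationError(
                    "signature_spec block size exceeds n_genes")
            if blk.tissue not in ("tumor", "normal"):
                raise ConfigurationError("signature_spec tissue must be "
                                         "'tumor' or 'normal'")
            if blk.stratum not in ("good", "poor"):
                raise ConfigurationError("signature_spec stratum must be "
                                         "'good' or 'poor'")
        if not 0.0 <= self.bg_rho < 1.0:
            raise ConfigurationError("bg_rho must be in [0,1)")
        if self.n_eqtl > self.n_snps or self.n_csnp > self.n_snps:
            raise ConfigurationError("planted SNP counts exceed n_snps")
        if not 0.0 < self.maf_min <= self.maf_max <= 0.5:
            raise ConfigurationError("MAF range must satisfy "
                                     "0 < maf_min <= maf_max <= 0.5")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ConfigurationError("outlier_rate must be in [0,1)")
        return self


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic cohort."""

    clinical_effects: dict = field(default_factory=dict)
    frailty_sd: float = 0.0
    signature_genes: dict = field(default_factory=dict)
    #   key "tissue/stratum" -> {"genes": [...], "effect": float}
    eqtl_pairs: list = field(default_factory=list)
    #   (snp_id, gene_id, effect)
    csnp_ids: list = field(default_factory=list)
    csnp_effect: float = 0.0
    realized_censoring: dict = field(default_factory=dict)
    stratum_labels: dict = field(default_factory=dict)
    #   patient id -> good/poor (true clinical-score stratum)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        return cls(**json.loads(text))


def _patient_ids(n):
    return np.array([f"P{i:04d}" for i in range(1, n + 1)], dtype=object)


def generate_clinical(config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw the clinicopathologic table from the configured marginals."""
    config.validate()
    n = config.n_patients
    ids = _patient_ids(n)
    age = rng.normal(config.age_mean, config.age_sd, n).clip(18, 90)
    sex = np.where(rng.random(n) < config.male_frac, "M", "F")
    tumor_size = np.exp(rng.normal(config.tumor_size_log_mean,
                                   config.tumor_size_log_sd, n))
    notn = 1 + rng.poisson(config.notn_lambda, n)
    afp = np.exp(rng.normal(config.afp_log_mean, config.afp_log_sd, n))
    albu = rng.normal(config.albu_mean, config.albu_sd, n).clip(15, 60)
    venous = rng.binomial(1, config.venous_frac, n)
    ptnm = rng.choice(np.arange(1, len(config.ptnm_probs) + 1), size=n,
                      p=config.ptnm_probs)
    ajcc = rng.choice(np.arange(1, len(config.ajcc_probs) + 1), size=n,
                      p=config.ajcc_probs)
    return pd.DataFrame(
        {"age": age, "sex": sex, "tumor_size": tumor_size, "NOTN": notn,
         "AFP": afp, "ALBU": albu, "venous_infiltration": venous,
         "pTNM": ptnm, "AJCC": ajcc},
        index=pd.Index(ids, name="patient"))


def clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric model matrix for hazard generation and Cox fitting.

    AFP enters on the log scale; sex as a 0/1 male indicator.
    """
    out = pd.DataFrame(index=clinical.index)
    out["age"] = clinical["age"].astype(float)
    out["sex"] = (clinical["sex"] == "M").astype(float) \
        if clinical["sex"].dtype == object else clinical["sex"].astype(float)
    out["tumor_size"] = clinical["tumor_size"].astype(float)
    out["NOTN"] = clinical["NOTN"].astype(float)
    out["log_afp"] = np.log(clinical["AFP"].astype(float))
    out["albu"] = clinical["ALBU"].astype(float)
    out["venous_infiltration"] = clinical["venous_infiltration"].astype(float)
    out["pTNM"] = clinical["pTNM"].astype(float)
    out["AJCC"] = clinical["AJCC"].astype(float)
    return out


def true_clinical_predictor(clinical: pd.DataFrame,
                            config: SimulationConfig) -> np.ndarray:
    """Planted clinical log-hazard x'beta (centred)."""
    design = clinical_design(clinical)
    lp = np.zeros(len(clinical))
    for name, beta in config.clinical_effects.items():
        if name not in design.columns:
            raise ConfigurationError(
                f"clinical_effects refers to unknown column {name!r}")
        lp += beta * design[name].to_numpy()
    return lp - lp.mean()


def _calibrate_censoring(event_times: np.ndarray, target: float) -> float:
    """Bisect the Uniform(0, c) censoring scale so that the *expected*
    censored fraction equals ``target``.

    With C ~ U(0, c), P(censor patient i) = P(C < T_i) = min(T_i / c, 1);
    the expectation over patients is continuous and decreasing in c.
    """
    def frac(c):
        return float(np.mean(np.minimum(event_times / c, 1.0)))

    lo, hi = 1e-6, float(event_times.max()) * 2 + 1.0
    for _ in range(200):
        if frac(hi) <= target:
            break
        hi *= 2.0
    else:
        raise CalibrationError("censoring calibration failed to bracket "
                               "the target fraction")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival(clinical: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator, *,
                      extra_loghazard=None, endpoint="survival"):
    """Draw right-censored outcome times under the Weibull PH model.

    ``extra_loghazard`` adds planted non-clinical terms (frailty, cSNP
    dosage effects) to the linear predictor before time generation.

    Returns ``(outcome DataFrame, realized censored fraction)``.
    """
    config.validate()
    unknown = set(config.clinical_effects) - set(clinical_design(
        clinical).columns)
    if unknown:
        raise ConfigurationError(
            f"clinical_effects refers to unknown column(s) {sorted(unknown)}")
    n = len(clinical)
    lp = true_clinical_predictor(clinical, config)
    if extra_loghazard is not None:
        lp = lp + np.asarray(extra_loghazard, float)
        lp = lp - lp.mean()

    shape = config.weibull_shape
    scale = config.weibull_scale if endpoint == "survival" \
        else config.dfs_weibull_scale
    target = config.censoring_target if endpoint == "survival" \
        else config.dfs_censoring_target

    # inverse-CDF sampling: T = scale * (-log U / exp(lp))^(1/shape)
    u = rng.random(n)
    T = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    c_max = _calibrate_censoring(T, target)
    C = c_max * rng.random(n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    time = np.maximum(time, 1e-3)       # keep times strictly positive
    if event.sum() == 0:
        raise CalibrationError("no events realized; censoring target too "
                               "extreme for this cohort size")
    outcome = make_outcome(time, event, ids=clinical.index)
    return outcome, float(1.0 - event.mean())


def _gene_ids(n):
    return np.array([f"G{i:05d}" for i in range(1, n + 1)], dtype=object)


def _snp_ids(n):
    return np.array([f"rs{i:06d}" for i in range(1, n + 1)], dtype=object)


def _correlated_noise(rng, n_genes, n_patients, block, rho):
    """Block-equicorrelated Gaussian noise, genes x patients."""
    eps = rng.normal(size=(n_genes, n_patients))
    if rho <= 0 or block <= 1:
        return eps
    n_blocks = int(np.ceil(n_genes / block))
    shared = rng.normal(size=(n_blocks, n_patients))
    shared_full = np.repeat(shared, block, axis=0)[:n_genes]
    return np.sqrt(rho) * shared_full + np.sqrt(1 - rho) * eps


def generate_expression(clinical: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator, *, frailty: np.ndarray,
                        stratum_labels: np.ndarray,
                        eqtl_dosage_effect=None):
    """Generate tumor and adjacent-normal expression matrices.

    Signature blocks load on the latent frailty within their configured
    stratum only; all genes get age/sex nuisance effects and rare gross
    outliers.  ``eqtl_dosage_effect`` is an optional genes x patients
    additive term carrying planted cis-eQTL signal (applied to the
    adjacent-normal matrix, the genotyped tissue).

    Returns ``(expr_tumor, expr_normal, signature_genes dict)``.
    """
    config.validate()
    n = len(clinical)
    gids = _gene_ids(config.n_genes)
    age = clinical["age"].to_numpy(float)
    sexm = (clinical["sex"] == "M").to_numpy(float) \
        if clinical["sex"].dtype == object \
        else clinical["sex"].to_numpy(float)
    age_c = (age - age.mean()) / 10.0

    signature_genes = {}
    mats = {}
    # allocate disjoint gene blocks for the signatures, in declared order
    cursor = 0
    block_slices = []
    for blk in config.signature_spec:
        if cursor + blk.size > config.n_genes:
            raise ConfigurationError(
                "signature blocks exceed n_genes in total")
        block_slices.append(slice(cursor, cursor + blk.size))
        cursor += blk.size

    for tissue in ("tumor", "normal"):
        X = _correlated_noise(rng, config.n_genes, n,
                              config.bg_block_size, config.bg_rho)
        # age/sex nuisance with gene-specific random coefficients
        a_coef = rng.normal(0.0, config.nuisance_age_effect, config.n_genes)
        s_coef = rng.normal(0.0, config.nuisance_sex_effect, config.n_genes)
        X += np.outer(a_coef, age_c) + np.outer(s_coef, sexm)

        for blk, sl in zip(config.signature_spec, block_slices):
            if blk.tissue != tissue:
                continue
            in_stratum = (stratum_labels == blk.stratum).astype(float)
            # per-gene loading on the frailty, applied within the stratum
            X[sl] += blk.effect * np.outer(np.ones(blk.size),
                                           frailty * in_stratum)
            key = f"{tissue}/{blk.stratum}"
            signature_genes[key] = {
                "genes": list(gids[sl]), "effect": blk.effect}

        if config.outlier_rate > 0:
            mask = rng.random(X.shape) < config.outlier_rate
            k = int(mask.sum())
            if k:
                mag = rng.uniform(config.outlier_min_sd,
                                  config.outlier_max_sd, k)
                sign = rng.choice([-1.0, 1.0], k)
                X[mask] += sign * mag * X.std()
        mats[tissue] = X

    if eqtl_dosage_effect is not None:
        mats["normal"] = mats["normal"] + eqtl_dosage_effect

    cols = clinical.index
    expr_tumor = pd.DataFrame(mats["tumor"], index=gids, columns=cols)
    expr_normal = pd.DataFrame(mats["normal"], index=gids, columns=cols)
    return expr_tumor, expr_normal, signature_genes


def generate_genotypes(config: SimulationConfig, rng: np.random.Generator):
    """Hardy-Weinberg genotypes plus SNP/gene position tables.

    Planted eQTL SNPs are placed within ``eqtl_cis_bp`` of their target
    gene's TSS; remaining SNPs are scattered uniformly.

    Returns ``(genotypes DataFrame, snp_pos, gene_pos, eqtl_pairs,
    csnp_ids)`` where ``eqtl_pairs`` is a list of (snp, gene, effect).
    """
    config.validate()
    n, M, Gn = config.n_patients, config.n_snps, config.n_genes
    sids = _snp_ids(M)
    gids = _gene_ids(Gn)
    ids = _patient_ids(n)

    # gene map: genes laid out along chromosomes at fixed spacing
    per_chrom = int(np.ceil(Gn / config.n_chromosomes))
    chrom = 1 + (np.arange(Gn) // per_chrom)
    tss = (1 + np.arange(Gn) % per_chrom) * config.gene_spacing_bp
    gene_pos = pd.DataFrame({"chrom": chrom, "tss": tss},
                            index=pd.Index(gids, name="gene"))

    chrom_span = (per_chrom + 1) * config.gene_spacing_bp
    snp_chrom = rng.integers(1, config.n_chromosomes + 1, M)
    snp_bp = rng.integers(1, chrom_span, M)

    # plant eQTLs on the first n_eqtl SNPs, each cis to a random gene
    eqtl_genes = rng.choice(Gn, size=config.n_eqtl, replace=False)
    eqtl_pairs = []
    for j, gi in enumerate(eqtl_genes):
        snp_chrom[j] = gene_pos["chrom"].iloc[gi]
        offset = int(rng.integers(-config.eqtl_cis_bp, config.eqtl_cis_bp))
        snp_bp[j] = max(1, int(gene_pos["tss"].iloc[gi]) + offset)
        if abs(snp_bp[j] - gene_pos["tss"].iloc[gi]) > config.eqtl_cis_bp:
            raise GenerationError("planted eQTL fell outside its cis window")
        eqtl_pairs.append((sids[j], gids[gi], config.eqtl_effect))

    # cSNPs: a configured fraction coincide with planted eQTL SNPs (these
    # drive the eSNP-in-cSNP enrichment); the rest are fresh SNPs
    n_shared = min(int(round(config.csnp_from_eqtl_frac * config.n_csnp)),
                   config.n_eqtl)
    n_fresh = config.n_csnp - n_shared
    fresh_idx = np.arange(config.n_eqtl, config.n_eqtl + n_fresh)
    if fresh_idx.size and fresh_idx[-1] >= M:
        raise ConfigurationError("n_eqtl + n_csnp exceeds n_snps")
    csnp_idx = np.concatenate([np.arange(n_shared), fresh_idx])
    csnp_ids = list(sids[csnp_idx.astype(int)])

    maf = rng.uniform(config.maf_min, config.maf_max, M)
    dosage = rng.binomial(2, maf[:, None], size=(M, n))
    genotypes = pd.DataFrame(dosage, index=pd.Index(sids, name="snp"),
                             columns=ids)
    snp_pos = pd.DataFrame({"chrom": snp_chrom, "bp": snp_bp},
                           index=pd.Index(sids, name="snp"))
    return genotypes, snp_pos, gene_pos, eqtl_pairs, csnp_ids


@dataclass
class SyntheticCohort:
    """Bundle of all generated tables plus the planted truth."""

    clinical: pd.DataFrame
    survival: pd.DataFrame
    dfs: pd.DataFrame
    expr_tumor: pd.DataFrame
    expr_normal: pd.DataFrame
    genotypes: pd.DataFrame
    snp_pos: pd.DataFrame
    gene_pos: pd.DataFrame
    truth: PlantedTruth
    config: SimulationConfig

    def write(self, outdir):
        """Write the standard TSV layout plus truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t",
                             float_format="%.17g")
        self.survival.to_csv(outdir / "survival.tsv", sep="\t",
                             index_label="patient", float_format="%.17g")
        self.dfs.to_csv(outdir / "dfs.tsv", sep="\t",
                        index_label="patient", float_format="%.17g")
        self.expr_tumor.to_csv(outdir / "expr_tumor.tsv", sep="\t",
                               index_label="gene", float_format="%.17g")
        self.expr_normal.to_csv(outdir / "expr_normal.tsv", sep="\t",
                                index_label="gene",
                                float_format="%.17g")
        self.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
        self.snp_pos.to_csv(outdir / "snp_pos.tsv", sep="\t")
        self.gene_pos.to_csv(outdir / "gene_pos.tsv", sep="\t")
        (outdir / "truth.json").write_text(self.truth.to_json())
        return outdir


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete cohort; all randomness flows from config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    clinical = generate_clinical(config, rng)
    genotypes, snp_pos, gene_pos, eqtl_pairs, csnp_ids = \
        generate_genotypes(config, rng)

    # latent prognostic frailty and true clinical stratum
    frailty = rng.normal(size=config.n_patients)
    lp_clin = true_clinical_predictor(clinical, config)
    med = np.median(lp_clin)
    stratum = np.where(lp_clin < med, "good",
                       np.where(lp_clin > med, "poor", "good"))

    # cSNP dosage contribution to the log-hazard
    snp_lp = np.zeros(config.n_patients)
    if csnp_ids:
        dos = genotypes.loc[csnp_ids].to_numpy(float)
        snp_lp = config.csnp_effect * (dos - dos.mean(axis=1,
                                                      keepdims=True)).sum(0)

    extra = config.frailty_sd * frailty + snp_lp
    survival, cens_surv = generate_survival(
        clinical, config, rng, extra_loghazard=extra, endpoint="survival")
    dfs, cens_dfs = generate_survival(
        clinical, config, rng, extra_loghazard=extra, endpoint="dfs")

    # planted cis-eQTL signal, applied to the genotyped (normal) tissue
    eqtl_term = np.zeros((config.n_genes, config.n_patients))
    gid_index = pd.Index(_gene_ids(config.n_genes))
    for snp, gene, effect in eqtl_pairs:
        dos = genotypes.loc[snp].to_numpy(float)
        eqtl_term[gid_index.get_loc(gene)] += effect * (dos - dos.mean())

    expr_tumor, expr_normal, signature_genes = generate_expression(
        clinical, config, rng, frailty=frailty, stratum_labels=stratum,
        eqtl_dosage_effect=eqtl_term)

    truth = PlantedTruth(
        clinical_effects=dict(config.clinical_effects),
        frailty_sd=config.frailty_sd,
        signature_genes=signature_genes,
        eqtl_pairs=[(s, g, e) for s, g, e in eqtl_pairs],
        csnp_ids=csnp_ids,
        csnp_effect=config.csnp_effect,
        realized_censoring={"survival": cens_surv, "dfs": cens_dfs},
        stratum_labels=dict(zip(clinical.index, stratum)),
    )
    return SyntheticCohort(clinical, survival, dfs, expr_tumor, expr_normal,
                           genotypes, snp_pos, gene_pos, truth, config)
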