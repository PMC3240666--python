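"""Genetics of expression and outcome: cis-eQTL and cSNP enrichment.

A cis-eQTL scan (simple linear regression of each expression trait on
additive dosage for every SNP within a window of the gene's TSS) is
thresholded by Benjamini-Hochberg FDR; the SNPs underlying significant
pairs are "eSNPs".  A cSNP scan fits one clinically adjusted Cox model
per SNP and keeps dosages with Wald p below alpha.  Enrichment of eSNPs
among cSNPs is scored hypergeometrically, and a randomized-endpoint
permutation rebuilds the scan under the null ("pseudo-cSNPs") to show
the enrichment is outcome-driven rather than structural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._cox import fit_batch
from .enrichment import OverlapResult, overlap_enrichment
from .survival import check_outcome

__all__ = [
    "EQTLResult", "CSNPResult", "cis_eqtl_scan", "bh_fdr", "csnp_scan",
    "esnp_csnp_enrichment", "pseudo_csnp_null",
]

logger = logging.getLogger(__name__)


@dataclass
class EQTLResult:
    """cis pairs tested, their p-values, and the FDR-thresholded calls."""

    pairs: pd.DataFrame         # columns snp, gene, beta, p
    q: float | None = None
    p_threshold: float | None = None
    n_discoveries: int = 0
    esnps: list = field(default_factory=list)

    def apply_fdr(self, q: float = 0.10) -> "EQTLResult":
        thr, flags = bh_fdr(self.pairs["p"].to_numpy(), q=q)
        hits = self.pairs.loc[flags]
        return EQTLResult(self.pairs, q, thr, int(flags.sum()),
                          sorted(hits["snp"].unique()))


@dataclass
class CSNPResult:
    endpoint: str
    alpha: float
    csnps: list                 # SNP ids with adjusted Wald p < alpha
    universe: list              # non-degenerate SNPs actually tested
    pvalues: pd.Series          # per-tested-SNP dosage Wald p


def cis_eqtl_scan(genotypes: pd.DataFrame, expr: pd.DataFrame,
                  snp_pos: pd.DataFrame, gene_pos: pd.DataFrame,
                  window_bp: int = 1_000_000) -> EQTLResult:
    """Linear-regression p for every (SNP, gene) pair within the window.

    ``genotypes`` is SNPs x patients (dosage 0/1/2), ``expr`` genes x
    patients; patients are aligned by column intersection.  Monomorphic
    SNPs are skipped; genes without any cis SNP are omitted (counted in
    a log message).
    """
    common = genotypes.columns.intersection(expr.columns)
    if len(common) < 10:
        raise ValueError("cis scan needs >= 10 shared patients")
    G = genotypes[common].to_numpy(float)
    E = expr[common].to_numpy(float)
    n = len(common)

    missing = [i for i in expr.index if i not in gene_pos.index] + \
              [s for s in genotypes.index if s not in snp_pos.index]
    if missing:
        raise ValueError(f"positions missing for ids: {missing[:5]}")
    spos = snp_pos.loc[genotypes.index]
    gpos = gene_pos.loc[expr.index]

    poly = G.std(axis=1) > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("cis scan: %d monomorphic SNP(s) skipped", n_mono)

    # standardise once; two-sided t-test on the Pearson correlation is
    # exactly the simple-regression slope test
    Ec = E - E.mean(axis=1, keepdims=True)
    Es = Ec / np.where(Ec.std(axis=1, keepdims=True) == 0, np.inf,
                       Ec.std(axis=1, keepdims=True))
    Gc = G - G.mean(axis=1, keepdims=True)
    Gsd = Gc.std(axis=1, keepdims=True)
    Gs = Gc / np.where(Gsd == 0, np.inf, Gsd)

    schrom = spos["chrom"].to_numpy()
    sbp = spos["bp"].to_numpy()
    rows = []
    n_genes_skipped = 0
    snp_ids = np.asarray(genotypes.index)
    gene_ids = np.asarray(expr.index)
    for gi in range(E.shape[0]):
        chrom = gpos["chrom"].iloc[gi]
        tss = gpos["tss"].iloc[gi]
        cis = np.flatnonzero((schrom == chrom) & poly &
                             (np.abs(sbp - tss) <= window_bp))
        if cis.size == 0:
            n_genes_skipped += 1
            continue
        r = Gs[cis] @ Es[gi] / n
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(np.abs(tstat), n - 2)
        sd_e = E[gi].std()
        beta = r * sd_e / Gsd[cis, 0]
        for j, snp_i in enumerate(cis):
            rows.append((snp_ids[snp_i], gene_ids[gi], beta[j], p[j]))
    if n_genes_skipped:
        logger.info("cis scan: %d gene(s) without a cis SNP omitted",
                    n_genes_skipped)
    pairs = pd.DataFrame(rows, columns=["snp", "gene", "beta", "p"])
    return EQTLResult(pairs)


def bh_fdr(pvalues, q: float = 0.10):
    """Benjamini-Hochberg step-up.

    Returns ``(threshold, flags)`` where threshold is the largest
    ``p_(i) <= i q / m`` (0.0 if none) and flags marks ``p <= threshold``.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    crit = (np.arange(1, m + 1) / m) * q
    ok = order <= crit
    threshold = float(order[ok].max()) if ok.any() else 0.0
    return threshold, p <= threshold if ok.any() else np.zeros(m, bool)


def csnp_scan(genotypes: pd.DataFrame, outcome, clinical,
              alpha: float = 0.01, ties="efron") -> CSNPResult:
    """Adjusted Cox scan: one model per SNP (dosage + clinical covariates).

    ``clinical`` is the numeric adjustment matrix (patients x c), e.g.
    the selected clinicopathologic parameters.  Monomorphic SNPs are
    excluded from the universe.  Returns SNPs with dosage Wald p < alpha.
    """
    time, event, ids = check_outcome(outcome)
    common = genotypes.columns.intersection(np.asarray(ids))
    if len(common) != len(ids):
        raise ValueError("genotype columns do not cover the outcome ids")
    G = genotypes[np.asarray(ids)].to_numpy(float)
    A = clinical.to_numpy(float) if isinstance(clinical, pd.DataFrame) \
        else np.asarray(clinical, float)
    if A.ndim == 1:
        A = A[:, None]
    n = len(ids)
    M = G.shape[0]

    poly = G.std(axis=1) > 0
    snp_ids = np.asarray(genotypes.index)
    universe = list(snp_ids[poly])
    idx = np.flatnonzero(poly)
    p_dim = 1 + A.shape[1]
    X = np.empty((idx.size, n, p_dim))
    X[:, :, 0] = G[idx]
    X[:, :, 1:] = A[None]

    base = fit_batch(A, time, event, ties=ties)
    init = np.concatenate(([0.0], base.beta[0])) if base.converged[0] \
        else None
    res = fit_batch(X, time, event, ties=ties, init=init)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = res.beta[:, 0] / res.se[:, 0]
        p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.where(res.converged & np.isfinite(p), p, 1.0)
    pser = pd.Series(p, index=snp_ids[idx], name="p")
    hits = list(pser.index[pser < alpha])
    endpoint = getattr(outcome, "name", "survival")
    return CSNPResult(str(endpoint), alpha, hits, universe, pser)


def esnp_csnp_enrichment(esnps, csnps, snp_universe) -> OverlapResult:
    """Enrichment of eSNPs among cSNPs over the tested SNP universe."""
    if len(set(esnps)) == 0:
        raise ValueError("empty eSNP set: fold enrichment undefined")
    return overlap_enrichment(esnps, csnps, snp_universe)


@dataclass
class PseudoCSNPNull:
    observed_fold: float
    null_folds: np.ndarray
    null_counts: np.ndarray       # pseudo-cSNPs per permutation
    empirical_p: float            # fraction of null folds >= observed


def pseudo_csnp_null(genotypes, outcome, clinical, esnps,
                     alpha: float = 0.01, n_perm: int = 20, seed: int = 0,
                     ties="efron") -> PseudoCSNPNull:
    """Randomized-endpoint null for the eSNP-in-cSNP enrichment.

    Each permutation shuffles the (time, event) pairs jointly across
    patients (preserving the censoring pattern's marginal), reruns the
    adjusted Cox scan, and records the enrichment fold of ``esnps``
    among the resulting pseudo-cSNPs.  Permutations yielding zero
    pseudo-cSNPs contribute fold 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = csnp_scan(genotypes, outcome, clinical, alpha=alpha,
                         ties=ties)
    obs_fold = esnp_csnp_enrichment(
        esnps, observed.csnps, observed.universe).fold if observed.csnps \
        else 0.0

    folds = np.zeros(n_perm)
    counts = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(len(outcome))
        y_perm = outcome.iloc[perm].set_index(outcome.index)
        scan = csnp_scan(genotypes, y_perm, clinical, alpha=alpha,
                         ties=ties)
        counts[b] = len(scan.csnps)
        if scan.csnps:
            folds[b] = esnp_csnp_enrichment(
                esnps, scan.csnps, scan.universe).fold
    emp_p = float(np.mean(folds >= obs_fold))
    return PseudoCSNPNull(obs_fold, folds, counts, emp_p)
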