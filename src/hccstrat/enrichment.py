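"""Gene-signature derivation and gene-set overlap enrichment.

Signatures are genes whose univariate Cox Wald p falls below a tiered
cutoff (genome-wide strict 2e-6, liberal 5e-4 / 0.01 / 0.05); overlap
against external gene lists is scored by fold enrichment
(observed / expected under random draws from the universe) and the
one-sided upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .survival import univariate_screen

__all__ = [
    "GeneSignature", "OverlapResult", "SIGNATURE_CUTOFFS",
    "derive_signature", "overlap_enrichment", "multi_list_membership",
]

logger = logging.getLogger(__name__)

#: tiered p-value cutoffs: genome-wide strict (Bonferroni scale), the
#: liberal comparison tier, and two permissive tiers
SIGNATURE_CUTOFFS = (2e-6, 5e-4, 0.01, 0.05)


@dataclass
class GeneSignature:
    endpoint: str
    tissue: str
    p_cutoff: float
    genes: list
    pvalues: pd.Series      # per-gene Cox Wald p, indexed by gene

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene ids must be unique")


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    universe: int
    overlap: int
    expected: float
    fold: float
    pvalue: float            # one-sided upper-tail hypergeometric

    def to_dict(self):
        return {"n_a": self.n_a, "n_b": self.n_b,
                "universe": self.universe, "overlap": self.overlap,
                "expected": self.expected, "fold": self.fold,
                "pvalue": self.pvalue}


def derive_signature(expr, outcome, p_cutoff: float = 5e-4,
                     adjusted: bool = False, clinical=None,
                     endpoint: str = "survival", tissue: str = "normal",
                     ties="efron") -> GeneSignature:
    """Genes associated with the endpoint at ``p <= p_cutoff``.

    ``expr`` is genes x patients.  By default the screen is unadjusted
    (comparable to published signatures built without clinicopathologic
    conditioning); ``adjusted=True`` includes the supplied clinical
    covariates in each per-gene model.
    """
    scr = univariate_screen(expr.T, outcome,
                            adjust=clinical if adjusted else None,
                            ties=ties)
    hits = scr.index[scr["p"] <= p_cutoff]
    return GeneSignature(endpoint, tissue, p_cutoff, list(hits),
                         scr.loc[hits, "p"])


def overlap_enrichment(set_a, set_b, universe) -> OverlapResult:
    """Fold enrichment and hypergeometric p for the overlap of two sets.

    Members outside the universe are dropped with a warning.  With
    ``k = |A ∩ B|`` and ``N = |universe|``, ``fold = k N / (|A| |B|)``
    (0 when k = 0) and ``p = P(X >= k)`` for
    ``X ~ Hypergeometric(N, |A|, |B|)``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    dropped = len(a - universe) + len(b - universe)
    if dropped:
        logger.warning("overlap_enrichment: %d gene(s) outside the "
                       "universe dropped", dropped)
    a &= universe
    b &= universe
    N, na, nb = len(universe), len(a), len(b)
    k = len(a & b)
    expected = na * nb / N
    fold = k / expected if (k > 0 and expected > 0) else 0.0
    # P(X >= k); sf(k-1) is the exact upper tail
    p = float(sps.hypergeom.sf(k - 1, N, na, nb)) if k > 0 else 1.0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return OverlapResult(na, nb, N, k, expected, fold, p)


def multi_list_membership(pvalues: pd.Series, published: dict,
                          strict_cutoff: float = 2e-6,
                          liberal_cutoff: float = 0.01,
                          min_lists: int = 2) -> pd.DataFrame:
    """Two-part membership table of prognosis-associated genes.

    Part 1 (``part = "genome_wide"``): genes whose own-study Cox p is at
    or below the genome-wide strict cutoff.  Part 2 (``part =
    "recurrent"``): genes present in at least ``min_lists`` published
    lists.  Per-list membership is printed "1"/"-"; the own-study p is
    printed only when at or below the liberal cutoff, else "-".
    """
    if pvalues.empty or not published:
        raise ValueError("need non-empty p-values and published lists")
    list_names = list(published)
    sets = {name: set(g for g in genes) for name, genes in
            published.items()}

    rows = []
    part1 = pvalues.index[pvalues <= strict_cutoff]
    for g in part1:
        row = {"gene": g, "part": "genome_wide",
               "p": _fmt_p(pvalues[g], liberal_cutoff)}
        for name in list_names:
            row[name] = "1" if g in sets[name] else "-"
        rows.append(row)

    all_listed = set().union(*sets.values())
    for g in sorted(all_listed, key=str):
        count = sum(g in sets[name] for name in list_names)
        if count < min_lists or g in set(part1):
            continue
        p = pvalues.get(g, np.nan)
        row = {"gene": g, "part": "recurrent",
               "p": _fmt_p(p, liberal_cutoff)}
        for name in list_names:
            row[name] = "1" if g in sets[name] else "-"
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "part", "p", *list_names])


def _fmt_p(p, cutoff):
    if p is None or (isinstance(p, float) and (np.isnan(p) or p > cutoff)):
        return "-"
    return f"{p:.3g}"
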