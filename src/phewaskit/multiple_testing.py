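"""Significance thresholds for the phenome scan.

Three corrections are supported: Bonferroni (alpha/m), the Benjamini-
Hochberg step-up threshold at FDR q, and simpleM — the eigenvalue-based
effective number of independent tests: the smallest x such that the top-x
eigenvalues of the test correlation matrix explain at least a fraction C
(default 0.995) of its total variance.  For a SNP x phenotype scan the
combined Meff defaults to the product of the SNP-side and phenotype-side
Meff values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "bonferroni_threshold",
    "bh_threshold",
    "simple_m",
    "annotate_significance",
    "phenotype_correlation",
    "snp_correlation",
    "make_thresholds",
]


@dataclass
class ThresholdSet:
    alpha: float
    m: int
    bonferroni_p: float
    bh_p: float
    meff: int
    simplem_p: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "m": self.m,
            "bonferroni_p": self.bonferroni_p, "bh_p": self.bh_p,
            "meff": self.meff, "simplem_p": self.simplem_p,
        }


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def bh_threshold(pvals, q: float = 0.05) -> float:
    """Benjamini-Hochberg step-up p-value threshold (0 when nothing passes).

    The threshold is the largest p_(k) with p_(k) <= k*q/m; every test with
    p <= threshold is a discovery.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    rejected, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    return float(p[rejected].max()) if rejected.any() else 0.0


def simple_m(corr, c: float = 0.995) -> int:
    """Effective number of independent tests among correlated tests.

    Eigenvalues of the correlation matrix are sorted descending (numerically
    negative ones clipped at 0); Meff is the smallest x whose leading
    eigenvalues explain at least fraction ``c`` of the total variance.
    """
    m = np.asarray(corr, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    eig = np.linalg.eigvalsh(m)
    eig = np.clip(eig, 0.0, None)[::-1]
    total = eig.sum()
    if total <= 0:
        raise ValueError("degenerate correlation matrix (zero total variance)")
    frac = np.cumsum(eig) / total
    return int(np.searchsorted(frac, c) + 1)


def phenotype_correlation(matrix) -> pd.DataFrame:
    """Correlation of phenotype case indicators (CASE=1, CONTROL=0,
    EXCLUDED=missing) with pairwise-complete observations.

    Constant (or never jointly observed) phenotype pairs contribute zero
    correlation; constant phenotypes are dropped.
    """
    ind = matrix.case_indicator()
    keep = [c for c in ind.columns if ind[c].dropna().nunique() > 1]
    corr = ind[keep].corr(min_periods=2)
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def snp_correlation(genotypes) -> pd.DataFrame:
    """Pairwise-complete correlation of SNP dosages."""
    corr = genotypes.dosages.T.corr(min_periods=2).fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def make_thresholds(pvals, alpha: float = 0.05, fdr_q: float = 0.05,
                    meff: int | None = None, simplem_c: float = 0.995,
                    phenotype_corr=None, snp_corr=None) -> ThresholdSet:
    """Assemble the threshold report for one test family.

    ``meff`` may be given directly; otherwise it is the product of the
    simpleM values of the supplied correlation matrices (falling back to the
    raw test count when neither is given).
    """
    p = np.asarray(pvals, dtype=float)
    m = int(p.size)
    if meff is None:
        factors = []
        if phenotype_corr is not None:
            factors.append(simple_m(phenotype_corr, simplem_c))
        if snp_corr is not None:
            factors.append(simple_m(snp_corr, simplem_c))
        meff = int(np.prod(factors)) if factors else m
    meff = min(meff, m) if m else meff
    return ThresholdSet(
        alpha=alpha, m=m,
        bonferroni_p=bonferroni_threshold(alpha, m),
        bh_p=bh_threshold(p, fdr_q),
        meff=meff,
        simplem_p=bonferroni_threshold(alpha, meff),
    )


def annotate_significance(results: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Add pass_bonferroni / pass_bh / pass_simplem flags (p equal to a
    threshold counts as passing)."""
    out = results.copy()
    if len(out) == 0:
        for col in ("pass_bonferroni", "pass_bh", "pass_simplem"):
            out[col] = pd.Series(dtype=bool)
        return out
    out["pass_bonferroni"] = out["p"] <= thresholds.bonferroni_p
    out["pass_bh"] = out["p"] <= thresholds.bh_p
    out["pass_simplem"] = out["p"] <= thresholds.simplem_p
    log.info("significance: %d bonferroni, %d BH, %d simpleM of %d",
             int(out["pass_bonferroni"].sum()), int(out["pass_bh"].sum()),
             int(out["pass_simplem"].sum()), len(out))
    return out
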