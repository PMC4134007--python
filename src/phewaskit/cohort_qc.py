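"""Genotype QC, relatedness pruning, BMI cleaning, and LD grouping.

QC retains SNPs with call rate > 99% and MAF > 0.01 (and imputation info
>= 0.7 where an info score is present).  Relatedness is resolved on the graph
of pairs with IBD pi-hat > 0.25: one member of each connected component is
kept, chosen uniformly at random with a seeded generator.  BMI is cleaned to
the plausible range [15, 70] kg/m^2 and averaged per person.  LD to the index
SNP is the squared Pearson correlation of unphased dosages (composite LD),
grouped as high (r^2 > 0.80), moderate (0.60 < r^2 <= 0.80), low (<= 0.60).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeSet",
    "LdGroup",
    "minor_allele_freq",
    "qc_filter",
    "hard_call",
    "prune_related",
    "clean_bmi",
    "average_bmi_table",
    "ld_r2",
    "ld_group",
]


class MonomorphicError(ValueError):
    pass


@dataclass
class GenotypeSet:
    """Dosage matrix (SNPs x individuals, NaN = missing) with SNP metadata.

    ``meta`` is indexed by snp_id with columns ``effect_allele``,
    ``other_allele`` and optional ``info`` (NaN for directly genotyped SNPs).
    """

    dosages: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.dosages.index)
        if "info" not in self.meta.columns:
            self.meta = self.meta.assign(info=np.nan)

    @property
    def individuals(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.index)

    def dosage(self, snp_id: str) -> pd.Series:
        return self.dosages.loc[snp_id]

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=1)

    def maf(self) -> pd.Series:
        return pd.Series(
            {s: minor_allele_freq(self.dosages.loc[s].to_numpy()) for s in self.snp_ids},
            name="maf",
        )

    def subset_individuals(self, ids) -> "GenotypeSet":
        keep = [i for i in self.individuals if i in set(ids)]
        return GenotypeSet(self.dosages.loc[:, keep], self.meta.copy())

    def subset_snps(self, snp_ids) -> "GenotypeSet":
        keep = [s for s in self.snp_ids if s in set(snp_ids)]
        return GenotypeSet(self.dosages.loc[keep], self.meta.loc[keep])


def minor_allele_freq(dosages) -> float:
    """min(f, 1-f) with f = sum(dosage) / (2 * n non-missing)."""
    arr = np.asarray(dosages, dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("all dosages missing")
    f = float(arr[mask].sum()) / (2.0 * n)
    return min(f, 1.0 - f)


def qc_filter(genotypes: GenotypeSet, min_call_rate: float = 0.99,
              min_maf: float = 0.01, min_info: float = 0.7):
    """Retain SNPs with call rate > threshold, MAF > threshold and (where an
    info score is present) info >= ``min_info``.

    Returns ``(filtered GenotypeSet, drop log DataFrame)``.
    """
    for t in (min_call_rate, min_maf, min_info):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    call = genotypes.call_rate()
    drops = []
    keep = []
    for snp in genotypes.snp_ids:
        reasons = []
        if not call[snp] > min_call_rate:
            reasons.append(f"call_rate {call[snp]:.4f} <= {min_call_rate}")
        try:
            maf = minor_allele_freq(genotypes.dosages.loc[snp].to_numpy())
        except ValueError:
            maf = np.nan
            reasons.append("all dosages missing")
        if not maf > min_maf:
            reasons.append(f"maf {maf:.4f} <= {min_maf}")
        info = genotypes.meta.loc[snp, "info"]
        if not pd.isna(info) and info < min_info:
            reasons.append(f"info {info:.3f} < {min_info}")
        if reasons:
            drops.append({"snp_id": snp, "reason": "; ".join(reasons)})
            log.info("QC drop %s: %s", snp, "; ".join(reasons))
        else:
            keep.append(snp)
    drop_log = pd.DataFrame(drops, columns=["snp_id", "reason"])
    return genotypes.subset_snps(keep), drop_log


def hard_call(posteriors) -> int:
    """Genotype from posterior probabilities (p0, p1, p2): the maximum-
    posterior dosage, ties broken toward the lower dosage."""
    p = np.asarray(posteriors, dtype=float)
    if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"invalid posterior simplex: {posteriors!r}")
    return int(np.argmax(p))  # argmax returns the first (lowest) maximizer


def prune_related(individuals, pairs: pd.DataFrame, threshold: float = 0.25,
                  rng=None) -> set[str]:
    """Resolve relatedness: among pairs with pi_hat > ``threshold``, keep one
    member per connected component (uniformly at random); keep all singletons.

    ``pairs`` has columns ``id_a, id_b, pi_hat``.
    """
    rng = np.random.default_rng(rng)
    ids = [str(i) for i in individuals]
    known = set(ids)
    g = nx.Graph()
    for row in pairs.itertuples(index=False):
        a, b = str(row.id_a), str(row.id_b)
        if a == b:
            raise ValueError(f"self-pair in IBD table: {a}")
        if a not in known or b not in known:
            raise ValueError(f"IBD pair references unknown individual: {a}, {b}")
        if row.pi_hat > threshold:
            g.add_edge(a, b)
    retained = set(ids)
    for component in nx.connected_components(g):
        members = sorted(component)
        chosen = members[rng.integers(len(members))]
        retained -= set(members)
        retained.add(chosen)
        log.info("related group %s -> kept %s", members, chosen)
    return retained


def clean_bmi(measurements, lo: float = 15.0, hi: float = 70.0) -> float:
    """Mean of in-range BMI values (inclusive bounds); NaN if none in range."""
    arr = np.asarray(list(measurements), dtype=float)
    arr = arr[~np.isnan(arr)]
    arr = arr[(arr >= lo) & (arr <= hi)]
    if arr.size == 0:
        return float("nan")
    return float(arr.mean())


def average_bmi_table(bmi: pd.DataFrame, lo: float = 15.0, hi: float = 70.0) -> pd.Series:
    """Per-person cleaned average BMI from a long table ``person_id, bmi``."""
    grouped = bmi.assign(person_id=bmi["person_id"].astype(str)).groupby("person_id")["bmi"]
    return grouped.apply(lambda v: clean_bmi(v, lo, hi)).rename("avg_bmi")


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete
    individuals (composite LD for unphased genotypes)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise ValueError("need >= 2 pairwise-complete individuals")
    if a.std() == 0 or b.std() == 0:
        raise MonomorphicError("monomorphic dosage vector: LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


class LdGroup(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"


def ld_group(r2: float) -> LdGroup:
    """High (r^2 > 0.80), moderate (0.60 < r^2 <= 0.80), low (r^2 <= 0.60)."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r^2 out of range: {r2}")
    if r2 > 0.80:
        return LdGroup.HIGH
    if r2 > 0.60:
        return LdGroup.MODERATE
    return LdGroup.LOW
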