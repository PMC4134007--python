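"""Fixed-effects inverse-variance meta-analysis across cohorts.

Per-cohort log odds ratios are harmonized to a common effect allele, then
pooled with weights w_i = 1/se_i^2:

    beta_meta = sum(w_i * beta_i) / sum(w_i),   se_meta = sum(w_i)^(-1/2)
    z = beta_meta / se_meta,                    p = 2 * Phi(-|z|)

Only cells testable in every cohort (shared SNP, shared phenotype, converged
fit) are pooled.  Heterogeneity (Cochran's Q, I^2) is computed and logged but
never gates results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phewas_scan import Z975

log = logging.getLogger(__name__)

__all__ = ["CohortEffect", "MetaResult", "ci_to_se", "harmonize",
           "inverse_variance_meta", "meta_phewas"]


@dataclass
class CohortEffect:
    cohort: str
    beta: float
    se: float
    effect_allele: str = ""
    other_allele: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"standard error must be positive: {self.se}")


@dataclass
class MetaResult:
    snp_id: str
    phecode: str
    beta: float
    se: float
    or_: float
    ci_lo: float
    ci_hi: float
    z: float
    p: float
    k: int
    q_stat: float = float("nan")
    i2: float = float("nan")


def ci_to_se(or_: float, ci_lo: float, ci_hi: float) -> float:
    """Reconstruct the log-OR standard error from a 95% CI:
    (ln hi - ln lo) / (2 * z_0.975)."""
    if not (0 < ci_lo <= or_ <= ci_hi):
        raise ValueError(f"CI ordering violated: {ci_lo} <= {or_} <= {ci_hi}")
    return float((np.log(ci_hi) - np.log(ci_lo)) / (2.0 * Z975))


def harmonize(effects: list[CohortEffect]) -> list[CohortEffect]:
    """Express every beta per copy of the first cohort's effect allele.

    Swapped allele labels flip the beta sign; non-matching allele sets are an
    error (no strand-ambiguity resolution is attempted).
    """
    if not effects:
        raise ValueError("no effects to harmonize")
    ref = effects[0]
    out = []
    for e in effects:
        if (e.effect_allele, e.other_allele) == (ref.effect_allele, ref.other_allele):
            out.append(e)
        elif (e.effect_allele, e.other_allele) == (ref.other_allele, ref.effect_allele):
            out.append(CohortEffect(e.cohort, -e.beta, e.se,
                                    ref.effect_allele, ref.other_allele))
        else:
            raise ValueError(
                f"allele mismatch for cohort {e.cohort}: "
                f"{e.effect_allele}/{e.other_allele} vs "
                f"{ref.effect_allele}/{ref.other_allele}"
            )
    return out


def inverse_variance_meta(effects: list[CohortEffect], snp_id: str = "",
                          phecode: str = "") -> MetaResult:
    """Pool aligned per-cohort effects with inverse-variance weights."""
    if not effects:
        raise ValueError("no effects to pool")
    betas = np.array([e.beta for e in effects], dtype=float)
    ses = np.array([e.se for e in effects], dtype=float)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (betas - beta) ** 2))
    dof = len(effects) - 1
    i2 = float(max(0.0, (q - dof) / q)) if q > 0 and dof > 0 else 0.0
    return MetaResult(
        snp_id, phecode, beta, se,
        float(np.exp(beta)), float(np.exp(beta - Z975 * se)),
        float(np.exp(beta + Z975 * se)), z, p, len(effects), q, i2,
    )


def _testable(table: pd.DataFrame) -> pd.DataFrame:
    ok = table["converged"].astype(bool) & table["beta"].notna() & (table["se"] > 0)
    return table.loc[ok]


def meta_phewas(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool per-cohort scan tables over the intersection of SNPs and of
    phenotypes testable in every cohort.

    ``tables`` maps cohort label -> scan table (one row per snp x phecode as
    produced by :func:`phewaskit.phewas_scan.run_phewas`).
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis needs >= 2 cohort tables")
    usable = {name: _testable(t).set_index(["snp_id", "phecode"]) for name, t in tables.items()}
    keys = None
    for t in usable.values():
        keys = t.index if keys is None else keys.intersection(t.index)
    keys = keys.sort_values()
    log.info("meta intersection: %d testable snp x phenotype cells across %d cohorts",
             len(keys), len(tables))
    if len(keys) == 0:
        log.warning("empty intersection of testable cells; empty meta table")
    rows = []
    for snp, phe in keys:
        effects = []
        n_cases = n_controls = 0
        extra = {}
        for name, t in usable.items():
            r = t.loc[(snp, phe)]
            effects.append(CohortEffect(name, float(r["beta"]), float(r["se"]),
                                        str(r.get("effect_allele", "")),
                                        str(r.get("other_allele", ""))))
            n_cases += int(r["n_cases"])
            n_controls += int(r["n_controls"])
            for col in ("description", "category", "bmi_adjusted"):
                if col in r.index:
                    extra[col] = r[col]
        m = inverse_variance_meta(harmonize(effects), snp_id=snp, phecode=phe)
        rows.append({
            "snp_id": snp, "phecode": phe, **extra,
            "n_cases": n_cases, "n_controls": n_controls,
            "beta": m.beta, "se": m.se, "or": m.or_,
            "ci_lo": m.ci_lo, "ci_hi": m.ci_hi,
            "z": m.z, "p": m.p, "k": m.k, "q_stat": m.q_stat, "i2": m.i2,
        })
        if m.i2 > 0.75:
            log.info("high heterogeneity for %s x %s: I2=%.2f", snp, phe, m.i2)
    return pd.DataFrame(rows)
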