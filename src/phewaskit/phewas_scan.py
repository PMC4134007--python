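"""Per-cohort association scan.

Each retained phenotype is regressed on a SNP's allele dosage (additive
coding) with logistic regression adjusted for age, sex, site and the first
three principal components, optionally also for average BMI; the SNP-BMI
relationship itself is assessed with ordinary least squares.  Effects are
reported as odds ratios with Wald 95% confidence intervals and two-sided
Wald p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort_qc import GenotypeSet
from .phenome_map import PhenotypeMatrix, Status

log = logging.getLogger(__name__)

#: exact 97.5% normal quantile used for all Wald intervals
Z975 = float(stats.norm.ppf(0.975))

#: a log-odds standard error above this flags quasi-separation
SE_FLAG = 10.0

__all__ = [
    "Z975",
    "AssocResult",
    "BmiAssocResult",
    "fit_logistic",
    "snp_phenotype_assoc",
    "run_phewas",
    "snp_bmi_assoc",
    "build_covariates",
    "SingleClassError",
    "RankDeficiencyError",
]


class SingleClassError(ValueError):
    """Outcome vector contains only cases or only controls."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient over complete cases."""


@dataclass
class AssocResult:
    """One SNP x phenotype logistic fit."""

    snp_id: str
    phecode: str
    beta: float
    se: float
    or_: float
    ci_lo: float
    ci_hi: float
    p: float
    n_cases: int
    n_controls: int
    bmi_adjusted: bool
    converged: bool
    reason: str = ""
    effect_allele: str = ""
    other_allele: str = ""

    def to_row(self) -> dict:
        row = asdict(self)
        row["or"] = row.pop("or_")
        return row


@dataclass
class BmiAssocResult:
    """Linear SNP-BMI association (kg/m^2 per effect allele)."""

    snp_id: str
    beta: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int


def build_covariates(demographics: pd.DataFrame, pcs: pd.DataFrame | None = None,
                     avg_bmi: pd.Series | None = None) -> pd.DataFrame:
    """Assemble the covariate frame: age, sex indicator (female=1),
    reference-coded site indicators, pc1..pc3 and optional avg_bmi."""
    demo = demographics.copy()
    demo["person_id"] = demo["person_id"].astype(str)
    demo = demo.set_index("person_id")
    cov = pd.DataFrame(index=demo.index)
    cov["age"] = demo["age"].astype(float)
    cov["sex_female"] = (demo["sex"].astype(str).str.upper() == "F").astype(float)
    if "site" in demo.columns:
        site = pd.get_dummies(demo["site"].astype(str), prefix="site", drop_first=True)
        cov = cov.join(site.astype(float))
    if pcs is not None:
        p = pcs.copy()
        p["person_id"] = p["person_id"].astype(str)
        p = p.set_index("person_id")
        for c in ("pc1", "pc2", "pc3"):
            cov[c] = p[c].astype(float)
    if avg_bmi is not None:
        cov["avg_bmi"] = avg_bmi.reindex(cov.index).astype(float)
    return cov


def _prepare_design(X: pd.DataFrame) -> pd.DataFrame:
    """Add intercept and drop constant (non-intercept) columns, e.g. the site
    term within a single-site cohort."""
    X = X.loc[:, [c for c in X.columns if X[c].nunique(dropna=False) > 1]]
    return sm.add_constant(X, has_constant="add")


def fit_logistic(y, X):
    """Maximum-likelihood logistic fit (Newton/IRLS, tol 1e-8, <= 25 steps).

    Returns ``(beta, se, converged)`` as pandas Series aligned with the
    columns of ``X``.  Standard errors come from the inverse observed
    information; non-convergence or any log-odds se > 10 clears the
    ``converged`` flag.
    """
    y = np.asarray(y, dtype=float)
    Xd = pd.DataFrame(X)
    if len(np.unique(y)) < 2:
        raise SingleClassError("outcome has a single class")
    arr = Xd.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank deficient (columns: {list(Xd.columns)})"
        )
    try:
        fit = sm.Logit(y, Xd.astype(float)).fit(
            method="newton", maxiter=25, tol=1e-8, disp=0, warn_convergence=False
        )
        beta = fit.params
        se = fit.bse
        converged = bool(fit.mle_retvals["converged"])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        nan = pd.Series(np.nan, index=Xd.columns)
        return nan, nan, False
    if not np.all(np.isfinite(se)) or np.nanmax(se) > SE_FLAG:
        converged = False
    return beta, se, converged


def _wald(beta: float, se: float):
    or_ = float(np.exp(beta))
    ci_lo = float(np.exp(beta - Z975 * se))
    ci_hi = float(np.exp(beta + Z975 * se))
    z = beta / se if se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    p = min(max(p, np.nextafter(0, 1)), 1.0) if np.isfinite(p) else p
    return or_, ci_lo, ci_hi, p


def snp_phenotype_assoc(dosage: pd.Series, status: pd.Series,
                        covariates: pd.DataFrame | None, adjust_bmi: bool,
                        snp_id: str = "", phecode: str = "",
                        effect_allele: str = "", other_allele: str = "") -> AssocResult:
    """Additive-model logistic association of one phenotype with one SNP.

    EXCLUDED individuals and incomplete cases are dropped before fitting;
    when ``adjust_bmi`` the ``avg_bmi`` column joins the design and persons
    without a cleaned BMI are dropped.
    """
    idx = status.index[status != Status.EXCLUDED]
    df = pd.DataFrame({"dosage": dosage.reindex(idx)})
    if covariates is not None and len(covariates.columns):
        cov = covariates.reindex(idx)
        if adjust_bmi:
            if "avg_bmi" not in cov.columns:
                raise ValueError("adjust_bmi requires an avg_bmi covariate column")
        else:
            cov = cov.drop(columns=["avg_bmi"], errors="ignore")
        df = df.join(cov)
    elif adjust_bmi:
        raise ValueError("adjust_bmi requires an avg_bmi covariate column")
    df["y"] = (status.reindex(idx) == Status.CASE).astype(float)
    df = df.dropna()
    n_cases = int(df["y"].sum())
    n_controls = int(len(df) - n_cases)

    def untestable(reason: str) -> AssocResult:
        return AssocResult(snp_id, phecode, np.nan, np.nan, np.nan, np.nan,
                           np.nan, np.nan, n_cases, n_controls, adjust_bmi,
                           False, reason, effect_allele, other_allele)

    if n_cases == 0 or n_controls == 0:
        return untestable("single-class outcome after exclusions")
    X = _prepare_design(df.drop(columns="y"))
    if "dosage" not in X.columns:
        return untestable("dosage constant among analyzed individuals")
    try:
        beta, se, converged = fit_logistic(df["y"], X)
    except RankDeficiencyError as exc:
        return untestable(str(exc))
    b, s = float(beta["dosage"]), float(se["dosage"])
    if not np.isfinite(b):
        return untestable("fit did not converge")
    or_, lo, hi, p = _wald(b, s)
    return AssocResult(snp_id, phecode, b, s, or_, lo, hi, p, n_cases,
                       n_controls, adjust_bmi, converged, "",
                       effect_allele, other_allele)


def run_phewas(genotypes: GenotypeSet, matrix: PhenotypeMatrix,
               covariates: pd.DataFrame, adjust_bmi: bool = False,
               pmap=None) -> pd.DataFrame:
    """Scan every SNP against every retained phenotype.

    Returns one row per (snp_id, phecode) in deterministic order; untestable
    cells are kept with their reason rather than dropped.
    """
    rows = []
    snp_ids = sorted(genotypes.snp_ids)
    phecodes = sorted(matrix.phecodes, key=float)
    for snp in snp_ids:
        dosage = genotypes.dosage(snp)
        ea = str(genotypes.meta.loc[snp, "effect_allele"])
        oa = str(genotypes.meta.loc[snp, "other_allele"])
        for phe in phecodes:
            res = snp_phenotype_assoc(
                dosage, matrix.status[phe], covariates, adjust_bmi,
                snp_id=snp, phecode=phe, effect_allele=ea, other_allele=oa,
            )
            row = res.to_row()
            if pmap is not None and phe in pmap:
                info = pmap.info(phe)
                row["description"] = info.description
                row["category"] = info.category
            rows.append(row)
    out = pd.DataFrame(rows)
    n_untestable = int((~out["converged"]).sum()) if len(out) else 0
    log.info("scan (bmi_adjusted=%s): %d cells, %d flagged", adjust_bmi,
             len(out), n_untestable)
    return out


def snp_bmi_assoc(dosage: pd.Series, avg_bmi: pd.Series,
                  covariates: pd.DataFrame | None = None,
                  snp_id: str = "") -> BmiAssocResult:
    """OLS of average BMI on allele dosage plus covariates."""
    df = pd.DataFrame({"dosage": dosage, "avg_bmi": avg_bmi})
    if covariates is not None and len(covariates.columns):
        df = df.join(covariates.drop(columns=["avg_bmi"], errors="ignore"))
    df = df.dropna()
    X = _prepare_design(df.drop(columns="avg_bmi"))
    if len(df) < X.shape[1] + 1:
        raise ValueError("too few complete cases for OLS")
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise RankDeficiencyError("BMI design matrix rank deficient")
    fit = sm.OLS(df["avg_bmi"].astype(float), X.astype(float)).fit()
    b = float(fit.params["dosage"])
    se = float(fit.bse["dosage"])
    p = float(fit.pvalues["dosage"])
    return BmiAssocResult(snp_id, b, se, b - Z975 * se, b + Z975 * se, p, len(df))
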