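"""Synthetic two-cohort EHR-linked genotype studies with planted effects.

The generator emulates the statistical structure of a two-cohort,
European-ancestry-like PheWAS of an obesity-associated locus:

* an index SNP at MAF 0.41 plus satellite SNPs built per haplotype by
  copying the index allele with probability sqrt(target r^2) (equal-MAF
  satellites hit the target r^2 in expectation);
* BMI with latent mean 29.5 and SD 7.0 kg/m^2, a planted per-allele effect
  of 0.535 kg/m^2, repeated noisy measurements and out-of-range outliers;
* phenotypes drawn from logistic models whose linear predictor combines a
  direct per-allele effect with a BMI-mediated channel
  (logit(baseline) + direct_log_or * dosage + bmi_log_or * (BMI - mean)),
  so BMI-mediated effects attenuate under BMI adjustment and direct
  pleiotropic effects do not;
* ICD-9 billing events: true cases receive 2-5 codes on distinct days while
  non-cases emit a single mention at a configurable rate, exercising the
  two-distinct-days case rule and the single-mention control exclusion;
* planted related pairs (pi-hat ~ 0.5) and a machine-readable truth table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_qc import GenotypeSet, ld_r2, minor_allele_freq
from .phenome_map import PhecodeEntry, PhecodeMap, load_fixture_map

log = logging.getLogger(__name__)

__all__ = [
    "PlantedEffect",
    "SatelliteSnp",
    "SimConfig",
    "CohortBundle",
    "StudyBundle",
    "default_phenotype_models",
    "default_satellites",
    "build_sim_map",
    "generate_genotypes",
    "generate_bmi",
    "generate_phenotypes_and_events",
    "generate_study",
    "write_study",
]

INDEX_SNP = "rs_index"


@dataclass(frozen=True)
class PlantedEffect:
    """Planted generative model for one phenotype."""

    phecode: str
    baseline_prevalence: float
    direct_log_or: float = 0.0  # log OR per effect allele, direct channel
    bmi_log_or: float = 0.0     # log OR per kg/m^2, mediation channel
    sex_restriction: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class SatelliteSnp:
    snp_id: str
    target_r2: float
    maf: float
    info: float = float("nan")  # imputation info score; NaN = genotyped


def default_satellites() -> tuple[SatelliteSnp, ...]:
    """LD structure mirroring the high/moderate/low groups around the index."""
    return (
        SatelliteSnp("rs_sat100", 1.00, 0.41, 0.98),
        SatelliteSnp("rs_sat092", 0.92, 0.37, 0.96),
        SatelliteSnp("rs_sat072", 0.72, 0.47, 0.95),
        SatelliteSnp("rs_sat062", 0.62, 0.42, 0.93),
        SatelliteSnp("rs_sat006", 0.06, 0.39, 0.91),
    )


def default_phenotype_models() -> tuple[PlantedEffect, ...]:
    """Planted architecture: BMI-mediated, partially mediated, direct
    (including a protective, female-only effect) and named null phenotypes."""
    return (
        # fully BMI-mediated weight phenotypes; steep BMI slopes because these
        # diagnoses are (near-)threshold functions of BMI itself
        PlantedEffect("278.1", 0.08, 0.0, 0.60),    # obesity
        PlantedEffect("278.11", 0.005, 0.0, 0.80),  # morbid obesity
        PlantedEffect("278.12", 0.30, 0.0, 0.45),   # overweight
        PlantedEffect("327.3", 0.06, 0.0, 0.20),    # sleep apnea
        # partially mediated: direct ln(1.09) + BMI channel
        PlantedEffect("250.2", 0.10, math.log(1.09), 0.08),
        # direct pleiotropic effects, no BMI channel
        PlantedEffect("610.1", 0.10, math.log(0.82), 0.0, "female"),
        PlantedEffect("571.5", 0.03, math.log(1.19), 0.03),
        PlantedEffect("041.1", 0.05, math.log(1.25), 0.0),   # staphylococcus
        PlantedEffect("041.2", 0.03, math.log(1.15), 0.0),   # streptococcus
        PlantedEffect("480.1", 0.015, math.log(1.15), 0.0),  # pneumococcal pna
        PlantedEffect("038.1", 0.01, math.log(1.15), 0.0),   # gram+ septicemia
        # named null phenotypes at common-diagnosis prevalences
        PlantedEffect("401.1", 0.55),
        PlantedEffect("272.1", 0.45),
        PlantedEffect("530.11", 0.30),
        PlantedEffect("729.5", 0.40),
        PlantedEffect("780.7", 0.45),
        PlantedEffect("740.1", 0.25),
    )


GRAM_POSITIVE_PHECODES = ("038.1", "041.1", "041.2", "480.1")


@dataclass
class SimConfig:
    """Study conditions for the generator.  Defaults emulate the two-cohort
    design: n = 10,487 + 13,711, index MAF 0.41, BMI ~ Normal(29.5, 7.0^2)
    with a 0.535 kg/m^2 per-allele effect."""

    n_per_cohort: tuple[int, ...] = (10487, 13711)
    cohort_names: tuple[str, ...] = ("cohort1", "cohort2")
    seed: int = 0
    index_maf: float = 0.41
    satellites: tuple[SatelliteSnp, ...] = field(default_factory=default_satellites)
    #: SNPs available per cohort (None = all); the second cohort defaults to
    #: a three-SNP subset so the meta intersection logic is exercised
    cohort_snp_subsets: dict | None = None
    swap_index_alleles: bool = True  # second cohort labels the index SNP by the other allele
    bmi_mean: float = 29.5
    bmi_sd: float = 7.0
    bmi_beta_per_allele: float = 0.535
    bmi_measure_sd: float = 1.5
    n_bmi_measurements: tuple[int, int] = (2, 5)
    bmi_outlier_rate: float = 0.01
    phenotype_models: tuple[PlantedEffect, ...] = field(default_factory=default_phenotype_models)
    n_null_phenotypes: int = 20
    null_prevalence_range: tuple[float, float] = (0.02, 0.15)
    single_mention_rate: float = 0.05
    unmapped_event_rate: float = 0.2
    missing_dosage_rate: float = 0.002
    related_pair_fraction: float = 0.005
    sites_per_cohort: tuple[int, ...] = (3, 1)
    female_fraction: float = 0.53
    age_range: tuple[float, float] = (40.0, 80.0)
    pc_sd: float = 0.1  # sd of the token ancestry PCs (variance 0.01)
    n_days: int = 3652  # 10-year event window
    date_start: str = "2004-01-01"

    def snp_subset(self, cohort: str) -> list[str] | None:
        if self.cohort_snp_subsets is not None:
            return self.cohort_snp_subsets.get(cohort)
        if cohort == self.cohort_names[-1] and len(self.cohort_names) > 1:
            subset = [INDEX_SNP]
            for sat in self.satellites:
                if sat.target_r2 >= 0.99 or sat.target_r2 <= 0.10:
                    subset.append(sat.snp_id)
            return subset
        return None


def build_sim_map(config: SimConfig) -> PhecodeMap:
    """Fixture map plus one synthetic null phecode entry per extra null
    phenotype (phecodes 900.0, 900.1, ...)."""
    entries = load_fixture_map().entries
    for i in range(config.n_null_phenotypes):
        code = f"{900 + i // 10}.{i % 10}"
        entries.append(PhecodeEntry(
            icd9=code, phecode=code, description=f"Synthetic null {i}",
            category="synthetic null", exclusion_lo=float(code),
            exclusion_hi=float(code), sex_restriction="none",
        ))
    return PhecodeMap(entries)


def null_phecodes(config: SimConfig) -> list[str]:
    return [f"{900 + i // 10}.{i % 10}" for i in range(config.n_null_phenotypes)]


def generate_genotypes(config: SimConfig, n: int, rng: np.random.Generator,
                       ids: list[str], snp_subset: list[str] | None = None) -> GenotypeSet:
    """Index + satellite genotypes via haplotype copying.

    Each satellite haplotype copies the index allele with probability
    sqrt(target_r2), else draws fresh at the satellite's own MAF; with equal
    MAFs the realized dosage r^2 equals the target in expectation (unequal
    MAFs lower the attainable ceiling, which is warned about).
    """
    hap = rng.random((n, 2)) < config.index_maf
    rows = {INDEX_SNP: hap.sum(axis=1).astype(float)}
    meta = {INDEX_SNP: {"effect_allele": "A", "other_allele": "C", "info": np.nan}}
    for sat in config.satellites:
        c = math.sqrt(sat.target_r2)
        if abs(sat.maf - config.index_maf) > 0.05 and 0 < sat.target_r2 < 1:
            log.warning("satellite %s: MAF %.2f differs from index %.2f; "
                        "attainable r^2 is below the target %.2f",
                        sat.snp_id, sat.maf, config.index_maf, sat.target_r2)
        copy = rng.random((n, 2)) < c
        fresh = rng.random((n, 2)) < sat.maf
        sat_hap = np.where(copy, hap, fresh)
        rows[sat.snp_id] = sat_hap.sum(axis=1).astype(float)
        meta[sat.snp_id] = {"effect_allele": "A", "other_allele": "G", "info": sat.info}
    dosages = pd.DataFrame(rows, index=ids).T
    if config.missing_dosage_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_dosage_rate
        dosages = dosages.mask(mask)
    gset = GenotypeSet(dosages, pd.DataFrame(meta).T)
    if snp_subset is not None:
        gset = gset.subset_snps(snp_subset)
    return gset


def generate_bmi(dosage: np.ndarray, config: SimConfig, rng: np.random.Generator,
                 ids: list[str]):
    """Latent BMI = Normal(mean, sd^2) + beta * dosage; repeated measurements
    with Normal(0, 1.5^2) error and out-of-range outliers at the configured
    rate.  Returns ``(true_bmi, long measurement table)``."""
    n = len(ids)
    true_bmi = rng.normal(config.bmi_mean, config.bmi_sd, n) \
        + config.bmi_beta_per_allele * np.nan_to_num(dosage)
    lo, hi = config.n_bmi_measurements
    k = rng.integers(lo, hi + 1, n)
    person = np.repeat(np.asarray(ids, dtype=object), k)
    values = np.repeat(true_bmi, k) + rng.normal(0.0, config.bmi_measure_sd, int(k.sum()))
    if config.bmi_outlier_rate > 0:
        out = rng.random(values.shape) < config.bmi_outlier_rate
        low_side = rng.random(values.shape) < 0.5
        outliers = np.where(low_side, rng.uniform(5.0, 14.9, values.shape),
                            rng.uniform(70.1, 95.0, values.shape))
        values = np.where(out, outliers, values)
    table = pd.DataFrame({"person_id": person, "bmi": values})
    return true_bmi, table


def _distinct_days(m: int, k: np.ndarray, n_days: int, rng: np.random.Generator):
    """Per case, k[i] strictly increasing day offsets (vectorized)."""
    kmax = int(k.max()) if m else 0
    day0 = rng.integers(0, n_days - 31 * kmax - 1, m)
    gaps = rng.integers(1, 31, (m, max(kmax - 1, 1)))
    cum = np.concatenate([np.zeros((m, 1), dtype=int), np.cumsum(gaps, axis=1)], axis=1)
    days = day0[:, None] + cum[:, :kmax]
    return days


def generate_phenotypes_and_events(ids: list[str], dosage: np.ndarray,
                                   true_bmi: np.ndarray, sex: np.ndarray,
                                   models, pmap: PhecodeMap, config: SimConfig,
                                   rng: np.random.Generator):
    """Draw case status per planted model and emit ICD-9 billing events.

    True cases receive 2-5 codes of the phenotype's ICD-9 group on distinct
    days; non-cases emit one single-day mention with probability
    ``single_mention_rate``.  Returns ``(events table, truth case frame)``.
    """
    n = len(ids)
    ids_arr = np.asarray(ids, dtype=object)
    start = pd.Timestamp(config.date_start)
    persons, days, codes = [], [], []
    truth = {}
    dos = np.nan_to_num(np.asarray(dosage, dtype=float))
    for model in models:
        eta = (math.log(model.baseline_prevalence / (1 - model.baseline_prevalence))
               + model.direct_log_or * dos
               + model.bmi_log_or * (true_bmi - config.bmi_mean))
        prob = 1.0 / (1.0 + np.exp(-eta))
        if model.sex_restriction == "female":
            prob = np.where(sex == "F", prob, 0.0)
        elif model.sex_restriction == "male":
            prob = np.where(sex == "M", prob, 0.0)
        case = rng.random(n) < prob
        truth[model.phecode] = case.astype(int)
        icd_codes = pmap.codes_for(model.phecode)
        case_idx = np.flatnonzero(case)
        m = case_idx.size
        if m:
            k = rng.integers(2, 6, m)
            daymat = _distinct_days(m, k, config.n_days, rng)
            take = np.arange(daymat.shape[1])[None, :] < k[:, None]
            persons.append(np.repeat(ids_arr[case_idx], k))
            days.append(daymat[take])
            codes.append(rng.choice(icd_codes, int(k.sum())))
        noncase_idx = np.flatnonzero(~case)
        if config.single_mention_rate > 0 and noncase_idx.size:
            single = noncase_idx[rng.random(noncase_idx.size) < config.single_mention_rate]
            if single.size:
                persons.append(ids_arr[single])
                days.append(rng.integers(0, config.n_days, single.size))
                codes.append(rng.choice(icd_codes, single.size))
    if config.unmapped_event_rate > 0:
        noise = np.flatnonzero(rng.random(n) < config.unmapped_event_rate)
        if noise.size:
            persons.append(ids_arr[noise])
            days.append(rng.integers(0, config.n_days, noise.size))
            codes.append(np.full(noise.size, "V70.0", dtype=object))
    if persons:
        events = pd.DataFrame({
            "person_id": np.concatenate(persons),
            "date": start + pd.to_timedelta(np.concatenate(days), unit="D"),
            "icd9": np.concatenate(codes),
        })
        events["date"] = events["date"].dt.strftime("%Y-%m-%d")
        events = events.sort_values(["person_id", "date", "icd9"], kind="mergesort")
        events = events.reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["person_id", "date", "icd9"])
    truth_frame = pd.DataFrame(truth, index=ids)
    return events, truth_frame


@dataclass
class CohortBundle:
    name: str
    demographics: pd.DataFrame   # person_id, age, sex, site
    covariates: pd.DataFrame     # person_id, pc1..pc3
    bmi: pd.DataFrame            # person_id, bmi (long)
    events: pd.DataFrame         # person_id, date, icd9
    genotypes: GenotypeSet
    ibd: pd.DataFrame            # id_a, id_b, pi_hat
    truth_cases: pd.DataFrame    # person x phecode planted case indicator
    true_bmi: pd.Series


@dataclass
class StudyBundle:
    config: SimConfig
    pmap: PhecodeMap
    cohorts: list[CohortBundle]
    truth: dict

    def cohort(self, name: str) -> CohortBundle:
        for c in self.cohorts:
            if c.name == name:
                return c
        raise KeyError(name)


def _all_models(config: SimConfig, rng: np.random.Generator):
    models = list(config.phenotype_models)
    lo, hi = config.null_prevalence_range
    for code in null_phecodes(config):
        models.append(PlantedEffect(code, float(rng.uniform(lo, hi))))
    return models


def generate_cohort(config: SimConfig, name: str, n: int, n_sites: int,
                    rng: np.random.Generator, models) -> CohortBundle:
    ids = [f"{name}_{i:06d}" for i in range(n)]
    gset = generate_genotypes(config, n, rng, ids, config.snp_subset(name))
    age = rng.uniform(*config.age_range, n).round(1)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    site = np.array([f"{name}_site{rng.integers(n_sites) + 1}" for _ in range(n)], dtype=object)
    demographics = pd.DataFrame({"person_id": ids, "age": age, "sex": sex, "site": site})
    pcs = pd.DataFrame({
        "person_id": ids,
        "pc1": rng.normal(0, config.pc_sd, n),
        "pc2": rng.normal(0, config.pc_sd, n),
        "pc3": rng.normal(0, config.pc_sd, n),
    })
    index_dosage = gset.dosages.loc[INDEX_SNP].to_numpy()
    true_bmi, bmi = generate_bmi(index_dosage, config, rng, ids)
    pmap = build_sim_map(config)
    events, truth_cases = generate_phenotypes_and_events(
        ids, index_dosage, true_bmi, sex, models, pmap, config, rng)
    n_pairs = int(round(config.related_pair_fraction * n))
    chosen = rng.choice(n, 2 * n_pairs, replace=False) if n_pairs else np.array([], int)
    ibd = pd.DataFrame({
        "id_a": [ids[i] for i in chosen[0::2]],
        "id_b": [ids[i] for i in chosen[1::2]],
        "pi_hat": rng.uniform(0.4, 0.6, n_pairs),
    })
    if config.swap_index_alleles and name == config.cohort_names[-1] and len(config.cohort_names) > 1:
        # label the index SNP by the other allele: dosage counts the C allele
        gset.dosages.loc[INDEX_SNP] = 2.0 - gset.dosages.loc[INDEX_SNP]
        gset.meta.loc[INDEX_SNP, ["effect_allele", "other_allele"]] = ["C", "A"]
    return CohortBundle(name, demographics, pcs, bmi, events, gset, ibd,
                        truth_cases, pd.Series(true_bmi, index=ids, name="true_bmi"))


def generate_study(config: SimConfig | None = None) -> StudyBundle:
    """Deterministically generate the full multi-cohort study for a seed."""
    config = config or SimConfig()
    if len(config.n_per_cohort) != len(config.cohort_names):
        raise ValueError("n_per_cohort and cohort_names lengths differ")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.cohort_names) + 1)
    models = _all_models(config, np.random.default_rng(children[0]))
    pmap = build_sim_map(config)
    cohorts = []
    sites = config.sites_per_cohort
    for i, (name, n) in enumerate(zip(config.cohort_names, config.n_per_cohort)):
        n_sites = sites[i] if i < len(sites) else 1
        rng = np.random.default_rng(children[i + 1])
        cohorts.append(generate_cohort(config, name, n, n_sites, rng, models))
    truth = {
        "seed": config.seed,
        "models": [dataclasses.asdict(m) for m in models],
        "index_snp": INDEX_SNP,
        "satellites": [dataclasses.asdict(s) for s in config.satellites],
        "cohorts": {},
    }
    for c in cohorts:
        realized_r2 = {}
        dos = c.genotypes.dosages
        if INDEX_SNP in dos.index:
            idx = dos.loc[INDEX_SNP].to_numpy()
            for sat in config.satellites:
                if sat.snp_id in dos.index:
                    realized_r2[sat.snp_id] = ld_r2(idx, dos.loc[sat.snp_id].to_numpy())
        truth["cohorts"][c.name] = {
            "n": len(c.demographics),
            "realized_maf": {s: minor_allele_freq(dos.loc[s].to_numpy())
                             for s in c.genotypes.snp_ids},
            "realized_r2_to_index": realized_r2,
            "truth_case_counts": {k: int(v) for k, v in c.truth_cases.sum().items()},
        }
    return StudyBundle(config, pmap, cohorts, truth)


def write_study(bundle: StudyBundle, outdir) -> dict:
    """Write the study in the dialects the pipeline reads; returns the path map."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {"phecode_map": str(outdir / "phecode_map.csv"),
                   "truth": str(outdir / "truth.json"), "cohorts": {}}
    bundle.pmap.to_csv(outdir / "phecode_map.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    for c in bundle.cohorts:
        d = outdir / c.name
        d.mkdir(exist_ok=True)
        c.events.to_csv(d / "events.csv", index=False)
        c.demographics.to_csv(d / "demographics.csv", index=False)
        c.bmi.to_csv(d / "bmi.csv", index=False)
        c.covariates.to_csv(d / "covariates.csv", index=False)
        pio.write_dosage_tsv(c.genotypes, d / "genotypes.tsv")
        pio.write_vcf(c.genotypes, d / "genotypes.vcf")
        c.ibd.to_csv(d / "ibd.tsv", sep="\t", index=False)
        paths["cohorts"][c.name] = {
            "events": str(d / "events.csv"),
            "demographics": str(d / "demographics.csv"),
            "bmi": str(d / "bmi.csv"),
            "covariates": str(d / "covariates.csv"),
            "genotypes": str(d / "genotypes.tsv"),
            "ibd": str(d / "ibd.tsv"),
        }
    return paths
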