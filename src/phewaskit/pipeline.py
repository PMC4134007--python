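"""End-to-end orchestration: QC -> phenotypes -> scans -> meta -> thresholds.

Cohorts are analyzed separately (relatedness pruning, genotype QC, BMI
cleaning, phenotype-matrix construction, logistic scans with and without BMI
adjustment) and then pooled with fixed-effects inverse-variance
meta-analysis; thresholds (Bonferroni, BH, simpleM) are computed on the
index SNP's meta scan and the annotated tables plus Manhattan-style plot
data are written as TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .cohort_qc import average_bmi_table, ld_group, ld_r2, prune_related, qc_filter
from .meta_analysis import meta_phewas
from .multiple_testing import (annotate_significance, make_thresholds,
                               phenotype_correlation, snp_correlation)
from .phenome_map import PhecodeMap, build_phenotype_matrix
from .phewas_scan import build_covariates, run_phewas, snp_bmi_assoc

log = logging.getLogger(__name__)

__all__ = ["CohortPaths", "RunConfig", "run_pipeline", "export_plot_data",
           "analyze_cohort"]


@dataclass
class CohortPaths:
    events: str
    demographics: str
    bmi: str
    covariates: str
    genotypes: str
    ibd: str


@dataclass
class RunConfig:
    cohorts: dict[str, CohortPaths]
    phecode_map: str
    index_snp: str
    outdir: str
    min_cases: int = 20
    min_call_rate: float = 0.99
    min_maf: float = 0.01
    min_info: float = 0.7
    ibd_threshold: float = 0.25
    alpha: float = 0.05
    fdr_q: float = 0.05
    simplem_c: float = 0.995
    adjust_bmi: str = "both"  # both | yes | no
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.adjust_bmi not in ("both", "yes", "no"):
            raise ValueError("adjust_bmi must be both/yes/no")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = {name: CohortPaths(**paths) for name, paths in raw.pop("cohorts").items()}
        return cls(cohorts=cohorts, **raw)


def _adjust_flags(mode: str) -> list[bool]:
    return {"both": [False, True], "yes": [True], "no": [False]}[mode]


@dataclass
class CohortAnalysis:
    name: str
    genotypes: object
    matrix: object
    covariates: pd.DataFrame
    avg_bmi: pd.Series
    scans: dict  # adjust flag -> DataFrame
    qc_log: pd.DataFrame
    pruned: list


def analyze_cohort(name: str, paths: CohortPaths, pmap: PhecodeMap,
                   cfg: RunConfig, rng) -> CohortAnalysis:
    """Run one cohort through pruning, QC, phenotyping and the scans."""
    genotypes = pio.read_genotypes(paths.genotypes)
    demographics = pio.read_demographics(paths.demographics)
    ibd = pio.read_ibd(paths.ibd)
    retained = prune_related(demographics["person_id"], ibd,
                             threshold=cfg.ibd_threshold, rng=rng)
    pruned = sorted(set(demographics["person_id"].astype(str)) - retained)
    log.info("[%s] pruned %d related individuals", name, len(pruned))
    demographics = demographics[demographics["person_id"].isin(retained)].reset_index(drop=True)
    genotypes = genotypes.subset_individuals(retained)
    genotypes, qc_log = qc_filter(genotypes, cfg.min_call_rate, cfg.min_maf, cfg.min_info)
    log.info("[%s] QC: %d SNPs retained, %d dropped", name,
             len(genotypes.snp_ids), len(qc_log))

    bmi = pio.read_bmi(paths.bmi)
    avg_bmi = average_bmi_table(bmi).reindex(demographics["person_id"].astype(str))
    pcs = pio.read_covariates(paths.covariates)
    covariates = build_covariates(demographics, pcs, avg_bmi)

    events = pio.read_events(paths.events)
    events = events[events["person_id"].isin(retained)]
    matrix = build_phenotype_matrix(events, demographics, pmap, cfg.min_cases)

    scans = {}
    for adjust in _adjust_flags(cfg.adjust_bmi):
        scans[adjust] = run_phewas(genotypes, matrix, covariates,
                                   adjust_bmi=adjust, pmap=pmap)
    return CohortAnalysis(name, genotypes, matrix, covariates, avg_bmi,
                          scans, qc_log, pruned)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the whole study; writes all tables under ``cfg.outdir`` and
    returns them in memory keyed by name."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phewaskit")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()


def _run(cfg: RunConfig, outdir: Path) -> dict:
    pmap = PhecodeMap.from_csv(cfg.phecode_map)
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(len(cfg.cohorts))
    analyses = []
    outputs: dict = {}
    for stream, (name, paths) in zip(streams, sorted(cfg.cohorts.items())):
        a = analyze_cohort(name, paths, pmap, cfg, np.random.default_rng(stream))
        analyses.append(a)
        for adjust, table in a.scans.items():
            tag = "adj" if adjust else "unadj"
            path = outdir / f"scan_{name}_{tag}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs[f"scan_{name}_{tag}"] = table
        a.qc_log.to_csv(outdir / f"qc_log_{name}.tsv", sep="\t", index=False)
        # SNP-BMI linear models and LD to the index SNP
        bmi_rows, ld_rows = [], []
        index_dosage = (a.genotypes.dosage(cfg.index_snp)
                        if cfg.index_snp in a.genotypes.snp_ids else None)
        for snp in a.genotypes.snp_ids:
            r = snp_bmi_assoc(a.genotypes.dosage(snp), a.avg_bmi,
                              a.covariates, snp_id=snp)
            bmi_rows.append(vars(r))
            if index_dosage is not None:
                r2 = ld_r2(index_dosage, a.genotypes.dosage(snp))
                ld_rows.append({"snp_id": snp, "r2": r2,
                                "ld_group": ld_group(r2).value})
        bmi_table = pd.DataFrame(bmi_rows)
        bmi_table.to_csv(outdir / f"bmi_assoc_{name}.tsv", sep="\t",
                         index=False, float_format="%.6g")
        outputs[f"bmi_assoc_{name}"] = bmi_table
        if ld_rows:
            ld_table = pd.DataFrame(ld_rows)
            ld_table.to_csv(outdir / f"ld_groups_{name}.tsv", sep="\t",
                            index=False, float_format="%.6g")
            outputs[f"ld_groups_{name}"] = ld_table

    # meta-analysis per adjustment
    thresholds = None
    plot_frames = []
    for adjust in _adjust_flags(cfg.adjust_bmi):
        tables = {a.name: a.scans[adjust] for a in analyses}
        if len(tables) >= 2:
            meta = meta_phewas(tables)
        else:
            meta = next(iter(tables.values())).rename(columns={"or_": "or"}).copy()
            meta["k"] = 1
        tag = "adj" if adjust else "unadj"
        if thresholds is None and len(meta):
            index_scan = meta[meta["snp_id"] == cfg.index_snp]
            family = index_scan if len(index_scan) else meta
            pooled_ind = pd.concat([a.matrix.case_indicator() for a in analyses])
            shared = [p for p in pooled_ind.columns
                      if all(p in a.matrix.phecodes for a in analyses)]
            phe_corr = phenotype_correlation_from_indicator(pooled_ind[shared])
            snp_corr = snp_correlation(max((a.genotypes for a in analyses),
                                           key=lambda g: len(g.snp_ids)))
            thresholds = make_thresholds(
                family["p"].dropna(), alpha=cfg.alpha, fdr_q=cfg.fdr_q,
                simplem_c=cfg.simplem_c, phenotype_corr=phe_corr,
                snp_corr=snp_corr)
            with open(outdir / "thresholds.json", "w") as fh:
                json.dump(thresholds.to_dict(), fh, indent=1)
            outputs["thresholds"] = thresholds
        if thresholds is not None:
            meta = annotate_significance(meta, thresholds)
        meta.to_csv(outdir / f"meta_{tag}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        outputs[f"meta_{tag}"] = meta
        sel = meta[meta["snp_id"] == cfg.index_snp] if len(meta) else meta
        plot_frames.append(sel)

    if any(len(f) for f in plot_frames):
        combined = pd.concat(plot_frames, ignore_index=True)
        plot = export_plot_data(combined, thresholds)
        plot.to_csv(outdir / "plot_data.tsv", sep="\t", index=False,
                    float_format="%.6g")
        outputs["plot_data"] = plot
    return outputs


def phenotype_correlation_from_indicator(ind: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in ind.columns if ind[c].dropna().nunique() > 1]
    corr = ind[keep].corr(min_periods=2).fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def export_plot_data(results: pd.DataFrame, thresholds=None) -> pd.DataFrame:
    """Manhattan-style plot table: rows sorted by category then phecode with
    a shared x-position per phenotype, -log10(p), effect direction and the
    adjustment flag; threshold lines ride along as frame attrs."""
    df = results.copy()
    if "category" not in df.columns:
        df["category"] = ""
    df["phecode_value"] = df["phecode"].astype(float)
    df = df.sort_values(["category", "phecode_value", "bmi_adjusted"],
                        kind="mergesort")
    order = (df[["category", "phecode_value", "phecode"]]
             .drop_duplicates(["category", "phecode"]))
    xpos = {p: i for i, p in enumerate(order["phecode"])}
    df["x"] = df["phecode"].map(xpos)
    df["neg_log10_p"] = -np.log10(df["p"])
    df["direction"] = np.sign(df["beta"]).fillna(0).astype(int)
    df["marker"] = np.where(df["bmi_adjusted"].astype(bool), "dot", "triangle")
    cols = ["x", "snp_id", "phecode", "description", "category", "p",
            "neg_log10_p", "or", "direction", "bmi_adjusted", "marker"]
    out = df[[c for c in cols if c in df.columns]].reset_index(drop=True)
    if thresholds is not None:
        out.attrs["thresholds"] = thresholds.to_dict()
    return out
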