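"""File dialects: events CSV, demographics, BMI, covariates, IBD pairs,
dosage TSV and VCF genotypes, status-matrix TSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_qc import GenotypeSet
from .phenome_map import PhenotypeMatrix


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "icd9": str})
    return df[["person_id", "date", "icd9"]]


def read_demographics(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"person_id": str, "sex": str, "site": str})


def read_bmi(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"person_id": str})


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"person_id": str})


def read_ibd(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})


# -- genotypes ---------------------------------------------------------------

def read_dosage_tsv(path) -> GenotypeSet:
    """TSV: ``snp_id, effect_allele, other_allele[, info], <person columns>``."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    df = df.set_index("snp_id")
    meta_cols = [c for c in ("effect_allele", "other_allele", "info") if c in df.columns]
    meta = df[meta_cols].copy()
    if "info" in meta.columns:
        meta["info"] = meta["info"].astype(float)
    dosages = df.drop(columns=meta_cols).astype(float)
    return GenotypeSet(dosages, meta)


def write_dosage_tsv(gset: GenotypeSet, path) -> None:
    out = gset.meta[["effect_allele", "other_allele", "info"]].join(gset.dosages)
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gset: GenotypeSet, path) -> None:
    """Plain-text VCF v4.2; integer dosages become GT calls, fractional
    dosages are written as DS."""
    dosages = gset.dosages
    integral = np.all(np.isin(dosages.fillna(0).to_numpy(), (0.0, 1.0, 2.0)))
    fmt = "GT" if integral else "DS"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=16>\n")
        if fmt == "GT":
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT">\n')
        if gset.meta["info"].notna().any():
            fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gset.individuals) + "\n")
        for pos, snp in enumerate(gset.snp_ids, start=1):
            meta = gset.meta.loc[snp]
            info = "." if pd.isna(meta["info"]) else f"INFO={meta['info']:.4g}"
            row = dosages.loc[snp]
            if fmt == "GT":
                calls = ["./." if pd.isna(v) else _GT[float(v)] for v in row]
            else:
                calls = ["." if pd.isna(v) else f"{float(v):.4g}" for v in row]
            fh.write("\t".join([
                "16", str(1000 + pos), snp, str(meta["other_allele"]),
                str(meta["effect_allele"]), ".", "PASS", info, fmt, *calls,
            ]) + "\n")


def read_vcf(path) -> GenotypeSet:
    """Read GT or DS genotypes; the ALT allele is the effect allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, meta = {}, {}
    for variant in vcf:
        snp = variant.ID or f"{variant.CHROM}:{variant.POS}"
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where(dos < 0, np.nan, dos)
        else:
            gt = np.asarray(variant.gt_types, dtype=float)
            dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        rows[snp] = dos
        info = variant.INFO.get("INFO")
        meta[snp] = {
            "effect_allele": variant.ALT[0] if variant.ALT else ".",
            "other_allele": variant.REF,
            "info": float(info) if info is not None else np.nan,
        }
    dosages = pd.DataFrame(rows, index=individuals).T
    return GenotypeSet(dosages, pd.DataFrame(meta).T)


def read_genotypes(path) -> GenotypeSet:
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_dosage_tsv(path)


# -- phenotype matrix --------------------------------------------------------

def write_matrix(matrix: PhenotypeMatrix, path) -> None:
    matrix.status.to_csv(path, sep="\t", index_label="person_id")


def read_matrix(path) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="person_id")
    df.index = df.index.astype(str)
    return PhenotypeMatrix(df.astype("int8"))
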