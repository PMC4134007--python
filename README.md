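# phewaskit

Phenome-wide association scans (PheWAS) from EHR billing data, with
BMI-mediation contrasts, two-cohort inverse-variance meta-analysis,
correlated multiple-testing correction, and a synthetic cohort generator
with planted pleiotropic effects.

## What it does, and for whom

A PheWAS turns the GWAS question around: instead of scanning many variants
against one phenotype, one variant is scanned against every phenotype that
can be constructed from clinical billing codes.  `phewaskit` is for
biostatisticians and informaticians running such scans on ICD-9-coded EHR
cohorts linked to genotypes — in particular for the *pleiotropy versus
mediation* design around an adiposity locus: compare each phenotype's odds
ratio before and after adjusting for body-mass index.  Associations carried
by the variant's effect on BMI attenuate toward OR 1; direct pleiotropic
associations do not.

The pipeline:

1. **Phenotypes** — ICD-9 events → phecode case/control/excluded status.
   Case = codes of the phenotype's group on ≥ 2 distinct days; single
   mentions and codes in the phenotype's exclusion range remove a person
   from the controls; phenotypes with < 20 cases are dropped.
2. **QC** — SNP call rate > 99%, MAF > 0.01, imputation info ≥ 0.7,
   max-posterior hard calls; one member kept per related group
   (IBD pi-hat > 0.25); BMI cleaned to [15, 70] kg/m² and averaged;
   LD to the index SNP grouped high / moderate / low (0.80, 0.60).
3. **Scan** — per cohort, logistic regression of every phenotype on allele
   dosage (additive model) adjusted for age, sex, site and three principal
   components, with and without average BMI; linear SNP–BMI models.
4. **Meta-analysis** — fixed-effects inverse-variance pooling over the
   cells testable in every cohort, after allele harmonization:
   β = Σwβ/Σw, se = (Σw)^(−1/2), w = se⁻², p = 2Φ(−|z|).
5. **Thresholds** — Bonferroni α/m, Benjamini–Hochberg step-up at q, and
   simpleM (effective number of tests from the eigenvalues of the test
   correlation matrix at C = 0.995).
6. **Outputs** — TSV result tables, a threshold report, a run log
   accounting for every dropped record, and Manhattan-style plot data.

Because real clinical cohorts are protected, the package ships a generator
(`phewaskit.synthetic_data`) that emulates the study's statistical
structure — two cohorts totalling ~24,000 individuals, an index SNP at
MAF 0.41 shifting BMI by 0.535 kg/m² per allele, satellites at configurable
r², and phenotypes planted as BMI-mediated, partially mediated, direct, or
null — together with a machine-readable truth table.  See
`docs/methods.md` for the models and all defaults.

## Worked example

```python
from phewaskit import (SimConfig, generate_study, write_study,
                       RunConfig, CohortPaths, run_pipeline)

paths = write_study(generate_study(SimConfig(seed=2014)), "scratch/study")
out = run_pipeline(RunConfig(
    cohorts={n: CohortPaths(**p) for n, p in paths["cohorts"].items()},
    phecode_map=paths["phecode_map"], index_snp="rs_index",
    outdir="results/pipeline", seed=99))
meta = out["meta_unadj"].query("snp_id == 'rs_index'")
print(meta.nsmallest(4, "p")[["description", "n_cases", "or", "p"]])
```

which prints (index SNP, unadjusted meta-analysis over both cohorts):

```
                   description  n_cases     or         p
                Morbid obesity     4870  1.187 1.094e-09
                       Obesity     7744  1.155 1.137e-08
    Fibrocystic breast disease     1074 0.7746 5.077e-08
     Staphylococcus infections     1466  1.214 4.314e-07
```

Reading the numbers: the weight phenotypes associate with the variant
because each copy of the effect allele raises BMI — rerun the scan with
`meta_adj` and their ORs collapse toward 1 (obesity 1.16 → 1.05, morbid
obesity 1.19 → 1.02).  The protective fibrocystic-breast-disease effect
(OR 0.77) and the staphylococcal-infection effect (OR 1.21) are planted as
direct and survive adjustment essentially unchanged — the signature of
pleiotropy not mediated by adiposity.  The same contrast for every
phenotype, against the generator's truth table, is in
`analysis/03_mediation_contrast.py`'s output
(`results/mediation_contrast.tsv`).

The numbered scripts under `analysis/` run the whole study narrative:
`01_simulate.py` (full-scale synthetic study), `02_run_pipeline.py`
(QC → scans → meta → thresholds), `03_mediation_contrast.py` (attenuation
versus truth; gram-positive composite phenotype), `04_plot_data.py`
(Manhattan-style plot export).  A `phewaskit` CLI exposes the same stages
as subcommands (`simulate`, `qc`, `phenotypes`, `scan`, `meta`,
`thresholds`, `plot-data`, `run-all`).

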