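# Methods

## The analysis

`phewaskit` implements an EHR-based phenome-wide association study (PheWAS)
of a single genetic locus: one index SNP (plus satellites in varying linkage
disequilibrium with it) is tested against every phenotype that can be
constructed from ICD-9 billing data, separately in two cohorts, with and
without adjustment for body-mass index, and the per-cohort effects are
pooled by fixed-effects inverse-variance meta-analysis.  The scientific
question the design answers is *pleiotropy versus mediation*: an association
that attenuates toward OR 1 once BMI enters the model is consistent with
transmission through the locus's effect on adiposity, while an association
that survives adjustment points to a direct (pleiotropic) pathway.

## Phenotype construction

Phenotypes are phecodes — curated groupings of ICD-9 codes with a decimal
code, a category, an optional sex restriction, and an *exclusion range* of
related phecodes.  For each person and phenotype:

* **CASE** — codes mapping to the phecode on at least two distinct calendar
  days.  The two mentions may be different ICD-9 codes; the distinct-day
  rule applies at the phecode level.
* **EXCLUDED** — not a case, and either (a) any code maps into the
  phenotype's closed exclusion interval (a single mention of the phenotype
  itself always does, because every phecode lies inside its own interval),
  or (b) the phenotype's sex restriction conflicts with the recorded sex.
  Persons with exactly one mention are therefore removed from the control
  pool rather than counted as controls — the conservative choice, since a
  single billing mention is weak evidence of either presence or absence of
  disease.
* **CONTROL** — everyone else.

Phenotypes with fewer than `min_cases` cases (default 20) are dropped and
logged.  Composite phenotypes (used for the gram-positive infection
analysis) are CASE if any member is a case, CONTROL if every member is a
control, and EXCLUDED otherwise.  Sex restriction is map-driven and defaults
to none; whether controls of a sex-specific phenotype should be restricted
to that sex is a genuine modelling choice that the map exposes rather than
hard-codes.

## Quality control

SNPs are retained when call rate exceeds 0.99 (strict), minor allele
frequency exceeds 0.01 (strict), and — for imputed SNPs carrying an info
score — info ≥ 0.7; posterior-probability triples are hard-called at the
maximum posterior with ties broken toward the lower dosage (ties have
measure zero in real data; the tie-break only pins down determinism).
Relatedness is resolved on the graph of pairs with IBD pi-hat > 0.25: one
member of each connected component is retained, chosen uniformly with a
seeded generator.  Component-wise retention generalizes pairwise retention
consistently when relatives chain (A–B, B–C).  BMI measurements outside
[15, 70] kg/m² (inclusive) are discarded and the remainder averaged per
person; a person with no in-range measurement has missing BMI and drops out
of BMI-adjusted fits only.  LD to the index SNP is the squared Pearson
correlation of unphased dosages (composite LD), grouped as high
(r² > 0.80), moderate (0.60 < r² ≤ 0.80) and low (r² ≤ 0.60).

## Association models

Each scan cell is a maximum-likelihood logistic regression (Newton/IRLS via
statsmodels, tolerance 1e-8, ≤ 25 iterations) of case status on allele
dosage (additive coding) with covariates age, sex, reference-coded site
indicators, the first three principal components, and optionally the
cleaned average BMI entering linearly.  Within a single-site cohort the
constant site column is dropped automatically.  Analysis is complete-case;
excluded persons never enter a fit.  Effects are reported as odds ratios
with Wald 95% intervals using the exact normal quantile z₀.₉₇₅ = 1.959964,
and two-sided Wald p-values — matching the OR + CI presentation convention;
likelihood-ratio tests are not used.  Non-convergence, or any log-odds
standard error above 10 (a quasi-separation signature), flags the cell
`converged=false`; flagged cells are reported but never pooled.  The
SNP–BMI relationship itself is ordinary least squares of average BMI on
dosage plus the same covariates.

## Meta-analysis

Per-cohort log odds ratios are harmonized to the first cohort's effect
allele (swapped labels flip the sign; non-matching allele sets are an
error — strand ambiguity is not resolved) and pooled with inverse-variance
weights: β = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^(−1/2), wᵢ = seᵢ⁻².  Only cells testable
in every cohort (shared SNP, shared phenotype, converged) are pooled;
pooling over the surviving subset would silently change the estimand
between rows.  Cochran's Q and I² are computed and logged but never gate
results.  Published per-cohort summaries can be fed in directly by
reconstructing the log-OR standard error from a 95% CI as
(ln hi − ln lo)/(2·z₀.₉₇₅).

## Multiple testing

Three thresholds are reported for a scan family: Bonferroni α/m; the
Benjamini–Hochberg step-up p-value threshold at FDR q (the largest sorted
p₍ₖ₎ ≤ k·q/m, zero when nothing passes; a p equal to a threshold counts as
passing); and simpleM — the effective number of independent tests, the
smallest x whose top-x eigenvalues of the test correlation matrix explain
≥ C of total variance, with C = 0.995 (the estimator's conventional value)
and numerically negative eigenvalues clipped at zero.  For a SNP × phenotype
scan the combined Meff defaults to the product of the SNP-side Meff (dosage
correlations) and the phenotype-side Meff (case-indicator correlations with
EXCLUDED treated as missing, pairwise complete); the factorization is the
natural product rule for a Kronecker-structured test family, and either
factor can be used alone.

## The synthetic study

The generator emulates the statistical structure of the two-cohort design
so the pipeline is fully testable without protected data.  Defaults (the
study conditions):

| quantity | default | note |
|---|---|---|
| cohort sizes | 10,487 / 13,711 | combined n = 24,198 |
| index SNP MAF | 0.41 | effect allele A |
| satellite r² | 1.00, 0.92, 0.72, 0.62, 0.06 | haplotype copying |
| BMI | Normal(29.5, 7.0²) kg/m² | latent, per person |
| BMI per-allele effect | 0.535 kg/m² | linear in dosage |
| BMI measurements | 2–5 per person, sd 1.5 | outliers at 1% |
| ages | Uniform(40, 80) | null covariate |
| sex | 53% female | |
| PCs | Normal(0, 0.01) (sd 0.1) | null covariates |
| related pairs | 0.5% of n, pi-hat ~ U(0.4, 0.6) | |
| single-mention rate | 5% of non-cases | exercises exclusion |
| missing dosages | 0.2% | |

Satellites are built per haplotype by copying the index allele with
probability √r², else drawing fresh at the satellite's own MAF; with equal
MAFs the realized dosage r² equals the target in expectation, and unequal
MAFs lower the attainable ceiling (warned at generation).  Phenotype status
is drawn from logistic models

    logit P(case) = logit(baseline) + direct_log_or·dosage
                    + bmi_log_or·(BMI_true − 29.5)

so a purely mediated phenotype (direct = 0, bmi > 0) shows a marginal SNP
association that attenuates toward OR 1 once average BMI enters the design,
while a direct phenotype is stable.  The planted architecture: obesity,
morbid obesity, overweight and sleep apnea are purely mediated — the weight
phenotypes with steep BMI slopes (0.45–0.8 per kg/m²) because those
diagnoses are near-threshold functions of BMI itself; type 2 diabetes and
non-alcoholic liver disease are partially mediated (direct OR 1.09 / 1.19
plus a BMI channel); fibrocystic breast disease carries a direct protective
female-only effect (OR 0.82); staphylococcal infection carries the
canonical direct risk effect OR 1.25, with streptococcal infection,
pneumococcal pneumonia and gram-positive septicemia at OR 1.15 feeding the
composite; hypertension, hyperlipidemia, GERD, limb pain, malaise and
osteoarthrosis are named nulls at common-diagnosis prevalences, plus 20
synthetic null phecodes.  True cases emit 2–5 codes of the phenotype's
ICD-9 group on distinct days; non-cases emit one single-day mention at the
configured rate; 20% of persons also receive an unmapped V-code event.
The second cohort carries a subset of the SNPs (exercising the meta
intersection) and labels the index SNP by the opposite allele (exercising
harmonization).  A truth table (planted parameters, realized MAFs, realized
r², realized case counts) is written beside every dataset.

What the generator does **not** emulate: ICD-9 co-occurrence structure and
longitudinal disease progression, genuine population structure behind the
PCs (they are pure noise), genotype correlation within planted related
pairs, and confounding between site and phenotype (off by default).
Passing tests therefore demonstrate the statistical machinery — case
construction, estimation, pooling, calibration — not robustness to EHR
coding pathologies or cryptic structure.

## Numerical and testing choices

All randomness descends from a single seed through named substreams, so
identical configurations reproduce byte-identical outputs.  Recovery tests
compare estimates with planted values within two standard errors; each such
interval is a 95% Monte-Carlo interval, so the planted-effect recovery
check pools estimates over six replicate studies of 20,000 individuals
(inverse-variance across replicates) rather than relying on a single draw.
Calibration is checked on 500 planted-null phenotypes at n = 5,000: the
nominal-0.05 rejection rate and a Kolmogorov–Smirnov uniformity test of the
null p-values.  The logistic fit is oracle-checked against the closed-form
2×2 cross-product ratio, and simpleM against an independent
eigendecomposition route.  Problem sizes in the test suite (hundreds to a
few thousand individuals for unit tests; 5,000–20,000 for the calibration
and recovery studies) were chosen as the smallest sizes at which the
statistical properties under test are well resolved.

## Known limitations

Firth or penalized regression is not offered, so very rare phenotypes in
small cohorts surface as flagged (quasi-separated) cells rather than
stabilized estimates.  BMI enters the adjusted model linearly; the residual
direct effect picked up when the mediator is measured with error
(average-of-2–5 noisy measurements, reliability ≈ 0.99) is of order 1% of
the mediated channel and is ignored.  Fixed-effects pooling assumes a
common effect; heterogeneity is reported, not modelled.  ICD-10, phecode
hierarchy roll-up beyond exclusion intervals, imputation, and population-
structure inference are out of scope; principal components are consumed as
inputs.
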