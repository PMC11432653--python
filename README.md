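# ldlprs

Construction and association analysis of an 8-SNP LDL-cholesterol
polygenic score in a premature coronary heart disease (PCHD) case-control
setting, with a calibrated synthetic-cohort generator so the whole
pipeline is testable without access to patient data.

The package is aimed at lipidology / cardiovascular-genetics researchers
who want to reproduce or adapt a small PCR-friendly LDL-C polygenic score
analysis: genotype QC (Hardy-Weinberg, linkage disequilibrium), score
construction, estimated pre-treatment LDL-C (eLDLC) and Dutch Lipid
Clinic Network (DLCN) phenotype derivation, and the complete statistical
battery linking the score to lipid traits, clinical familial
hypercholesterolemia (FH) probability, and PCHD risk.

## The score

Six biallelic SNPs plus the APOE ε genotype (from rs429358 and rs7412):

| rsID | gene | counted allele | weight (mmol/L) |
|------|------|----------------|-----------------|
| rs6511720 | LDLR | common (G) | 0.180 |
| rs629301 | CELSR2 | common (T) | 0.146 |
| rs1367117 | APOB | minor (A) | 0.105 |
| rs4299376 | ABCG8 | minor (G) | 0.071 |
| rs1800562 | HFE | common (G) | 0.057 |
| rs2479409 | PCSK9 | minor (G) | 0.052 |

For the three SNPs whose minor allele is LDL-C-lowering the effect is
nullified and the weight is carried by the common allele instead, so
every counted allele is LDL-C-raising. The APOE genotype adds a
genotype-level term (ε2ε2 −0.800 … ε4ε4 +0.260 mmol/L). Writing `g_i`
for the counted-allele count at SNP *i* and `w_i` for its weight:

    aPRS = Σ_i c_i·g_i + a(APOE)        (integer allele count, range −2…14)
    wPRS = Σ_i w_i·g_i + w(APOE)        (mmol/L, range −0.800…1.482)

and the analyses use the cohort-standardized `wPRS Z = (wPRS − mean)/SD`.
APOB rs676210 is assayed but excluded from scoring by default because of
its strong LD with rs1367117 (D′ ≈ 0.99). Weights live in a versioned
YAML config (`src/ldlprs/config/score_definition.yaml`), so other
published 6/12-SNP score variants can be expressed without code changes.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
simulated cohort (n = 2000 keeps the study's 125:97 case:control ratio):

```sh
python analysis/01_simulate_cohort.py   # writes results/cohort/
python analysis/02_genotype_qc.py
python analysis/03_score_cohort.py
python analysis/04_trait_associations.py
```

which prints, among others:

```
rs1367117-rs676210: D' = 0.992 (r2 = 0.807)
LD screen at D' >= 0.9: excluded ['rs676210']
HC   n=  874  median aPRS 7.0 (IQR 6.0-8.0)  median wPRS 0.796 (IQR 0.620-0.919)
nFH  n= 1099  median aPRS 8.0 (IQR 7.0-9.0)  median wPRS 0.837 (IQR 0.720-0.942)
dFH  n=   27  median aPRS 8.0 (IQR 7.0-9.0)  median wPRS 0.889 (IQR 0.788-0.946)
per-SD associations with wPRS Z (estimate [95% CI], configured):
  eLDLC_per_sd            0.232 [0.189, 0.275]  p=0.0000  (configured 0.2)
  HDLC_per_sd            -0.117 [-0.161, -0.074]  p=0.0000  (configured -0.14)
  eLDLC_gt_190_per_sd     1.399 [1.252, 1.563]  p=0.0000  (configured 1.36)
  dlcn_ge_3_per_sd        1.686 [1.529, 1.858]  p=0.0000  (configured 1.58)
```

The QC stage finds the planted APOB LD pair and drops rs676210 from
scoring; the per-SD estimates recover the generator's configured effects
within sampling error: a +1 SD increase in wPRS raises eLDLC by ~0.2 SD,
lowers HDLC, and raises the odds of eLDLC > 190 mg/dL and of a DLCN
score ≥ 3. `05_pchd_models.py` fits the univariate/multivariate PCHD
models and the percentile-extreme contrasts; `06_fh_screening.py` runs
the DLCN-category trend and ROC screening analyses.

The same pipeline runs from the command line on any conforming input:

```sh
ldlprs simulate --n 2000 --seed 7 --out cohort/
ldlprs score cohort/genotypes.csv --out scores.csv
ldlprs analyze --genotypes cohort/genotypes.csv \
               --phenotypes cohort/phenotypes.csv --seed 7 --out report/
```

Input dialects: genotype CSV (rows = individuals, columns = rsIDs,
values 0/1/2 counting the score's minor allele, blank = missing) or VCF
(REF/ALT orientation is reconciled against the score definition);
phenotype CSV with measured lipids in mg/dL, statin type/dose, and DLCN
item flags.

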