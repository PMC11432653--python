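# Methods

## Score model

The weighted polygenic score is a fixed-weight allele count: six
biallelic SNPs contribute `w_i` mmol/L of LDL-C per counted allele, and
the APOE ε genotype contributes a genotype-level term. Three SNPs
(LDLR rs6511720, CELSR2 rs629301, HFE rs1800562) have LDL-C-*lowering*
minor alleles; their effects are nullified and the weight is assigned to
the common allele, so the score is monotone in LDL-C-raising allele
load. The additive variant replaces weights by integer contributions.
Exhaustive enumeration of all 3⁶ × 6 genotype combinations shows the
scores span exactly [−2, 14] (additive) and [−0.800, 1.482] mmol/L
(weighted), and that changing one counted allele moves the weighted
score by exactly that SNP's weight.

APOE ε genotypes are called from unphased rs429358/rs7412 dosages via
the standard haplotype table (ε2 = T,T; ε3 = T,C; ε4 = C,C). The
double heterozygote is ambiguous between ε2ε4 and ε1ε3; it is called
ε2ε4, the standard convention given the rarity of ε1. Dosage pairs that
would require an ε1 (C,T) haplotype are rejected as input errors.

Scores are standardized to Z scores over the full combined cohort
(cases + controls), matching the single-Z-score analysis design, and
binned by the empirical percentile rank ("fraction strictly below plus
half the ties"; decile = ⌈rank/10⌉ clipped to 1–10). Quantile thresholds
use linear interpolation. Individuals missing any score SNP or the APOE
call are excluded from scoring and flagged; there is no imputation.

## Genotype QC

Hardy-Weinberg equilibrium uses the asymptotic 1-df chi-squared test
without continuity correction on the allele frequency estimated from the
genotype counts; monomorphic loci return a degenerate zero statistic.

Pairwise linkage disequilibrium on unphased genotypes estimates the four
two-locus haplotype frequencies by EM (only the double heterozygote is
phase-ambiguous), starting from linkage equilibrium, with a 1e-10
log-likelihood tolerance and a 1000-iteration cap. D′ uses the
sign-dependent allele-frequency bound; the association test is the 1-df
chi-squared 2N·r² on the 2N haplotypes. Whether the original analysis
used EM haplotypes or composite disequilibrium is not stated; EM is the
standard unphased estimator and is what the generator's planted
D′ = 0.99 pair is recovered with (±0.02 at n = 5000). The pipeline's LD
screen drops, from any pair exceeding the configured D′ cut (default
0.9), the SNP that is not part of the score definition (or the
lower-weight one if both are), recording the exclusion in the run
manifest.

## Phenotype derivation

Estimated pre-treatment LDL-C is `eLDLC = LDLC / (1 − r)`, where `r` is
the expected fractional reduction for the reported statin type and daily
dose. The published source for these factors is not reproduced in the
analysis we follow, so the package ships an editable default table
(atorvastatin/simvastatin/rosuvastatin/pravastatin/fluvastatin at common
doses, r = 0.20–0.55) compiled from standard dose-response summaries;
it is explicitly external knowledge, all eLDLC-dependent tests pin the
shipped table, and combination therapy falls back to the statin-only
factor unless a combination entry is configured. Unknown statin/dose
entries exclude the record with a logged warning rather than guessing.

The DLCN score (genetic items excluded) sums four sections: family
history (max of item points: 1 for a first-degree relative with
premature CHD or high LDL-C, 2 for a relative with xanthoma/arcus or an
affected child), clinical history (sum: 2 for personal premature CHD,
1 for premature cerebral/peripheral disease), physical examination
(max: 6 tendon xanthomata, 4 arcus before 45), and the LDL-C band
evaluated on eLDLC converted to mmol/L (factor 38.67): ≥8.5 → 8,
6.5–8.4 → 5, 5.0–6.4 → 3, 4.0–4.9 → 1. Whether clinical-history items
sum or take the maximum varies between published DLCN implementations;
summing is used here, which only matters for the rare patient with both
items. Categories: unlikely < 3, possible 3–5, probable 6–8,
definite > 8; cases split into nFH/dFH at DLCN > 8.

## Statistical battery

Choices the source analysis leaves unnamed are fixed as: Woolf CIs and
Wald p for 2×2 odds ratios (Haldane-Anscombe +0.5 on any zero cell,
flagged), Wald CIs for logistic coefficients (IRLS maximum likelihood
via statsmodels), DeLong CIs for AUC, Katz log CIs for tail risk ratios,
two-tailed p-values throughout, and no multiple-testing adjustment
(p in (0.05, 0.15] is flagged "marginal" instead). These conventions
reproduce the published univariate ORs and CIs from the printed group
counts to last-digit rounding.

The Jonckheere-Terpstra trend statistic is the sum of pairwise
Mann-Whitney counts in group order, tested with the tie-corrected normal
approximation, or a seeded permutation test (≥10⁴ draws) whenever any
group has fewer than 5 observations; with two groups it reduces exactly
to Mann-Whitney. Mann-Whitney itself is exact for min(n) ≤ 8 without
ties. Hosmer-Lemeshow uses decile-of-risk groups (merged when ties
collapse quantiles) with g − 2 degrees of freedom. Nested logistic
models are compared by the likelihood-ratio chi-squared as the canonical
statistic, with an extra-sum-of-squares-style F-form on the residual
deviances reported alongside (the original analysis names an
"extra sum-of-squares F test" whose exact mapping onto logistic deviance
is ambiguous); both models' AUCs are attached. ROC analysis evaluates
operating points at midpoints between adjacent unique score values
(positive = score strictly above threshold, matching "wPRS > t"
phrasing), selects them by Youden's J or by the largest threshold
achieving a requested sensitivity (1.0 for the no-false-negative
screening rule), and computes AUC both empirically and via the
Mann-Whitney U identity, which agree to machine precision.

## Synthetic cohort

No raw data are publicly available, so the generator emulates the
cohort's published statistical structure; its defaults are the study
conditions and are not tuned per run:

- **Genotypes**: independent loci under HWE at the healthy-control
  allele frequencies (rs6511720 0.118, rs629301 0.221, rs1367117 0.345,
  rs4299376 0.350, rs1800562 0.031, rs2479409 0.350); the
  rs1367117–rs676210 pair drawn from two-locus haplotype frequencies
  solving D′ = 0.99 (rs676210's own frequency is not published; 0.30 is
  a European reference-panel value); APOE genotypes drawn directly from
  the published genotype distribution (ε2ε3 0.103, ε2ε4 0.041,
  ε3ε3 0.660, ε3ε4 0.196).
- **Traits**: a single-index model — phenotypes depend on genotypes only
  through the wPRS Z score, since all published effects are expressed
  per wPRS SD and nothing identifies per-SNP pleiotropy. HDLC, BMI and
  the latent Lp(a) index follow trait_Z = β·wPRS_Z + √(1−β²)·ε with
  β = −0.14, +0.15, +0.05; Lp(a) maps through a lognormal with the
  9.7 mg/dL assay floor (which slightly attenuates its measured β).
  Trait means/SDs (eLDLC 150 ± 58, HDLC 43 ± 12, BMI 28.6 ± 4.2 —
  mg/dL, mg/dL, kg/m²) are back-converted from published medians/IQRs
  assuming near-normality and are declared approximations.
- **eLDLC** carries two configured marginal parameters at once: the
  linear per-SD effect (+0.20 SD) and the odds ratio per SD for
  exceeding 190 mg/dL (1.36). A single bivariate-Gaussian draw cannot
  satisfy both exactly, so the draw is two-stage: the exceedance
  indicator comes from the configured logistic law (intercept solved so
  the marginal exceedance rate matches the trait distribution), then the
  trait value is drawn from the correspondingly truncated normal whose
  latent slope is solved numerically (Brent's method on the analytic
  truncated-normal moments averaged over the cohort's empirical wPRS Z
  values) so the marginal standardized linear effect equals its
  configured value. Refitting both models on generated cohorts recovers
  both parameters within sampling error.
- **DLCN** is not drawn directly: item flags and eLDLC are generated and
  the score is computed through the phenotype engine, so the round trip
  exercises the same code paths as real data. The configured
  DLCN ≥ 3 odds ratio per wPRS SD (1.58) is realized by coupling the
  family-history probability to the score
  (logit slope 0.74, solved once against large-n cohorts and frozen) —
  a biologically sensible channel, since relatives share score alleles.
  One coupling constant cannot pin two moments: the *linear* DLCN effect
  then emerges at ≈ +0.21 SD per SD rather than the published +0.16,
  a known, documented approximation.
- **Case-control labels** come from a logistic model with the published
  complete-model odds ratios (family history 10.01, smoking 10.86,
  hypertension 2.42, alcohol 0.29, eLDLC 1.012/mg/dL, HDLC 0.949/mg/dL,
  Lp(a) 1.020/mg/dL); the intercept is solved for the target case
  fraction (study proportion 125:222) and a Bernoulli draw is adjusted
  by the minimal number of probability-weighted random flips to match
  the requested counts exactly. Group-specific allele frequencies are
  *not* sampled directly — they emerge through the case model,
  preventing double-counting of the genotype→disease path. After
  labelling, cases receive the personal premature-CHD DLCN item (an
  inclusion criterion), group-rate statin exposure (HC 8.2%, cases
  70.4%), and measured LDLC back-derived from eLDLC through the same
  correction table, making the masking exactly invertible.
- **Determinism**: one seed, expanded via `SeedSequence.spawn` into
  per-stage substreams; identical (spec, n, seed) is bit-identical.

What the generator does **not** emulate: monogenic FH mutations,
pedigree structure, per-SNP pleiotropy, assay noise and self-report
error in statin exposure, the skew of real lipid distributions (beyond
Lp(a)/TG), or the cohort's exact recruitment process. Passing recovery
tests therefore show that the pipeline estimates what the generator
encodes — they do not validate the published cohort-specific statistics
(median PRS values, exact regression coefficients, AUCs ≈ 0.855/0.895,
the 45th-percentile screening threshold), which require the original
data. The percentile-extreme contrast is checked as a directional
property (top-vs-bottom-decile risk ratio > 1 in ≥95% of replicates
under the default positive coupling), not as a value.

## Problem sizes and numerical notes

Recovery checks run at n = 10 000 (effects), n = 5000 (LD), 100
replicates of n = 2000 (tail risk ratio), and 800 replicates for the
5% ± 1.5% type-I-error checks of JT/Mann-Whitney/Wald — sizes chosen so
Monte-Carlo error is comfortably inside each tolerance. Percentile ties
are assigned left-closed deterministically and fully tied score vectors
fall into a single bin with a warning. Logistic separation or
non-convergence is reported via a flag rather than an exception;
rank-deficient designs and degenerate 2×2 tables are rejected. Report
tables round only at serialization (2 decimals for estimates, 4 for
p-values).
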