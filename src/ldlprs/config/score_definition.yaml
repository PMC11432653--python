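# Default 8-SNP LDL-cholesterol polygenic score definition.
#
# Six biallelic SNPs plus the two-SNP APOE epsilon genotype. Weights are
# per counted allele, in mmol/L of LDLC. For rs6511720, rs629301 and
# rs1800562 the minor allele is LDLC-lowering; their effects are nullified
# and the weight is instead assigned to the corresponding common allele,
# which is therefore the counted (risk) allele.
version: "table2-default"
snps:
  rs6511720:
    gene: LDLR
    minor_allele: T
    common_allele: G
    counted_allele: common
    aprs_per_allele: 1
    weight_per_allele: 0.180
  rs629301:
    gene: CELSR2
    minor_allele: G
    common_allele: T
    counted_allele: common
    aprs_per_allele: 1
    weight_per_allele: 0.146
  rs1367117:
    gene: APOB
    minor_allele: A
    common_allele: G
    counted_allele: minor
    aprs_per_allele: 1
    weight_per_allele: 0.105
  rs4299376:
    gene: ABCG8
    minor_allele: G
    common_allele: T
    counted_allele: minor
    aprs_per_allele: 1
    weight_per_allele: 0.071
  rs1800562:
    gene: HFE
    minor_allele: A
    common_allele: G
    counted_allele: common
    aprs_per_allele: 1
    weight_per_allele: 0.057
  rs2479409:
    gene: PCSK9
    minor_allele: G
    common_allele: A
    counted_allele: minor
    aprs_per_allele: 1
    weight_per_allele: 0.052
# APOE epsilon genotype -> (additive contribution, weight in mmol/L).
apoe:
  e2e2: {aprs: -2, weight: -0.800}
  e2e3: {aprs: -1, weight: -0.400}
  e2e4: {aprs: 0, weight: -0.270}
  e3e3: {aprs: 0, weight: 0.000}
  e3e4: {aprs: 1, weight: 0.130}
  e4e4: {aprs: 2, weight: 0.260}
# Assayed but excluded from scoring by default: rs676210 is in strong LD
# with rs1367117 (D' = 0.99) and would double-count the APOB signal.
excluded_snps:
  rs676210:
    gene: APOB
    minor_allele: A
    common_allele: G
    reason: "LD with rs1367117"
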