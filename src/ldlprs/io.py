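"""Readers and writers for the genotype and phenotype table dialects.

Genotype CSV: one row per individual (first column = identifier), one
column per rsID, values 0/1/2 counting the score definition's MINOR
allele, empty = missing. VCF input is reconciled against the score
definition: when REF/ALT orientation is flipped relative to the
minor/common assignment the dosage is flipped with a logged warning.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .score import ScoreDefinition

logger = logging.getLogger(__name__)


def read_genotype_csv(path) -> GenotypeTable:
    df = pd.read_csv(path, index_col=0)
    return GenotypeTable(df.astype(float))


def write_genotype_csv(table: GenotypeTable, path) -> None:
    out = table.dosage.copy()
    # integers where present, blanks for missing
    out.to_csv(path, float_format="%.0f")


def _locus_alleles(definition: ScoreDefinition, rsid: str) -> tuple[str, str] | None:
    if rsid in definition.snps:
        e = definition.snps[rsid]
        return e.minor_allele, e.common_allele
    if rsid in definition.excluded_snps:
        e = definition.excluded_snps[rsid]
        return e["minor_allele"], e["common_allele"]
    apoe_alleles = {"rs429358": ("C", "T"), "rs7412": ("T", "C")}
    return apoe_alleles.get(rsid)


def read_genotype_vcf(path, definition: ScoreDefinition | None = None) -> GenotypeTable:
    """Read the assayed loci from a VCF, orienting dosages to the score
    definition's minor allele regardless of the file's REF/ALT polarity."""
    from cyvcf2 import VCF

    definition = definition or ScoreDefinition.default()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        alleles = _locus_alleles(definition, rsid) if rsid else None
        if alleles is None:
            logger.warning("skipping unrecognized variant %r", rsid)
            continue
        minor, common = alleles
        alt = variant.ALT[0] if variant.ALT else None
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = variant.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
        dose[gt == 2] = np.nan
        if variant.REF == minor and alt == common:
            logger.warning("%s: REF/ALT flipped relative to score definition; "
                           "flipping dosage", rsid)
            dose = 2.0 - dose
        elif not (variant.REF == common and alt == minor):
            raise ValueError(
                f"{rsid}: VCF alleles {variant.REF}/{alt} do not match "
                f"score definition {common}/{minor}"
            )
        cols[rsid] = dose
    return GenotypeTable(pd.DataFrame(cols, index=pd.Index(samples, name="individual")))


def write_genotype_vcf(table: GenotypeTable, path,
                       definition: ScoreDefinition | None = None) -> None:
    """Minimal single-chromosome VCF export (common allele as REF)."""
    definition = definition or ScoreDefinition.default()
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "##contig=<ID=1>"]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT", *map(str, table.individuals)]
    lines.append("\t".join(header))
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for pos, rsid in enumerate(table.rsids, start=1):
        alleles = _locus_alleles(definition, rsid)
        if alleles is None:
            continue
        minor, common = alleles
        row = ["1", str(pos), rsid, common, minor, ".", "PASS", ".", "GT"]
        for v in table.dosage[rsid]:
            row.append("./." if pd.isna(v) else gt_map[float(v)])
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_phenotype_csv(path) -> pd.DataFrame:
    """Phenotype table; boolean item columns are coerced from 0/1/true/false."""
    df = pd.read_csv(path, index_col=0)
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna().unique()) <= {
                "True", "False", "true", "false"}:
            df[col] = df[col].str.lower() == "true"
    return df


def write_phenotype_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path)
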