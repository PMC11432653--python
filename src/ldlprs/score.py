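"""Additive and weighted 8-SNP LDL-cholesterol polygenic scores.

The score counts, for each of six biallelic SNPs, a *counted allele*: for
the LDLC-raising minor alleles (APOB rs1367117, ABCG8 rs4299376, PCSK9
rs2479409) the minor allele itself; for the LDLC-lowering minor alleles
(LDLR rs6511720, CELSR2 rs629301, HFE rs1800562) the effect is nullified
and the *common* allele carries the weight instead. The APOE epsilon
genotype contributes a seventh, genotype-level term. The additive score
(aPRS) sums integer contributions; the weighted score (wPRS) sums
per-allele effect sizes in mmol/L of LDLC.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .genotypes import APOE_GENOTYPES, GenotypeTable, call_apoe_series

logger = logging.getLogger(__name__)

APOE_SNPS = ("rs429358", "rs7412")


@dataclass(frozen=True)
class SnpScoreEntry:
    rsid: str
    gene: str
    minor_allele: str
    common_allele: str
    counted_allele: str  # "minor" | "common"
    aprs_per_allele: int
    weight_per_allele: float

    def counted_count(self, minor_dosage):
        """Count of the counted allele given the minor-allele dosage."""
        if self.counted_allele == "minor":
            return minor_dosage
        return 2 - minor_dosage


@dataclass(frozen=True)
class ScoreDefinition:
    """The full score contract: six SNP entries plus the APOE genotype map."""

    version: str
    snps: dict[str, SnpScoreEntry]
    apoe_aprs: dict[str, int]
    apoe_weight: dict[str, float]
    excluded_snps: dict[str, dict]

    def __post_init__(self) -> None:
        if len(self.snps) != 6:
            raise ValueError("score definition requires exactly 6 non-APOE SNPs")
        missing = set(APOE_GENOTYPES) - set(self.apoe_weight)
        if missing:
            raise ValueError(f"APOE map missing genotypes: {sorted(missing)}")

    @property
    def score_rsids(self) -> list[str]:
        return list(self.snps)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScoreDefinition":
        snps = {
            rsid: SnpScoreEntry(
                rsid=rsid,
                gene=e.get("gene", ""),
                minor_allele=e["minor_allele"],
                common_allele=e["common_allele"],
                counted_allele=e["counted_allele"],
                aprs_per_allele=int(e["aprs_per_allele"]),
                weight_per_allele=float(e["weight_per_allele"]),
            )
            for rsid, e in cfg["snps"].items()
        }
        apoe = cfg["apoe"]
        return cls(
            version=str(cfg.get("version", "unversioned")),
            snps=snps,
            apoe_aprs={g: int(v["aprs"]) for g, v in apoe.items()},
            apoe_weight={g: float(v["weight"]) for g, v in apoe.items()},
            excluded_snps=dict(cfg.get("excluded_snps", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScoreDefinition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScoreDefinition":
        ref = resources.files("ldlprs.config") / "score_definition.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    def wprs_bounds(self) -> tuple[float, float]:
        lo = sum(min(0.0, 2 * e.weight_per_allele) for e in self.snps.values())
        hi = sum(max(0.0, 2 * e.weight_per_allele) for e in self.snps.values())
        return (lo + min(self.apoe_weight.values()), hi + max(self.apoe_weight.values()))


def _counted_matrix(table: GenotypeTable, definition: ScoreDefinition) -> pd.DataFrame:
    cols = {}
    for rsid, entry in definition.snps.items():
        if rsid not in table.dosage.columns:
            raise KeyError(f"genotype table lacks score SNP {rsid}")
        cols[rsid] = entry.counted_count(table.dosage[rsid].astype(float))
    return pd.DataFrame(cols, index=table.individuals)


def compute_scores(table: GenotypeTable, definition: ScoreDefinition | None = None) -> pd.DataFrame:
    """Compute aPRS and wPRS for every individual in a genotype table.

    The table must carry the six score SNPs plus rs429358/rs7412 for the
    APOE term. Individuals missing any score SNP or the APOE call get NaN
    scores and ``complete = False``; they are excluded from downstream
    standardization and binning.
    """
    definition = definition or ScoreDefinition.default()
    counted = _counted_matrix(table, definition)
    for snp in APOE_SNPS:
        if snp not in table.dosage.columns:
            raise KeyError(f"genotype table lacks APOE SNP {snp}")
    apoe = call_apoe_series(table.dosage["rs429358"], table.dosage["rs7412"])

    aprs = pd.Series(0.0, index=table.individuals)
    wprs = pd.Series(0.0, index=table.individuals)
    for rsid, entry in definition.snps.items():
        aprs = aprs + entry.aprs_per_allele * counted[rsid]
        wprs = wprs + entry.weight_per_allele * counted[rsid]
    aprs = aprs + apoe.map(definition.apoe_aprs)
    wprs = wprs + apoe.map(definition.apoe_weight)

    complete = aprs.notna() & wprs.notna()
    n_excl = int((~complete).sum())
    if n_excl:
        logger.warning("%d individuals excluded from PRS (missing genotypes)", n_excl)
    return pd.DataFrame(
        {"aPRS": aprs, "wPRS": wprs, "apoe": apoe, "complete": complete}
    )


def compute_aprs(dosages: dict[str, float], apoe_genotype: str,
                 definition: ScoreDefinition | None = None) -> int:
    """Additive PRS for a single individual (integer allele count score)."""
    definition = definition or ScoreDefinition.default()
    total = 0
    for rsid, entry in definition.snps.items():
        d = dosages[rsid]
        if d is None or (isinstance(d, float) and math.isnan(d)):
            raise ValueError(f"missing dosage at {rsid}; individual excluded")
        total += entry.aprs_per_allele * entry.counted_count(int(d))
    return int(total + definition.apoe_aprs[apoe_genotype])


def compute_wprs(dosages: dict[str, float], apoe_genotype: str,
                 definition: ScoreDefinition | None = None) -> float:
    """Weighted PRS for a single individual, in mmol/L units."""
    definition = definition or ScoreDefinition.default()
    total = 0.0
    for rsid, entry in definition.snps.items():
        d = dosages[rsid]
        if d is None or (isinstance(d, float) and math.isnan(d)):
            raise ValueError(f"missing dosage at {rsid}; individual excluded")
        total += entry.weight_per_allele * entry.counted_count(int(d))
    return float(total + definition.apoe_weight[apoe_genotype])


def standardize_scores(scores) -> pd.Series:
    """Z-score a vector by its sample mean and SD (n-1 denominator)."""
    s = pd.Series(scores, dtype=float)
    vals = s.dropna()
    if len(vals) < 2:
        raise ValueError("need >= 2 scores to standardize")
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate score distribution (zero SD)")
    return (s - vals.mean()) / sd


def percentile_rank(scores) -> pd.Series:
    """Empirical percentile rank: fraction strictly below + half of ties."""
    s = pd.Series(scores, dtype=float)
    vals = s.dropna().to_numpy()
    n = len(vals)
    if n == 0:
        raise ValueError("empty score vector")
    order = np.sort(vals)
    below = np.searchsorted(order, s.to_numpy(), side="left")
    at_or_below = np.searchsorted(order, s.to_numpy(), side="right")
    rank = 100.0 * (below + 0.5 * (at_or_below - below)) / n
    out = pd.Series(rank, index=s.index)
    out[s.isna()] = np.nan
    return out


def assign_decile(scores) -> pd.Series:
    """Decile 1-10 from the empirical percentile rank (ceil(rank/10))."""
    rank = percentile_rank(scores)
    if rank.nunique(dropna=True) == 1:
        logger.warning("all scores tied; every individual falls in one bin")
    dec = np.ceil(rank / 10.0).clip(1, 10)
    return dec.astype("Int64", errors="ignore") if dec.isna().any() else dec.astype(int)


def percentile_threshold(scores, q: float) -> float:
    """Empirical quantile with linear interpolation (q in [0, 100])."""
    vals = pd.Series(scores, dtype=float).dropna().to_numpy()
    if len(vals) == 0:
        raise ValueError("empty score vector")
    return float(np.percentile(vals, q))


def scored_cohort(table: GenotypeTable, definition: ScoreDefinition | None = None) -> pd.DataFrame:
    """Per-individual aPRS, wPRS, wPRS Z score, percentile rank and decile.

    Standardization and binning are against the full (combined) cohort of
    individuals with complete scores.
    """
    scores = compute_scores(table, definition)
    ok = scores["complete"]
    out = scores.copy()
    out["wPRS_z"] = np.nan
    out.loc[ok, "wPRS_z"] = standardize_scores(scores.loc[ok, "wPRS"])
    out["percentile"] = np.nan
    out.loc[ok, "percentile"] = percentile_rank(scores.loc[ok, "wPRS"])
    out["decile"] = np.nan
    out.loc[ok, "decile"] = assign_decile(scores.loc[ok, "wPRS"])
    return out
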