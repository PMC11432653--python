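"""End-to-end orchestration: ingest -> QC -> score -> phenotype-derive ->
associate -> report.

Every number a report carries is produced by a direct call into the
library modules on the same data; the report layer only arranges and
serializes them.
"""
from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from . import __version__
from .genotypes import GenotypeTable, hwe_chisq, ld_pairwise
from .phenotype import (DlcnTable, StatinCorrectionTable, assign_groups,
                        dlcn_score_frame, estimate_pretreatment_ldlc)
from .score import APOE_SNPS, ScoreDefinition, scored_cohort
from .stats import (AssociationResult, extreme_percentile_comparison,
                    jonckheere_terpstra, linear_fit_standardized, logistic_fit,
                    mann_whitney, nested_model_compare, roc_analysis,
                    spearman_corr)

logger = logging.getLogger(__name__)

CONTINUOUS_TRAITS = ("eLDLC", "HDLC", "BMI", "Lpa", "dlcn_points")
UNIVARIATE_BINARY = ("family_history", "smoking", "hypertension", "alcohol")
REDUCED_MODEL = ("alcohol", "hypertension", "BMI", "family_history", "smoking")
COMPLETE_MODEL = ("alcohol", "hypertension", "family_history", "smoking",
                  "eLDLC", "HDLC", "Lpa")


@dataclass
class RunConfig:
    genotypes: str | None = None
    phenotypes: str | None = None
    synthetic: bool = False
    n: int | None = None
    seed: int | None = None
    score_definition: str | None = None
    ld_dprime_cut: float = 0.9
    top_percentile: float = 90.0
    bottom_percentiles: tuple = (10.0, 20.0)
    output_dir: str | None = None

    def validate(self) -> None:
        real = self.genotypes is not None and self.phenotypes is not None
        if real == self.synthetic:
            raise ValueError("exactly one of real input or synthetic spec required")
        if self.synthetic and self.seed is None:
            raise ValueError("seed required for synthetic runs")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    manifest: dict
    results: list[AssociationResult] = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            serial = df.copy()
            for col in serial.columns:
                if serial[col].dtype.kind == "f":
                    digits = 4 if "p_value" in col or col.startswith("p") else 2
                    serial[col] = serial[col].round(digits)
            serial.to_csv(out / f"{name}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _rows(results: list[tuple[str, AssociationResult]]) -> pd.DataFrame:
    return pd.DataFrame([{"label": label, **r.to_row()} for label, r in results])


def qc_genotypes(table: GenotypeTable, definition: ScoreDefinition,
                 groups: pd.Series, ld_cut: float) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-group HWE for every assayed non-APOE SNP and a pairwise LD
    screen; returns (hwe table, ld table, SNPs to exclude from scoring)."""
    snps = [s for s in table.rsids if s not in APOE_SNPS]
    hwe_rows = []
    for grp in groups.unique():
        sub = GenotypeTable(table.dosage.loc[groups == grp])
        for rsid in snps:
            res = hwe_chisq(sub.genotype_counts(rsid))
            hwe_rows.append({"group": grp, "rsid": rsid, "chi2": res.chi2,
                             "p_value": res.p, "degenerate": res.degenerate})
    ld_rows, excluded = [], []
    core = set(definition.snps)
    for i, a in enumerate(snps):
        for b in snps[i + 1:]:
            try:
                ld = ld_pairwise(table.dosage[a], table.dosage[b])
            except ValueError:
                continue
            ld_rows.append({"rsid_a": a, "rsid_b": b, "D": ld.D,
                            "D_prime": ld.D_prime, "r2": ld.r2, "p_value": ld.p})
            if ld.D_prime >= ld_cut:
                # drop the non-core member; if both are core, the lower-weight one
                if a in core and b in core:
                    drop = min(a, b, key=lambda r: definition.snps[r].weight_per_allele)
                else:
                    drop = a if a not in core else b
                if drop not in excluded:
                    excluded.append(drop)
                    logger.warning("LD screen: %s excluded (D'=%.3f with %s)",
                                   drop, ld.D_prime, a if drop == b else b)
    return pd.DataFrame(hwe_rows), pd.DataFrame(ld_rows), excluded


def derive_phenotypes(pheno: pd.DataFrame,
                      statin_table: StatinCorrectionTable | None = None,
                      dlcn_table: DlcnTable | None = None) -> pd.DataFrame:
    """eLDLC from measured LDLC + statin exposure, then DLCN and groups.

    Rows whose statin exposure has no correction-table entry are dropped
    with a logged count.
    """
    statin_table = statin_table or StatinCorrectionTable.default()
    df = pheno.copy()
    eldlc, keep = [], []
    for idx, row in df.iterrows():
        try:
            eldlc.append(estimate_pretreatment_ldlc(
                float(row["LDLC"]), row.get("statin_type"),
                row.get("statin_dose"), statin_table))
            keep.append(idx)
        except KeyError:
            logger.warning("row %s: unresolvable statin exposure; excluded", idx)
    df = df.loc[keep]
    df["eLDLC"] = eldlc
    dl = dlcn_score_frame(df, table=dlcn_table)
    df["dlcn_points"] = dl["dlcn_points"]
    df["dlcn_category"] = dl["dlcn_category"]
    df["subgroup"] = assign_groups(df)
    return df


def emit_group_summary(df: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Median (IQR) per continuous trait and n (%) per categorical item per
    group, with between-group p-values: normality-gated t/Welch vs
    Mann-Whitney for continuous traits, chi-squared for categorical.
    p-values above 0.10 are suppressed.
    """
    groups = [g for g in df[group_col].unique() if (df[group_col] == g).sum() > 0]
    if len(groups) != 2:
        # summarize without tests when not exactly two groups
        pass
    rows = []
    cont = [c for c in CONTINUOUS_TRAITS + ("LDLC", "TC", "wPRS", "aPRS")
            if c in df.columns]
    cat = [c for c in UNIVARIATE_BINARY if c in df.columns]
    for col in cont:
        row = {"variable": col, "type": "continuous"}
        vals = {}
        for g in groups:
            v = df.loc[df[group_col] == g, col].dropna().astype(float)
            vals[g] = v
            q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
            row[f"{g}"] = f"{med:.1f} ({q1:.1f}-{q3:.1f})"
        if len(groups) == 2:
            a, b = (vals[g].to_numpy() for g in groups[:2])
            p = _gated_two_sample_p(a, b)
            row["p_value"] = p if p <= 0.10 else np.nan
        rows.append(row)
    for col in cat:
        row = {"variable": col, "type": "categorical"}
        for g in groups:
            v = df.loc[df[group_col] == g, col].astype(bool)
            row[f"{g}"] = f"{int(v.sum())} ({100 * v.mean():.1f}%)"
        if len(groups) == 2:
            tab = pd.crosstab(df[group_col], df[col].astype(bool))
            if tab.shape == (2, 2):
                chi2, p, _, _ = sps.chi2_contingency(tab)
                row["p_value"] = p if p <= 0.10 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _gated_two_sample_p(a: np.ndarray, b: np.ndarray) -> float:
    """t-test (Welch on unequal variance) when both samples pass the
    Lilliefors normality check at alpha = 0.05, else Mann-Whitney."""
    normal = True
    for v in (a, b):
        if len(v) < 5 or np.std(v) == 0:
            normal = False
            break
        _, p_norm = lilliefors(v)
        if p_norm < 0.05:
            normal = False
            break
    if normal:
        _, p_var = _f_test_var(a, b)
        equal_var = p_var >= 0.05
        _, p = sps.ttest_ind(a, b, equal_var=equal_var)
        return float(p)
    from .stats import mann_whitney as mw
    return mw(a, b).p_value


def _f_test_var(a, b):
    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2 * min(sps.f.sf(f, dfa, dfb), sps.f.cdf(f, dfa, dfb))
    return f, min(p, 1.0)


def run_full_analysis(
    genotypes: GenotypeTable,
    phenotypes: pd.DataFrame,
    definition: ScoreDefinition | None = None,
    config: RunConfig | None = None,
    jt_seed: int = 0,
) -> ReportBundle:
    """Run QC, scoring, phenotype derivation and the association battery,
    returning a ReportBundle whose tables mirror the published layout."""
    definition = definition or ScoreDefinition.default()
    config = config or RunConfig(synthetic=True, seed=jt_seed)

    group = phenotypes["group"].astype(str)
    hwe_tab, ld_tab, ld_dropped = qc_genotypes(
        genotypes, definition, group, config.ld_dprime_cut)

    scored = scored_cohort(genotypes, definition)
    score_cols = [c for c in ("aPRS", "wPRS", "wPRS_z", "percentile", "decile")]
    df = phenotypes.drop(columns=[c for c in score_cols if c in phenotypes], errors="ignore")
    df = df.join(scored[score_cols])
    if "eLDLC" not in df or "dlcn_points" not in df:
        df = derive_phenotypes(df)
    elif "subgroup" not in df:
        dl = dlcn_score_frame(df)
        df["dlcn_points"] = dl["dlcn_points"]
        df["dlcn_category"] = dl["dlcn_category"]
        df["subgroup"] = assign_groups(df)

    y_case = (group == "PCHD").astype(int).to_numpy()
    w = df["wPRS_z"].to_numpy(float)

    # frequency table analog: per-group MAF + median PRS
    freq_rows = []
    for g in df["subgroup"].unique():
        sub = GenotypeTable(genotypes.dosage.loc[df["subgroup"] == g])
        for rsid in [s for s in genotypes.rsids if s not in APOE_SNPS]:
            freq_rows.append({"group": g, "rsid": rsid,
                              "maf": sub.minor_allele_frequency(rsid)})
        for prs in ("aPRS", "wPRS"):
            v = df.loc[df["subgroup"] == g, prs]
            freq_rows.append({"group": g, "rsid": prs, "maf": np.nan,
                              "median": v.median(), "iqr_low": v.quantile(0.25),
                              "iqr_high": v.quantile(0.75)})
    freq_tab = pd.DataFrame(freq_rows)

    # trait associations with wPRS Z (standardized betas / ORs)
    assoc = []
    for trait in CONTINUOUS_TRAITS:
        if trait in df:
            assoc.append((f"{trait}_per_sd",
                          linear_fit_standardized(df[trait].to_numpy(float), w)))
    assoc.append(("eLDLC_gt_190_per_sd",
                  logistic_fit((df["eLDLC"] > 190).astype(int), {"w": w}).results["w"]))
    assoc.append(("dlcn_ge_3_per_sd",
                  logistic_fit((df["dlcn_points"] >= 3).astype(int), {"w": w}).results["w"]))
    for b in UNIVARIATE_BINARY:
        if b in df:
            assoc.append((f"{b}_or_per_sd",
                          logistic_fit(df[b].astype(int), {"w": w}).results["w"]))
    assoc.append(("spearman_wprs_eldlc", spearman_corr(df["wPRS"], df["eLDLC"])))
    assoc.append(("spearman_wprs_dlcn", spearman_corr(df["wPRS"], df["dlcn_points"])))
    trait_tab = _rows(assoc)

    # univariate PCHD models
    uni = []
    for name, x in (
        [(b, df[b].astype(int)) for b in UNIVARIATE_BINARY if b in df]
        + [(t, df[t].astype(float)) for t in ("BMI", "eLDLC", "HDLC", "Lpa") if t in df]
        + [("wPRS_z", df["wPRS_z"]), ("aPRS_z", sps.zscore(df["aPRS"].astype(float), ddof=1))]
    ):
        uni.append((name, logistic_fit(y_case, {name: x}).results[name]))
    uni_tab = _rows(uni)

    # multivariate models and nested comparison
    reduced = logistic_fit(y_case, {k: df[k].astype(float) for k in REDUCED_MODEL if k in df})
    complete = logistic_fit(y_case, {k: df[k].astype(float) for k in COMPLETE_MODEL if k in df})
    plus = logistic_fit(y_case, {**{k: df[k].astype(float) for k in REDUCED_MODEL if k in df},
                                 "wPRS_z": df["wPRS_z"]})
    cmp_wprs = nested_model_compare(reduced, plus)
    multi_rows = []
    for model_name, fit in (("reduced", reduced), ("complete", complete),
                            ("reduced_plus_wprs", plus)):
        for term, r in fit.results.items():
            multi_rows.append({"model": model_name, "term": term, **r.to_row()})
        multi_rows.append({"model": model_name, "term": "_summary",
                           "estimate": fit.cox_snell_r2, "test": "cox_snell_r2",
                           "n": fit.n, "p_value": np.nan,
                           "ci_low": fit.accuracy, "ci_high": np.nan,
                           "marginal": False})
    multi_tab = pd.DataFrame(multi_rows)

    # decile trends (JT) and percentile-extreme comparisons
    trend = []
    deciles = df["decile"].astype(int)
    for trait in ("eLDLC", "dlcn_points"):
        groups_ord = [df.loc[deciles == d, trait].to_numpy(float)
                      for d in sorted(deciles.unique())]
        trend.append((f"jt_{trait}_by_decile",
                      jonckheere_terpstra(groups_ord, seed=jt_seed)))
    for bottom in config.bottom_percentiles:
        trend.append((f"rr_top{config.top_percentile:.0f}_vs_bottom{bottom:.0f}",
                      extreme_percentile_comparison(df["wPRS"], y_case,
                                                    config.top_percentile, bottom)))
    trend_tab = _rows(trend)

    # FH-phenotype discrimination (DLCN categories / dFH screening)
    fh_rows = []
    cat_order = ["unlikely", "possible", "probable", "definite"]
    cat_groups = [df.loc[df["dlcn_category"] == c, "wPRS"].to_numpy(float)
                  for c in cat_order if (df["dlcn_category"] == c).any()]
    if len(cat_groups) >= 2:
        fh_rows.append(("jt_wprs_by_dlcn_category",
                        jonckheere_terpstra(cat_groups, seed=jt_seed)))
    ge3 = (df["dlcn_points"] >= 3).astype(int).to_numpy()
    fh_rows.append(("mw_wprs_dlcn_ge3_vs_lt3",
                    mann_whitney(df.loc[ge3 == 1, "wPRS"], df.loc[ge3 == 0, "wPRS"])))
    roc_ge3 = roc_analysis(df["wPRS"].to_numpy(float), ge3, criterion="youden")
    fh_tab = _rows(fh_rows)
    roc_rows = [{"label": "roc_wprs_dlcn_ge3", "auc": roc_ge3.auc,
                 "auc_ci_low": roc_ge3.auc_ci[0], "auc_ci_high": roc_ge3.auc_ci[1],
                 "threshold": roc_ge3.operating_threshold,
                 "sensitivity": roc_ge3.operating_sensitivity,
                 "specificity": roc_ge3.operating_specificity, "criterion": "youden"}]
    is_dfh = (df["subgroup"] == "dFH").astype(int).to_numpy()
    if is_dfh.sum() > 0:
        roc_dfh = roc_analysis(df["wPRS"].to_numpy(float), is_dfh,
                               criterion="sensitivity", target_sensitivity=1.0)
        roc_rows.append({"label": "roc_wprs_dfh_screening", "auc": roc_dfh.auc,
                         "auc_ci_low": roc_dfh.auc_ci[0],
                         "auc_ci_high": roc_dfh.auc_ci[1],
                         "threshold": roc_dfh.operating_threshold,
                         "sensitivity": roc_dfh.operating_sensitivity,
                         "specificity": roc_dfh.operating_specificity,
                         "criterion": "sensitivity=1.0"})
    roc_tab = pd.DataFrame(roc_rows)

    summary_tab = emit_group_summary(df)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "score_definition": definition.version,
        "seed": config.seed,
        "n_individuals": int(len(df)),
        "n_cases": int(y_case.sum()),
        "n_controls": int(len(df) - y_case.sum()),
        "ld_dprime_cut": config.ld_dprime_cut,
        "ld_excluded_snps": ld_dropped,
        "n_incomplete_scores": int((~scored["complete"]).sum()),
        "nested_wprs_lr_p": cmp_wprs.p_value,
        "config_hash": hashlib.sha256(
            json.dumps(vars(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    tables = {
        "group_summary": summary_tab,
        "frequencies_and_prs": freq_tab,
        "hwe": hwe_tab,
        "ld": ld_tab,
        "trait_associations": trait_tab,
        "univariate_pchd": uni_tab,
        "multivariate_pchd": multi_tab,
        "trends_and_extremes": trend_tab,
        "fh_discrimination": fh_tab,
        "roc": roc_tab,
    }
    return ReportBundle(tables=tables, manifest=manifest)
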