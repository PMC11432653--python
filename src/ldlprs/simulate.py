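"""Synthetic genotype-phenotype case-control cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes: score-SNP genotypes under Hardy-Weinberg equilibrium at
configured allele frequencies, one strong-LD APOB pair, APOE genotypes
drawn from a genotype distribution, phenotypic traits coupled to the
weighted polygenic score through a single index (the wPRS Z score), and
case-control labels from a logistic risk model.

Two of the configured effects are *marginal population parameters* that a
naive bivariate-Gaussian draw cannot satisfy simultaneously: the linear
per-SD effect of wPRS on eLDLC and the odds ratio per SD for exceeding
the eLDLC threshold. eLDLC is therefore generated in two stages -- an
exceedance indicator from the configured logistic law, then a conditional
truncated-normal draw whose latent slope is solved numerically so the
standardized linear effect matches its configured value as well.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .genotypes import GenotypeTable
from .score import ScoreDefinition, compute_scores, standardize_scores

logger = logging.getLogger(__name__)

_APOE_TO_DOSAGES = {
    "e2e2": (0, 2), "e2e3": (0, 1), "e2e4": (1, 1),
    "e3e3": (0, 0), "e3e4": (1, 0), "e4e4": (2, 0),
}


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration; defaults reproduce the study conditions.

    Allele and APOE genotype frequencies default to the healthy-control
    column of the published frequency table; trait effects are the
    published standardized per-SD coefficients; threshold effects are the
    published per-SD odds ratios; the case model carries the published
    complete-model odds ratios. Trait means/SDs are back-converted from
    published medians/IQRs assuming near-normality and are therefore
    approximations. ``fh_wprs_slope`` couples the family-history item to
    the wPRS Z score; its default was solved once (large-n calibration)
    so the DLCN >= 3 threshold effect is realized.
    """

    n_cases: int = 125
    n_controls: int = 97
    maf: dict = field(default_factory=lambda: {
        "rs6511720": 0.118, "rs629301": 0.221, "rs1367117": 0.345,
        "rs4299376": 0.350, "rs1800562": 0.031, "rs2479409": 0.350,
        "rs676210": 0.300,  # excluded from scoring; frequency not published
    })
    apoe_probs: dict = field(default_factory=lambda: {
        "e2e2": 0.000, "e2e3": 0.103, "e2e4": 0.041,
        "e3e3": 0.660, "e3e4": 0.196, "e4e4": 0.000,
    })
    ld_pairs: dict = field(default_factory=lambda: {("rs1367117", "rs676210"): 0.99})
    trait_effects: dict = field(default_factory=lambda: {
        "eLDLC": 0.20, "HDLC": -0.14, "BMI": 0.15, "Lpa": 0.05,
    })
    dlcn_effect: float = 0.16          # emergent, via eLDLC bands + items
    threshold_effects: dict = field(default_factory=lambda: {
        "eLDLC_gt_190": 1.36, "DLCN_ge_3": 1.58,
    })
    eldlc_threshold: float = 190.0     # mg/dL
    trait_means: dict = field(default_factory=lambda: {
        "eLDLC": 150.0, "HDLC": 43.0, "BMI": 28.6,
    })
    trait_sds: dict = field(default_factory=lambda: {
        "eLDLC": 58.0, "HDLC": 12.0, "BMI": 4.2,
    })
    lpa_log_median: float = 11.0       # mg/dL, lognormal with assay floor 9.7
    lpa_log_sigma: float = 0.75
    lpa_floor: float = 9.7
    tg_log_median: float = 130.0
    tg_log_sigma: float = 0.45
    binary_rates: dict = field(default_factory=lambda: {
        "smoking": 0.568, "hypertension": 0.360,
        "alcohol": 0.297, "family_history": 0.239,
    })
    fh_wprs_slope: float = 0.74        # calibrated; see class docstring
    case_model: dict = field(default_factory=lambda: {
        "alcohol": np.log(0.29), "hypertension": np.log(2.42),
        "family_history": np.log(10.01), "smoking": np.log(10.86),
        "eLDLC": np.log(1.012), "HDLC": np.log(0.949), "Lpa": np.log(1.020),
    })
    statin_rate: dict = field(default_factory=lambda: {"HC": 0.082, "PCHD": 0.704})
    statin_mix: tuple = (
        ("atorvastatin", 20.0, 0.21), ("atorvastatin", 40.0, 0.27),
        ("atorvastatin", 80.0, 0.12), ("rosuvastatin", 10.0, 0.10),
        ("rosuvastatin", 20.0, 0.10), ("rosuvastatin", 40.0, 0.05),
        ("simvastatin", 20.0, 0.08), ("simvastatin", 40.0, 0.07),
    )
    item_rates_cases: dict = field(default_factory=lambda: {
        "premature_cerebral_peripheral": 0.08,
        "relative_xanthoma_or_arcus": 0.02, "child_high_ldl": 0.005,
        "relative_high_ldl": 0.03,
        "tendon_xanthomata": 0.01, "arcus_cornealis_before_45": 0.02,
    })
    item_rates_controls: dict = field(default_factory=lambda: {
        "relative_xanthoma_or_arcus": 0.005, "child_high_ldl": 0.002,
        "relative_high_ldl": 0.02,
    })

    def validate(self) -> None:
        for rsid, f in self.maf.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"{rsid}: frequency {f} outside (0, 1)")
        tot = sum(self.apoe_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"APOE genotype probabilities sum to {tot}")
        for trait, b in self.trait_effects.items():
            if abs(b) >= 1:
                raise ValueError(f"{trait}: |beta| must be < 1")
        for (a, b), dp in self.ld_pairs.items():
            if not 0.0 <= dp <= 1.0:
                raise ValueError(f"D' for ({a}, {b}) outside [0, 1]")


def _two_locus_haplotype_freqs(p_a: float, p_b: float, d_prime: float):
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    d = d_prime * d_max
    haps = np.array([
        p_a * p_b + d, p_a * (1 - p_b) - d,
        (1 - p_a) * p_b - d, (1 - p_a) * (1 - p_b) + d,
    ])
    if (haps < -1e-12).any():
        raise ValueError(
            f"infeasible D' = {d_prime} at frequencies ({p_a}, {p_b}); "
            f"feasible maximum D = {d_max}"
        )
    return np.clip(haps, 0.0, 1.0)


def sample_genotypes(spec: CohortSpec, n: int, rng: np.random.Generator) -> GenotypeTable:
    """Draw genotypes for n individuals: HWE binomial at each independent
    locus, two-haplotype draws for LD pairs, APOE genotypes directly from
    the genotype distribution (then expanded to the two SNP dosages)."""
    spec.validate()
    cols: dict[str, np.ndarray] = {}
    in_pair = {r for pair in spec.ld_pairs for r in pair}
    for rsid, f in spec.maf.items():
        if rsid in in_pair:
            continue
        cols[rsid] = rng.binomial(2, f, size=n).astype(float)
    for (ra, rb), d_prime in spec.ld_pairs.items():
        haps = _two_locus_haplotype_freqs(spec.maf[ra], spec.maf[rb], d_prime)
        draws = rng.choice(4, size=(n, 2), p=haps)
        # hap index 0, 1 carry allele A; 0, 2 carry allele B
        cols[ra] = (draws <= 1).sum(axis=1).astype(float)
        cols[rb] = ((draws == 0) | (draws == 2)).sum(axis=1).astype(float)
    genos = list(spec.apoe_probs)
    probs = np.array([spec.apoe_probs[g] for g in genos])
    apoe = rng.choice(len(genos), size=n, p=probs)
    d429, d7412 = zip(*(_APOE_TO_DOSAGES[genos[i]] for i in apoe))
    cols["rs429358"] = np.array(d429, dtype=float)
    cols["rs7412"] = np.array(d7412, dtype=float)
    idx = pd.Index([f"S{i:06d}" for i in range(n)], name="individual")
    return GenotypeTable(pd.DataFrame(cols, index=idx))


# ------------------------------------------------- eLDLC dual-constraint draw

def _solve_intercept(gamma_w: np.ndarray, target_mean: float) -> float:
    lo, hi = -30.0, 30.0
    return float(optimize.brentq(
        lambda a: special.expit(a + gamma_w).mean() - target_mean, lo, hi
    ))


def _eldlc_model_corr(b: float, w: np.ndarray, gamma: float, c: float) -> float:
    """Model-implied corr(w, Y) for latent slope b under the two-stage draw."""
    s = np.sqrt(1.0 - b * b)
    a = (c - b * w) / s
    q = special.ndtr(-a)                      # latent exceedance probability
    alpha = _solve_intercept(gamma * w, float(q.mean()))
    p = special.expit(alpha + gamma * w)
    phi = stats.norm.pdf(a)
    sf = np.clip(special.ndtr(-a), 1e-300, 1.0)
    cdf = np.clip(special.ndtr(a), 1e-300, 1.0)
    lam_up = phi / sf
    lam_dn = phi / cdf
    mu_up = b * w + s * lam_up
    mu_dn = b * w - s * lam_dn
    m = p * mu_up + (1 - p) * mu_dn
    e2_up = (b * w) ** 2 + 2 * b * w * s * lam_up + s * s * (1 + a * lam_up)
    e2_dn = (b * w) ** 2 - 2 * b * w * s * lam_dn + s * s * (1 - a * lam_dn)
    ey2 = p * e2_up + (1 - p) * e2_dn
    var_y = float(ey2.mean() - m.mean() ** 2)
    cov = float((w * m).mean() - w.mean() * m.mean())
    return cov / np.sqrt(w.var() * var_y)


def _draw_eldlc(w: np.ndarray, spec: CohortSpec, rng: np.random.Generator):
    """eLDLC draw satisfying both the configured standardized linear beta
    and the configured exceedance odds ratio per wPRS SD."""
    beta = spec.trait_effects["eLDLC"]
    gamma = float(np.log(spec.threshold_effects["eLDLC_gt_190"]))
    mean, sd = spec.trait_means["eLDLC"], spec.trait_sds["eLDLC"]
    c = (spec.eldlc_threshold - mean) / sd
    # negative latent slopes are admissible: a small linear beta must be able
    # to offset the correlation induced by the exceedance odds ratio
    b = float(optimize.brentq(
        lambda bb: _eldlc_model_corr(bb, w, gamma, c) - beta, -0.9, 0.9, xtol=1e-6
    ))
    s = np.sqrt(1.0 - b * b)
    a = (c - b * w) / s
    q = special.ndtr(-a)
    alpha = _solve_intercept(gamma * w, float(q.mean()))
    p = special.expit(alpha + gamma * w)
    exceed = rng.random(len(w)) < p
    u = rng.random(len(w))
    z = np.empty(len(w))
    sf = np.clip(special.ndtr(-a), 1e-300, 1.0)
    cdf = np.clip(special.ndtr(a), 1e-300, 1.0)
    # inverse-CDF truncated normal draws, tail-stable
    z[exceed] = stats.norm.isf(sf[exceed] * (1 - u[exceed]))
    z[~exceed] = stats.norm.ppf(cdf[~exceed] * u[~exceed])
    y = b * w + s * z
    return mean + sd * y, exceed


def sample_phenotypes(genotypes: GenotypeTable, spec: CohortSpec,
                      rng: np.random.Generator,
                      definition: ScoreDefinition | None = None) -> pd.DataFrame:
    """Draw pre-label phenotypes conditional on the wPRS Z score.

    Continuous traits follow trait_Z = beta * wPRS_Z + sqrt(1 - beta^2) * eps
    (eLDLC via the dual-constraint scheme); Lp(a) maps a latent index
    through a lognormal with the assay floor; the family-history flag is
    the one binary risk factor coupled to the score. Group-dependent
    fields (statin exposure, personal-history DLCN items, measured LDLC)
    are finalized by :func:`assign_case_control`.
    """
    spec.validate()
    scores = compute_scores(genotypes, definition or ScoreDefinition.default())
    if not scores["complete"].all():
        raise ValueError("generated genotypes must be fully scoreable")
    w = standardize_scores(scores["wPRS"]).to_numpy()
    n = len(w)
    df = pd.DataFrame(index=genotypes.individuals)
    df["aPRS"] = scores["aPRS"].to_numpy()
    df["wPRS"] = scores["wPRS"].to_numpy()
    df["wPRS_z"] = w
    df["apoe"] = scores["apoe"].to_numpy()

    eldlc, exceed = _draw_eldlc(w, spec, rng)
    df["eLDLC"] = np.maximum(eldlc, 25.0)  # physiologic floor; trims a <1% tail
    assert ((eldlc > spec.eldlc_threshold) == exceed).all()

    for trait in ("HDLC", "BMI"):
        b = spec.trait_effects[trait]
        z = b * w + np.sqrt(1 - b * b) * rng.standard_normal(n)
        df[trait] = spec.trait_means[trait] + spec.trait_sds[trait] * z
    df["HDLC"] = df["HDLC"].clip(lower=15.0)
    df["BMI"] = df["BMI"].clip(lower=16.0)

    b = spec.trait_effects["Lpa"]
    g = b * w + np.sqrt(1 - b * b) * rng.standard_normal(n)
    df["Lpa"] = np.maximum(
        np.exp(np.log(spec.lpa_log_median) + spec.lpa_log_sigma * g), spec.lpa_floor
    )
    df["TG"] = np.exp(np.log(spec.tg_log_median)
                      + spec.tg_log_sigma * rng.standard_normal(n))

    for name in ("smoking", "hypertension", "alcohol"):
        df[name] = rng.random(n) < spec.binary_rates[name]
    kappa = spec.fh_wprs_slope
    alpha_fh = _solve_intercept(kappa * w, spec.binary_rates["family_history"])
    df["family_history"] = rng.random(n) < special.expit(alpha_fh + kappa * w)

    df["age"] = np.clip(rng.normal(48.0, 5.0, size=n).round(), 25, 60)
    df["male"] = rng.random(n) < 0.79
    return df


def assign_case_control(records: pd.DataFrame, spec: CohortSpec,
                        rng: np.random.Generator,
                        n_cases: int | None = None,
                        n_controls: int | None = None) -> pd.DataFrame:
    """Label individuals HC/PCHD from the configured logistic case model
    and finalize the group-dependent fields.

    The intercept is solved so the expected case count matches the target;
    a Bernoulli draw is then adjusted by the minimal number of random,
    probability-weighted flips to match the count exactly. Cases receive
    the personal premature-CHD item (an inclusion criterion), group-rate
    statin exposure, and measured LDLC back-derived from eLDLC through the
    statin correction table.
    """
    from .phenotype import StatinCorrectionTable

    n = len(records)
    if n_cases is None or n_controls is None:
        frac = spec.n_cases / (spec.n_cases + spec.n_controls)
        n_cases = int(round(n * frac))
        n_controls = n - n_cases
    if n_cases + n_controls != n:
        raise ValueError("n_cases + n_controls must equal the cohort size")
    if not 0 < n_cases < n:
        raise ValueError("case count unattainable")

    eta = np.zeros(n)
    for name, coef in spec.case_model.items():
        eta += coef * records[name].astype(float).to_numpy()
    alpha = _solve_intercept(eta, n_cases / n)
    p = special.expit(alpha + eta)
    case = rng.random(n) < p
    diff = int(case.sum()) - n_cases
    if diff > 0:  # demote the excess, preferring low-probability cases
        idx = np.flatnonzero(case)
        wts = (1 - p[idx]) / (1 - p[idx]).sum()
        case[rng.choice(idx, size=diff, replace=False, p=wts)] = False
    elif diff < 0:
        idx = np.flatnonzero(~case)
        wts = p[idx] / p[idx].sum()
        case[rng.choice(idx, size=-diff, replace=False, p=wts)] = True

    df = records.copy()
    df["group"] = np.where(case, "PCHD", "HC")
    df["premature_chd"] = case

    for col, rate in spec.item_rates_cases.items():
        draw = rng.random(n) < rate
        df[col] = draw & case
    for col, rate in spec.item_rates_controls.items():
        draw = rng.random(n) < rate
        df[col] = df[col] | (draw & ~case) if col in df else (draw & ~case)
    # the family-history DLCN item is the sampled family-history flag
    df["relative_premature_chd"] = df["family_history"]

    statin_p = np.where(case, spec.statin_rate["PCHD"], spec.statin_rate["HC"])
    treated = rng.random(n) < statin_p
    mix_p = np.array([m[2] for m in spec.statin_mix])
    mix_p = mix_p / mix_p.sum()
    choice = rng.choice(len(spec.statin_mix), size=n, p=mix_p)
    table = StatinCorrectionTable.default()
    stype = np.array([spec.statin_mix[i][0] for i in choice], dtype=object)
    sdose = np.array([spec.statin_mix[i][1] for i in choice])
    df["statin_type"] = np.where(treated, stype, None)
    df["statin_dose"] = np.where(treated, sdose, np.nan)
    r = np.array([
        table.reduction(t, d) if t is not None else 0.0
        for t, d in zip(df["statin_type"], df["statin_dose"])
    ])
    df["LDLC"] = df["eLDLC"].to_numpy() * (1.0 - r)
    df["TC"] = df["LDLC"] + df["HDLC"] + df["TG"] / 5.0
    df["nonHDLC"] = df["TC"] - df["HDLC"]
    return df


def simulate_cohort(
    spec: CohortSpec | None = None,
    n: int | None = None,
    seed: int = 0,
    definition: ScoreDefinition | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Generate a complete labelled cohort.

    ``n`` defaults to ``spec.n_cases + spec.n_controls``; larger cohorts
    keep the configured case fraction. The single seed is expanded into
    independent per-stage substreams so stages can be regenerated
    independently; identical (spec, n, seed) gives identical output.
    """
    spec = spec or CohortSpec()
    spec.validate()
    total = n if n is not None else spec.n_cases + spec.n_controls
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_g, rng_p, rng_c = (np.random.default_rng(s) for s in ss)
    genotypes = sample_genotypes(spec, total, rng_g)
    pheno = sample_phenotypes(genotypes, spec, rng_p, definition)
    frac = spec.n_cases / (spec.n_cases + spec.n_controls)
    n_cases = int(round(total * frac))
    labelled = assign_case_control(pheno, spec, rng_c,
                                   n_cases=n_cases, n_controls=total - n_cases)
    return genotypes, labelled


def spec_with(base: CohortSpec | None = None, **overrides) -> CohortSpec:
    """Convenience: a copy of the (default) spec with fields replaced."""
    return replace(base or CohortSpec(), **overrides)
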