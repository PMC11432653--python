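"""The association battery: 2x2 odds ratios, logistic and linear
regression, Hosmer-Lemeshow calibration, nested-model comparison, rank
tests, ordered-trend (Jonckheere-Terpstra) testing, ROC analysis with
DeLong confidence intervals, and percentile-extreme risk comparisons.

All p-values are two-tailed unless stated otherwise; p in (0.05, 0.15] is
flagged as marginally significant. No multiple-testing adjustment is
applied anywhere.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


@dataclass
class AssociationResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    test_name: str
    n: int
    extras: dict = field(default_factory=dict)

    @property
    def marginal(self) -> bool:
        return 0.05 < self.p_value <= 0.15

    def to_row(self) -> dict:
        return {
            "test": self.test_name,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "marginal": self.marginal,
        }


# ---------------------------------------------------------------- 2x2 tables

def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> AssociationResult:
    """Odds ratio with Woolf 95% CI and Wald p from a 2x2 table.

    Cell layout: a = exposed cases, b = unexposed cases, c = exposed
    controls, d = unexposed controls. A zero cell triggers the
    Haldane-Anscombe +0.5 correction on all cells (flagged in extras).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if (cells[:2].sum() == 0 or cells[2:].sum() == 0
            or cells[[0, 2]].sum() == 0 or cells[[1, 3]].sum() == 0):
        raise ValueError("degenerate 2x2 table (empty row or column)")
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = np.log(or_) / se
    return AssociationResult(
        estimate=float(or_),
        ci_low=float(np.exp(np.log(or_) - Z95 * se)),
        ci_high=float(np.exp(np.log(or_) + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        test_name="odds_ratio_2x2",
        n=int(a + b + c + d),
        extras={"haldane_corrected": corrected, "log_or_se": float(se)},
    )


# ------------------------------------------------------------- regressions

@dataclass
class LogisticFit:
    """A fitted logistic model with per-covariate results and summary metrics."""

    results: dict[str, AssociationResult]
    model: object
    n: int
    deviance: float
    null_deviance: float
    llf: float
    llnull: float
    cox_snell_r2: float
    accuracy: float
    sensitivity: float
    specificity: float
    converged: bool
    fittedvalues: np.ndarray
    params: pd.Series
    exog_names: list[str]


def logistic_fit(outcome, covariates, add_constant: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS via statsmodels).

    Returns per-covariate odds ratios with Wald 95% CIs and p-values, plus
    deviance, Cox-Snell R^2 and classification metrics at probability 0.5.
    Perfect separation or non-convergence is reported via ``converged``.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(covariates).astype(float)
    if X.shape[1] == 0:
        X = pd.DataFrame(index=np.arange(len(y)))
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome and covariates differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if X.shape[0] <= X.shape[1] + int(add_constant):
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(sm.add_constant(X, has_constant="add")) < X.shape[1] + 1:
        raise ValueError("rank-deficient design matrix (collinear columns)")
    exog = sm.add_constant(X, has_constant="add") if add_constant else X
    model = sm.Logit(y, exog)
    converged = True
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception as err:  # perfect separation raises in statsmodels
        logger.warning("logistic fit failed: %s", err)
        fit = model.fit(disp=0, maxiter=200, method="bfgs")
        converged = False
    if not converged:
        logger.warning("logistic fit did not converge (possible separation)")

    ci = fit.conf_int()
    results = {}
    with np.errstate(over="ignore"):  # CI bounds may overflow under separation
        for name in exog.columns:
            beta = fit.params[name]
            results[name] = AssociationResult(
                estimate=float(np.exp(beta)),
                ci_low=float(np.exp(ci.loc[name, 0])),
                ci_high=float(np.exp(ci.loc[name, 1])),
                p_value=float(fit.pvalues[name]),
                test_name="logistic_wald",
                n=len(y),
                extras={"beta": float(beta), "se": float(fit.bse[name])},
            )
    p_hat = np.asarray(fit.predict(exog))
    pred = (p_hat >= 0.5).astype(float)
    tp = float(((pred == 1) & (y == 1)).sum())
    tn = float(((pred == 0) & (y == 0)).sum())
    lr = 2 * (fit.llf - fit.llnull)
    return LogisticFit(
        results=results,
        model=fit,
        n=len(y),
        deviance=float(-2 * fit.llf),
        null_deviance=float(-2 * fit.llnull),
        llf=float(fit.llf),
        llnull=float(fit.llnull),
        cox_snell_r2=float(1 - np.exp(-lr / len(y))),
        accuracy=float((pred == y).mean()),
        sensitivity=float(tp / max((y == 1).sum(), 1)),
        specificity=float(tn / max((y == 0).sum(), 1)),
        converged=converged,
        fittedvalues=p_hat,
        params=fit.params,
        exog_names=list(exog.columns),
    )


def hosmer_lemeshow(fitted_probs, outcomes, groups: int = 10) -> AssociationResult:
    """Hosmer-Lemeshow decile-of-risk goodness-of-fit chi-squared (df = g-2)."""
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < groups:
        raise ValueError("fewer observations than groups")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("fitted probabilities must lie in (0, 1)")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, groups + 1)))
    if len(edges) - 1 < groups:
        logger.warning("ties collapsed decile-of-risk groups: %d -> %d",
                       groups, len(edges) - 1)
    bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    chi2 = 0.0
    g_used = 0
    for g in range(len(edges) - 1):
        m = bins == g
        if m.sum() == 0:
            continue
        g_used += 1
        o1, e1 = y[m].sum(), p[m].sum()
        o0, e0 = (1 - y[m]).sum(), (1 - p[m]).sum()
        if e1 > 0:
            chi2 += (o1 - e1) ** 2 / e1
        if e0 > 0:
            chi2 += (o0 - e0) ** 2 / e0
    df = max(g_used - 2, 1)
    return AssociationResult(
        estimate=float(chi2),
        ci_low=np.nan,
        ci_high=np.nan,
        p_value=float(stats.chi2.sf(chi2, df)),
        test_name="hosmer_lemeshow",
        n=len(y),
        extras={"df": df, "groups_used": g_used},
    )


def nested_model_compare(fit_small: LogisticFit, fit_large: LogisticFit) -> AssociationResult:
    """Compare nested logistic models.

    The canonical statistic is the likelihood-ratio chi-squared on the
    parameter difference; an extra-sum-of-squares style F-form on the
    residual deviances is reported alongside, as are both model AUCs.
    """
    small_terms = set(fit_small.exog_names)
    large_terms = set(fit_large.exog_names)
    if not small_terms <= large_terms or fit_small.n != fit_large.n:
        raise ValueError("models are not nested on the same observations")
    df = len(large_terms) - len(small_terms)
    lr = fit_small.deviance - fit_large.deviance
    if df == 0:
        return AssociationResult(0.0, np.nan, np.nan, 1.0, "lr_test", fit_small.n,
                                 extras={"df": 0, "F": 0.0, "F_p": 1.0})
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df))
    denom_df = fit_large.n - len(large_terms)
    f_stat = (lr / df) / (fit_large.deviance / denom_df)
    f_p = float(stats.f.sf(f_stat, df, denom_df))
    y = np.asarray(fit_large.model.model.endog)
    auc_small = auc_mann_whitney(fit_small.fittedvalues, y)
    auc_large = auc_mann_whitney(fit_large.fittedvalues, y)
    return AssociationResult(
        estimate=float(lr), ci_low=np.nan, ci_high=np.nan, p_value=p,
        test_name="lr_test", n=fit_large.n,
        extras={"df": df, "F": float(f_stat), "F_p": f_p,
                "auc_small": auc_small, "auc_large": auc_large},
    )


def linear_fit_standardized(y, x, standardize: bool = True) -> AssociationResult:
    """Simple linear regression; with ``standardize`` both variables are
    z-scored so the slope is the standardized beta (= Pearson r)."""
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    if len(yv) < 3:
        raise ValueError("need n >= 3")
    if np.std(xv) == 0 or (standardize and np.std(yv) == 0):
        raise ValueError("zero-variance input")
    if standardize:
        yv = (yv - yv.mean()) / yv.std(ddof=1)
        xv = (xv - xv.mean()) / xv.std(ddof=1)
    fit = sm.OLS(yv, sm.add_constant(xv)).fit()
    ci = fit.conf_int()
    return AssociationResult(
        estimate=float(fit.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(fit.pvalues[1]),
        test_name="linear_standardized_beta" if standardize else "linear_beta",
        n=len(yv),
        extras={"se": float(fit.bse[1]), "r2": float(fit.rsquared)},
    )


# ---------------------------------------------------------------- rank tests

def spearman_corr(x, y) -> AssociationResult:
    """Spearman rank correlation with t-approximation p-value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) < 3:
        raise ValueError("need n >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(xv, yv)
    n = len(xv)
    if abs(rho) < 1:
        se = np.sqrt((1 - rho**2) / (n - 2))
        z = np.arctanh(rho)
        zse = 1 / np.sqrt(n - 3) if n > 3 else np.nan
        lo, hi = np.tanh(z - Z95 * zse), np.tanh(z + Z95 * zse)
    else:
        lo = hi = rho
    return AssociationResult(float(rho), float(lo), float(hi), float(p),
                             "spearman", n)


def mann_whitney(group_a, group_b) -> AssociationResult:
    """Mann-Whitney U, exact for min(n) <= 8 without ties, otherwise the
    tie-corrected normal approximation; two-tailed."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return AssociationResult(
        estimate=float(res.statistic),
        ci_low=np.nan, ci_high=np.nan,
        p_value=float(res.pvalue),
        test_name=f"mann_whitney_{method}",
        n=len(a) + len(b),
        extras={"n_a": len(a), "n_b": len(b)},
    )


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            less = (gi[:, None] < gj[None, :]).sum()
            ties = (gi[:, None] == gj[None, :]).sum()
            jt += less + 0.5 * ties
    return float(jt)


def jonckheere_terpstra(
    groups,
    alternative: str = "two-sided",
    permutations: int = 10_000,
    seed: int | None = None,
    force_permutation: bool | None = None,
) -> AssociationResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    JT is the sum of pairwise Mann-Whitney counts in group order (ties
    count one half). The p-value uses the tie-corrected normal
    approximation, replaced by a seeded permutation test (>= ``permutations``
    draws) whenever any group has fewer than 5 observations.
    ``alternative`` is one of "increasing", "decreasing", "two-sided".
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 ordered groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("all groups must be non-empty")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    jt = _jt_statistic(gs)
    sizes = np.array([len(g) for g in gs], dtype=float)
    n = sizes.sum()
    mean_jt = (n**2 - (sizes**2).sum()) / 4.0

    pooled = np.concatenate(gs)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    term1 = (n * (n - 1) * (2 * n + 5)
             - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
             - (t * (t - 1) * (2 * t + 5)).sum()) / 72.0
    term2 = ((sizes * (sizes - 1) * (sizes - 2)).sum()
             * (t * (t - 1) * (t - 2)).sum()) / (36.0 * n * (n - 1) * (n - 2))
    term3 = ((sizes * (sizes - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n * (n - 1))
    var_jt = term1 + term2 + term3

    use_perm = force_permutation if force_permutation is not None else bool(sizes.min() < 5)
    if var_jt <= 0:
        use_perm = True
    z = (jt - mean_jt) / np.sqrt(var_jt) if var_jt > 0 else np.nan

    if use_perm:
        rng = np.random.default_rng(seed)
        splits = np.cumsum(sizes.astype(int))[:-1]
        count = 0
        obs_dev = abs(jt - mean_jt)
        exceed_inc = 0
        for _ in range(permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, splits)
            jt_p = _jt_statistic(parts)
            if abs(jt_p - mean_jt) >= obs_dev - 1e-12:
                count += 1
            if jt_p >= jt - 1e-12:
                exceed_inc += 1
        p_two = (count + 1) / (permutations + 1)
        p_inc = (exceed_inc + 1) / (permutations + 1)
        p_dec = 1 - (exceed_inc) / (permutations + 1)
        method = "permutation"
    else:
        p_inc = float(stats.norm.sf(z))
        p_dec = float(stats.norm.cdf(z))
        p_two = float(2 * stats.norm.sf(abs(z)))
        method = "normal"
    p = {"increasing": p_inc, "decreasing": p_dec, "two-sided": p_two}[alternative]
    return AssociationResult(
        estimate=jt, ci_low=np.nan, ci_high=np.nan, p_value=float(min(p, 1.0)),
        test_name=f"jonckheere_terpstra_{method}",
        n=int(n),
        extras={"z": float(z) if np.isfinite(z) else np.nan, "mean": float(mean_jt),
                "var": float(var_jt), "alternative": alternative},
    )


# ----------------------------------------------------------------------- ROC

def auc_mann_whitney(scores, labels) -> float:
    """AUC via the Mann-Whitney identity U / (n1 * n0), ties half-weighted."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _delong_auc_var(scores, labels) -> tuple[float, float]:
    """DeLong AUC and its variance via placement (structural) components."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    # placement values by midranks
    all_s = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_s)
    pos_ranks, neg_ranks = ranks[:m], ranks[m:]
    auc = (pos_ranks.sum() - m * (m + 1) / 2) / (m * n)
    v10 = (pos_ranks - stats.rankdata(pos)) / n
    v01 = 1.0 - (neg_ranks - stats.rankdata(neg)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    auc_p: float
    operating_threshold: float
    operating_sensitivity: float
    operating_specificity: float
    criterion: str
    n: int


def roc_analysis(
    scores,
    labels,
    criterion: str = "youden",
    target_sensitivity: float | None = None,
) -> RocCurve:
    """Empirical ROC curve with DeLong AUC CI and an operating point.

    Operating thresholds are midpoints between adjacent unique score
    values (a prediction is positive when score > threshold). The point
    either maximizes Youden's J or is the largest threshold achieving a
    requested sensitivity (``criterion='sensitivity'``), e.g. 1.0 for a
    no-false-negative screening rule.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for ROC analysis")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cand = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([( s[y == 1] > t).mean() for t in cand])
    spec = np.array([( s[y == 0] <= t).mean() for t in cand])

    auc, var = _delong_auc_var(s, y)
    se = np.sqrt(var)
    lo, hi = max(auc - Z95 * se, 0.0), min(auc + Z95 * se, 1.0)
    z = (auc - 0.5) / se if se > 0 else np.inf
    auc_p = float(2 * stats.norm.sf(abs(z)))

    if criterion == "youden":
        idx = int(np.argmax(sens + spec - 1.0))
    elif criterion == "sensitivity":
        if target_sensitivity is None:
            raise ValueError("target_sensitivity required")
        ok = np.where(sens >= target_sensitivity - 1e-12)[0]
        if len(ok) == 0:
            raise ValueError("requested sensitivity unattainable")
        idx = int(ok[np.argmax(spec[ok])])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return RocCurve(
        thresholds=cand, sensitivity=sens, specificity=spec,
        auc=float(auc), auc_ci=(float(lo), float(hi)), auc_p=auc_p,
        operating_threshold=float(cand[idx]),
        operating_sensitivity=float(sens[idx]),
        operating_specificity=float(spec[idx]),
        criterion=criterion, n=len(y),
    )


# --------------------------------------------------- percentile-extreme risk

def extreme_percentile_comparison(
    scores,
    outcome,
    top_pct: float = 90.0,
    bottom_pct: float = 10.0,
) -> AssociationResult:
    """Outcome risk in the top score tail (> top percentile) vs the bottom
    tail (<= bottom percentile): risk ratio with Katz log CI and a
    two-sided Fisher exact p."""
    s = pd.Series(scores, dtype=float)
    y = pd.Series(np.asarray(outcome, dtype=int), index=s.index)
    hi_cut = np.percentile(s.dropna(), top_pct)
    lo_cut = np.percentile(s.dropna(), bottom_pct)
    top = s > hi_cut
    bot = s <= lo_cut
    n1, n0 = int(top.sum()), int(bot.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("empty percentile tail")
    a = int(y[top].sum())
    c = int(y[bot].sum())
    p1, p0 = a / n1, c / n0
    if c == 0 or a == 0:
        a_, c_, n1_, n0_ = a + 0.5, c + 0.5, n1 + 0.5, n0 + 0.5
    else:
        a_, c_, n1_, n0_ = a, c, n1, n0
    rr = (a_ / n1_) / (c_ / n0_)
    se = np.sqrt(1 / a_ - 1 / n1_ + 1 / c_ - 1 / n0_)
    table = [[a, n1 - a], [c, n0 - c]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return AssociationResult(
        estimate=float(rr),
        ci_low=float(np.exp(np.log(rr) - Z95 * se)),
        ci_high=float(np.exp(np.log(rr) + Z95 * se)),
        p_value=float(fisher_p),
        test_name="risk_ratio_extreme_percentiles",
        n=n1 + n0,
        extras={"prevalence_top": p1, "prevalence_bottom": p0,
                "n_top": n1, "n_bottom": n0,
                "top_pct": top_pct, "bottom_pct": bottom_pct},
    )
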