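"""Genotype containers, APOE epsilon-genotype calling, Hardy-Weinberg and
linkage-disequilibrium machinery.

Dosages throughout count the locus's *minor* allele as fixed by the score
definition (0, 1, 2, or NaN for missing) -- not the ALT allele of whatever
file the genotypes came from.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

APOE_GENOTYPES = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")

# epsilon haplotypes on (rs429358, rs7412): e2 = (T, T), e3 = (T, C), e4 = (C, C)
_APOE_CALL = {
    (0, 0): "e3e3",
    (1, 0): "e3e4",
    (2, 0): "e4e4",
    (0, 1): "e2e3",
    (0, 2): "e2e2",
    (1, 1): "e2e4",  # ambiguous double heterozygote; e1 ignored by convention
}


@dataclass(frozen=True)
class SNPLocus:
    """A biallelic score SNP with its allele identities."""

    rsid: str
    gene: str
    minor_allele: str
    common_allele: str
    minor_allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.minor_allele == self.common_allele:
            raise ValueError(f"{self.rsid}: minor and common allele identical")
        maf = self.minor_allele_frequency
        if maf is not None and not 0.0 <= maf <= 0.5:
            raise ValueError(f"{self.rsid}: MAF {maf} outside [0, 0.5]")


@dataclass
class GenotypeTable:
    """Per-individual minor-allele dosages for a set of rsID-keyed loci.

    ``dosage`` is individuals x rsids, values in {0, 1, 2} or NaN.
    """

    dosage: pd.DataFrame
    loci: dict[str, SNPLocus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.dosage.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def individuals(self) -> pd.Index:
        return self.dosage.index

    @property
    def rsids(self) -> list[str]:
        return list(self.dosage.columns)

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """(n_MM, n_Mm, n_mm) counts, common homozygote first."""
        d = self.dosage[rsid].dropna()
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())

    def minor_allele_frequency(self, rsid: str) -> float:
        d = self.dosage[rsid].dropna()
        if len(d) == 0:
            raise ValueError(f"{rsid}: no non-missing genotypes")
        return float(d.sum() / (2 * len(d)))


def call_apoe_genotype(g429358: float, g7412: float) -> str | None:
    """Call the APOE epsilon genotype from the two unphased SNP dosages.

    Parameters
    ----------
    g429358 : dosage of C at rs429358 (the e4-defining allele)
    g7412 : dosage of T at rs7412 (the e2-defining allele)

    Returns the genotype label, or None when either dosage is missing. The
    double heterozygote is called e2e4 (the e1e3 alternative requires the
    vanishingly rare e1 haplotype). Dosage pairs implying an e1 (C, T)
    haplotype -- (2, 1), (1, 2), (2, 2) -- are rejected.
    """
    if g429358 is None or g7412 is None:
        return None
    if isinstance(g429358, float) and np.isnan(g429358):
        return None
    if isinstance(g7412, float) and np.isnan(g7412):
        return None
    key = (int(g429358), int(g7412))
    if key[0] not in (0, 1, 2) or key[1] not in (0, 1, 2):
        raise ValueError(f"dosages out of range: {key}")
    try:
        return _APOE_CALL[key]
    except KeyError:
        raise ValueError(
            f"rs429358/rs7412 dosages {key} imply an e1 haplotype, "
            "outside the e2/e3/e4 model"
        ) from None


def call_apoe_series(g429358: pd.Series, g7412: pd.Series) -> pd.Series:
    """Vectorized APOE calling; missing input gives missing output."""
    out = [
        call_apoe_genotype(a, b)
        for a, b in zip(g429358.to_numpy(float), g7412.to_numpy(float))
    ]
    return pd.Series(out, index=g429358.index, dtype=object)


@dataclass
class HweResult:
    chi2: float
    df: int
    p: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    degenerate: bool = False


def hwe_chisq(genotype_counts: tuple[int, int, int]) -> HweResult:
    """Asymptotic 1-df chi-squared test for Hardy-Weinberg equilibrium.

    ``genotype_counts`` is (n_MM, n_Mm, n_mm). The allele frequency is
    estimated from the counts; no continuity correction is applied.
    A monomorphic locus returns chi2 = 0 with ``degenerate`` set.
    """
    n_mm_, n_het, n_mm = (int(c) for c in genotype_counts)
    if min(n_mm_, n_het, n_mm) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_mm_ + n_het + n_mm
    if n == 0:
        raise ValueError("no individuals")
    p_hat = (2 * n_mm_ + n_het) / (2 * n)
    q_hat = 1.0 - p_hat
    expected = (p_hat**2 * n, 2 * p_hat * q_hat * n, q_hat**2 * n)
    observed = (n_mm_, n_het, n_mm)
    if p_hat in (0.0, 1.0):
        return HweResult(0.0, 1, 1.0, observed, expected, degenerate=True)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(float(chi2), 1, float(stats.chi2.sf(chi2, 1)), observed, expected)


@dataclass
class LdResult:
    D: float
    D_prime: float
    r2: float
    haplotype_freqs: dict[str, float]
    chi2: float
    p: float
    n: int
    converged: bool
    n_iter: int


def _hap_loglik(counts: np.ndarray, h: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype counts under
    haplotype frequencies h = (pAB, pAb, paB, pab) and random mating."""
    pAB, pAb, paB, pab = h
    # genotype probability matrix indexed [dosage A][dosage B]
    g = np.empty((3, 3))
    g[2, 2] = pAB**2
    g[2, 1] = 2 * pAB * pAb
    g[2, 0] = pAb**2
    g[1, 2] = 2 * pAB * paB
    g[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    g[1, 0] = 2 * pAb * pab
    g[0, 2] = paB**2
    g[0, 1] = 2 * paB * pab
    g[0, 0] = pab**2
    with np.errstate(divide="ignore"):
        lg = np.log(g)
    mask = counts > 0
    return float((counts[mask] * lg[mask]).sum())


def ld_pairwise(
    dosages_a,
    dosages_b,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LdResult:
    """Pairwise linkage disequilibrium between two loci from unphased
    genotypes, via EM estimation of the four haplotype frequencies.

    D = pAB - pA*pB; D' = |D| / Dmax with the sign-dependent allele-frequency
    bound; r2 = D^2 / (pA qA pB qB). The LD test is the 1-df chi-squared
    2N * r2 on the 2N sampled haplotypes. EM starts at linkage equilibrium;
    only the double heterozygote is phase-ambiguous.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep].astype(int), b[keep].astype(int)
    n = len(a)
    if n < 2:
        raise ValueError("need >= 2 complete genotype pairs")
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1.0)

    pA = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic locus")

    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    ll = _hap_loglik(counts, h)
    n_dh = counts[1, 1]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pAB, pAb, paB, pab = h
        denom = pAB * pab + pAb * paB
        x = 0.5 if denom == 0 else pAB * pab / denom  # P(double het is AB|ab)
        cAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + x * n_dh
        cAb = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + (1 - x) * n_dh
        caB = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1] + (1 - x) * n_dh
        cab = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + x * n_dh
        h = np.array([cAB, cAb, caB, cab]) / (2 * n)
        ll_new = _hap_loglik(counts, h)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        logger.warning("LD EM did not converge in %d iterations", max_iter)

    pAB = float(h[0])
    D = pAB - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    chi2 = 2 * n * r2
    p = float(stats.chi2.sf(chi2, 1))
    haps = {"AB": float(h[0]), "Ab": float(h[1]), "aB": float(h[2]), "ab": float(h[3])}
    return LdResult(float(D), float(min(d_prime, 1.0)), float(min(r2, 1.0)),
                    haps, float(chi2), p, n, converged, it)
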