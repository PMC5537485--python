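"""Cross-study evidence combination and follow-up statistics.

Four pieces of post-scan machinery:

* correlated inverse-variance-weighted (IVW) fixed-effect meta-analysis for
  studies whose estimation errors are correlated (e.g. maternal and paternal
  lifespan effects from the same families, error correlation about 0.11);
* Fisher's combined probability test with an empirically estimated null CDF
  (row sums of -2 ln P over off-target variants) instead of the chi-square
  reference, for combining P values across partially overlapping studies;
* a binomial depletion test: whether life-shortening alleles are
  under-represented among older cohort participants more often than chance;
* effect-scale conversion from a per-allele mortality hazard ratio to years
  of life (10 * ln HR, doubled when offspring genotypes proxy for parents);
* transcript-level MR requiring a minimum number of independent eQTL
  instruments per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mr import InstrumentSet, fit_mr

__all__ = ["MetaInput", "CombinedP", "correlated_ivw", "empirical_fisher",
           "depletion_test", "hr_to_years", "transcript_mr",
           "InsufficientInstrumentsError"]


class InsufficientInstrumentsError(ValueError):
    """Fewer independent instruments than the trustworthiness floor."""


@dataclass
class MetaInput:
    """Per-study estimates of one effect with correlated errors."""

    estimates: np.ndarray
    ses: np.ndarray
    rho: np.ndarray  # error correlation matrix, unit diagonal

    def __post_init__(self):
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        k = len(self.estimates)
        if self.ses.shape != (k,) or self.rho.shape != (k, k):
            raise ValueError("inconsistent meta-analysis input shapes")
        if not np.allclose(self.rho, self.rho.T) \
                or not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("rho must be symmetric with unit diagonal")


@dataclass
class CombinedP:
    p_combined: float
    statistic: float  # sum of -2 ln p
    method: str  # "chi-square" | "empirical"


def correlated_ivw(meta: MetaInput):
    """Fixed-effect IVW meta-analysis adjusted for correlated errors.

    With error covariance Sigma_jk = rho_jk * se_j * se_k, the combined
    estimate uses weights w = Sigma^-1 1 / (1' Sigma^-1 1) and has variance
    1 / (1' Sigma^-1 1).  Returns (beta, se, z, p).
    """
    k = len(meta.estimates)
    if k < 2:
        raise ValueError("need at least 2 studies")
    sigma = meta.rho * np.outer(meta.ses, meta.ses)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rho is not positive definite") from exc
    ones = np.ones(k)
    siginv_ones = np.linalg.solve(sigma, ones)
    denom = float(ones @ siginv_ones)
    w = siginv_ones / denom
    beta = float(w @ meta.estimates)
    se = float(np.sqrt(1.0 / denom))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta, se, z, p


def empirical_fisher(p_values, null_p_matrix=None) -> CombinedP:
    """Fisher's method with an empirical null for the combined statistic.

    ``p_values``: per-study one-sided P values for one variant.
    ``null_p_matrix``: N_off x k matrix of the same studies' P values at
    off-target variants, capturing the dependence among studies; when
    absent the classical chi-square(2k) reference is used.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    T = float(np.sum(-2.0 * np.log(p)))
    if null_p_matrix is None:
        p_comb = float(stats.chi2.sf(T, df=2 * len(p)))
        return CombinedP(p_comb, T, "chi-square")
    null = np.asarray(null_p_matrix, dtype=float)
    if null.ndim != 2 or null.shape[1] != len(p):
        raise ValueError("null matrix must be N_off x k for k studies")
    if np.any(null <= 0) or np.any(null > 1):
        raise ValueError("null p values must lie in (0, 1]")
    null_T = np.sum(-2.0 * np.log(null), axis=1)
    n_off = null_T.size
    p_comb = (1.0 + int(np.sum(null_T >= T))) / (1.0 + n_off)
    return CombinedP(float(p_comb), T, "empirical")


def depletion_test(one_sided_p, alpha: float = 0.05,
                   sign_depleted_count: int | None = None,
                   n: int | None = None):
    """Binomial tests for depletion of life-shortening alleles in the old.

    ``one_sided_p`` are per-variant one-sided P values for the association
    of participant age with the life-shortening allele (small = depleted).
    The count-based test asks whether more than ``alpha`` of them fall below
    ``alpha``: P(X >= #{p < alpha}) under Binomial(n, alpha).  The optional
    sign-based test asks whether the direction of depletion alone is skewed:
    P(X >= sign_depleted_count) under Binomial(n, 1/2).  Exact tail sums.

    Returns a dict with counts and P values.
    """
    p = np.asarray(one_sided_p, dtype=float)
    n_var = p.size if n is None else int(n)
    if n_var < 1:
        raise ValueError("need n >= 1")
    count = int(np.sum(p < alpha))
    if count > n_var:
        raise ValueError("count exceeds n")
    out = {"n": n_var, "count_below": count,
           "p_count": float(stats.binom.sf(count - 1, n_var, alpha))}
    if sign_depleted_count is not None:
        if sign_depleted_count > n_var:
            raise ValueError("sign-depleted count exceeds n")
        out["sign_depleted"] = int(sign_depleted_count)
        out["p_sign"] = float(stats.binom.sf(sign_depleted_count - 1,
                                             n_var, 0.5))
    return out


def hr_to_years(hr: float, offspring_proxy: bool = False) -> float:
    """Convert a per-allele mortality hazard ratio to years of life lost.

    years = 10 * ln(HR); positive for deleterious alleles (HR > 1).  When
    the GWAS used offspring genotypes as a proxy for parental genotypes the
    observed effect is halved, so the conversion doubles it.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    years = 10.0 * np.log(hr)
    if offspring_proxy:
        years *= 2.0
    return float(years)


def transcript_mr(eqtl_effects, outcome_effects, n_eqtl: int, n_l: int,
                  min_instruments: int = 5):
    """Univariate MR of one transcript's expression on the outcome.

    Requires at least ``min_instruments`` independent eQTL instruments so
    a single pleiotropic variant cannot drive the signal.  Returns
    (alpha_hat, se, p).
    """
    x = np.asarray(eqtl_effects, dtype=float)
    y = np.asarray(outcome_effects, dtype=float)
    if x.size != y.size:
        raise ValueError("effect vectors differ in length")
    if x.size < min_instruments:
        raise InsufficientInstrumentsError(
            f"{x.size} instruments; need at least {min_instruments}")
    inst = InstrumentSet(variant_ids=[f"iv{i}" for i in range(x.size)],
                         chromosomes=np.ones(x.size, dtype=int),
                         B=x[:, None], b_y=y, trait_names=["transcript"],
                         n_t=np.array([float(n_eqtl)]), n_l=n_l)
    fit = fit_mr(inst)
    return float(fit.alpha[0]), float(fit.se[0]), float(fit.p[0])
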