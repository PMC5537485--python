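"""Gaussian Bayes-factor scan with a pooled permutation null.

For each variant the observed standardized outcome effect ``gamma_hat`` has
sampling distribution N(delta, sigma0^2) with sigma0^2 = 1/n_l.  Under the
null delta = 0; under the alternative delta is drawn from the variant's
prior N(mu, var_mu).  The Bayes factor is the ratio of the marginal
likelihood of ``gamma_hat`` under the alternative to its likelihood under
the null, which for conjugate Gaussians has the closed form

    log BF = 1/2 log(sigma0^2 / (sigma0^2 + var_mu))
             + gamma^2 / (2 sigma0^2)
             - (gamma - mu)^2 / (2 (sigma0^2 + var_mu))

Calibration is permutation-based: null Z-statistics are generated K times
for the same variants (either by regressing fresh standard-normal phenotypes
on the reference-panel dosages, or by drawing Z ~ MVN(0, C) per LD block),
null Bayes factors are computed with each variant's own prior, and the K*m
pooled null values yield an empirical P value per observed Bayes factor.
Benjamini-Hochberg on these P values controls the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ld import LDPanel
from .prior import PriorTable

__all__ = ["ScanResult", "NullBFStore", "log_bf", "generate_null",
           "null_z_replicates", "empirical_p", "bh_fdr", "error_rates",
           "genomic_lambda", "scan"]


# ---------------------------------------------------------------------------
# Bayes factor
# ---------------------------------------------------------------------------

def log_bf(gamma_hat, n_l, mu, var_mu):
    """Natural-log Bayes factor of the prior-informed alternative vs the null.

    Accepts scalars or arrays (broadcast).  ``var_mu = 0`` with ``mu = 0``
    gives log BF = 0 identically: the hypotheses coincide.
    """
    var_mu = np.asarray(var_mu, dtype=float)
    if np.any(var_mu < 0):
        raise ValueError("var_mu must be >= 0")
    n_l = np.asarray(n_l, dtype=float)
    if np.any(n_l < 1):
        raise ValueError("n_l must be >= 1")
    gamma = np.asarray(gamma_hat, dtype=float)
    mu = np.asarray(mu, dtype=float)
    s0 = 1.0 / n_l
    s1 = s0 + var_mu
    out = 0.5 * np.log(s0 / s1) + gamma ** 2 / (2 * s0) - (gamma - mu) ** 2 / (2 * s1)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Null generation
# ---------------------------------------------------------------------------

@dataclass
class NullBFStore:
    """Pooled null log Bayes factors, K replicates x m variants."""

    null_log_bf: np.ndarray  # shape (K, m)
    seed: int
    generation_mode: str  # "phenotype-permutation" | "mvn"

    def __post_init__(self):
        self.null_log_bf = np.asarray(self.null_log_bf, dtype=float)

    @property
    def K(self) -> int:
        return self.null_log_bf.shape[0]

    @property
    def m(self) -> int:
        return self.null_log_bf.shape[1]

    def pooled_sorted(self) -> np.ndarray:
        """All K*m null values, ascending (cached)."""
        if not hasattr(self, "_sorted"):
            self._sorted = np.sort(self.null_log_bf, axis=None)
        return self._sorted


def null_z_replicates(panel: LDPanel, variant_ids, K: int, seed: int,
                      mode: str = "mvn") -> np.ndarray:
    """K replicates of null Z-statistics preserving the panel's LD.

    mode="phenotype-permutation": each replicate regresses a fresh
    standard-normal phenotype (one value per panel individual) on every
    standardized dosage column; the score statistics are exactly correlated
    as the genotypes are.  mode="mvn": Z ~ MVN(0, C) drawn blockwise from
    the panel correlation (variants more than one LD block apart treated as
    independent), much faster for large K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    cols = panel.loc(np.asarray(variant_ids))
    m = len(cols)
    if mode == "phenotype-permutation":
        X = panel._centered[:, cols] / (panel._sd[cols] * np.sqrt(panel.n_ref))
        Z = np.empty((K, m))
        for k in range(K):
            y = rng.standard_normal(panel.n_ref)
            y = (y - y.mean()) / y.std()
            Z[k] = y @ X
        return Z
    if mode == "mvn":
        Z = np.empty((K, m))
        chrom = panel.variants["chr"].to_numpy()[cols]
        pos = panel.variants["pos"].to_numpy()[cols]
        for lo, hi in _ld_chunks(chrom, pos):
            C = panel.correlation_by_index(cols[lo:hi])
            L = _safe_cholesky(C)
            Z[:, lo:hi] = rng.standard_normal((K, hi - lo)) @ L.T
        return Z
    raise ValueError(f"unknown mode {mode!r}")


def _ld_chunks(chrom: np.ndarray, pos: np.ndarray, gap_bp: int = 250_000,
               max_len: int = 512):
    """Split variants into runs separated by chromosome breaks or >gap_bp."""
    m = len(chrom)
    start = 0
    for i in range(1, m + 1):
        if (i == m or chrom[i] != chrom[i - 1]
                or pos[i] - pos[i - 1] > gap_bp or i - start >= max_len):
            yield start, i
            start = i


def _safe_cholesky(C: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(8):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(len(C)))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    raise np.linalg.LinAlgError("correlation block not positive definite")


def generate_null(priors: PriorTable, panel: LDPanel, n_l: int, K: int,
                  seed: int, mode: str = "mvn") -> NullBFStore:
    """Null log Bayes factors for every prior-table variant.

    Each replicate's null Z are converted to standardized effects at the
    outcome sample size and scored with each variant's own (mu, var_mu).
    """
    Z = null_z_replicates(panel, priors.df["snp"].to_numpy(), K, seed, mode)
    gamma = Z / np.sqrt(n_l)
    nb = log_bf(gamma, n_l, priors.mu[None, :], priors.var_mu[None, :])
    return NullBFStore(nb, seed=seed, generation_mode=mode)


# ---------------------------------------------------------------------------
# Empirical P, FDR, error rates
# ---------------------------------------------------------------------------

def empirical_p(observed_log_bf: np.ndarray, null: NullBFStore) -> np.ndarray:
    """Pooled empirical P values with add-one correction.

    p_i = (1 + #{null >= observed_i}) / (1 + K*m), counting over the entire
    pooled null store.  Computed by sorting, not by a quadratic scan.
    """
    pooled = null.pooled_sorted()
    total = pooled.size
    n_ge = total - np.searchsorted(pooled, observed_log_bf, side="left")
    return (1.0 + n_ge) / (1.0 + total)


def bh_fdr(p: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up: discovery flags and monotone q-values."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


def error_rates(null: NullBFStore, log_bf_threshold: float,
                n_discoveries: int):
    """Weak-control error measures at a log-BF selection threshold.

    Returns (exceedance_rate, estimated_fdr): the pooled fraction of null
    log BFs above the threshold (per-comparison error rate), and the
    implied expected false discoveries per actual discovery.
    """
    if n_discoveries < 0:
        raise ValueError("n_discoveries must be >= 0")
    pooled = null.pooled_sorted()
    exceed = (pooled.size - np.searchsorted(pooled, log_bf_threshold,
                                            side="right")) / pooled.size
    est_fdr = null.m * exceed / max(n_discoveries, 1)
    return float(exceed), float(est_fdr)


def genomic_lambda(p=None, chi2=None) -> float:
    """Genomic inflation factor: median association chi-square over its
    null median (0.4549364)."""
    if chi2 is None:
        if p is None:
            raise ValueError("provide p or chi2")
        chi2 = stats.chi2.isf(np.asarray(p, dtype=float), df=1)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("empty input")
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# Scan driver
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Observed scan: per-variant Bayes factor, empirical P, q and flags.

    ``df`` columns: snp, chr, pos, gamma_hat, mu, var_mu, log_bf,
    p_empirical, q_bh, discovery; sorted by log_bf descending.
    """

    df: pd.DataFrame
    fdr: float
    null_K: int

    @property
    def n_discoveries(self) -> int:
        return int(self.df["discovery"].sum())


def scan(outcome, priors: PriorTable, null: NullBFStore,
         fdr: float = 0.05) -> ScanResult:
    """Score the observed outcome against the priors and the pooled null.

    ``outcome`` is a harmonized SumStatTable aligned to the prior table's
    variants (matched by snp id).
    """
    odf = outcome.df.set_index("snp")
    pdf = priors.df
    common = pdf["snp"].isin(odf.index)
    pdf = pdf[common].reset_index(drop=True)
    gamma = odf.loc[pdf["snp"], "b"].to_numpy(float)
    n_l = int(odf["n"].iloc[0])

    lbf = log_bf(gamma, n_l, pdf["mu"].to_numpy(), pdf["var_mu"].to_numpy())
    pvals = empirical_p(lbf, null)
    reject, qvals = bh_fdr(pvals, q=fdr)
    df = pd.DataFrame({"snp": pdf["snp"], "chr": pdf["chr"],
                       "pos": pdf["pos"], "gamma_hat": gamma,
                       "mu": pdf["mu"], "var_mu": pdf["var_mu"],
                       "log_bf": lbf, "p_empirical": pvals, "q_bh": qvals,
                       "discovery": reject})
    df = df.sort_values("log_bf", ascending=False, kind="mergesort")
    return ScanResult(df.reset_index(drop=True), fdr=fdr, null_K=null.K)
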