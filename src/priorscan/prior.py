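"""Per-variant priors for the outcome effect from MR causal estimates.

The prior mean for variant i is the sum over selected traits of the
variant's truncated standardized trait effect times the trait's causal
effect on the outcome:

    mu_i = sum_t b_it * alpha_t

Because the trait-effect estimates and the causal-effect estimates come
from non-overlapping data they are independent, and the exact variance of
the sum of products is

    Var(mu_i) = b_i' Cov(alpha) b_i + sum_t (alpha_t^2 + Cov(alpha)_tt) / n_t

using Var(b_it) = 1/n_t.  The sampling variance 1/n_t is retained even for
entries truncated to zero, so every variant carries a strictly positive —
if weak — prior variance.

Leave-one-chromosome-out discipline: the causal estimate used for a variant
is always the one fit without that variant's own chromosome, so the prior
is independent of the variant's observed outcome statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mr import CausalEffectEstimate
from .sumstats import SumStatTable

__all__ = ["PriorTable", "prior_mean", "prior_variance", "build_prior_table",
           "read_prior_table", "write_prior_table"]


@dataclass
class PriorTable:
    """Per-variant prior mean and variance of the standardized outcome effect.

    ``df`` columns: snp, chr, pos, mu, var_mu, traits (comma-joined names of
    traits contributing a nonzero truncated effect; empty for zero-mean
    priors).
    """

    df: pd.DataFrame

    def __post_init__(self):
        if (self.df["var_mu"] <= 0).any():
            raise ValueError("prior variance must be strictly positive")

    def __len__(self):
        return len(self.df)

    @property
    def mu(self) -> np.ndarray:
        return self.df["mu"].to_numpy()

    @property
    def var_mu(self) -> np.ndarray:
        return self.df["var_mu"].to_numpy()


def prior_mean(b_i: np.ndarray, alpha: CausalEffectEstimate) -> float:
    """Prior mean ``mu = sum_t b_it * alpha_t`` for one variant."""
    b_i = np.asarray(b_i, dtype=float)
    if b_i.shape != alpha.alpha.shape:
        raise ValueError("trait-dimension mismatch between b and alpha")
    return float(b_i @ alpha.alpha)


def prior_variance(b_i: np.ndarray, alpha: CausalEffectEstimate,
                   n_t=None) -> float:
    """Exact prior variance of ``sum_t b_t alpha_t`` with independent factors.

    ``n_t`` defaults to the sample sizes recorded in the causal estimate.
    """
    b_i = np.asarray(b_i, dtype=float)
    n_t = np.asarray(alpha.n_t if n_t is None else n_t, dtype=float)
    if b_i.shape != alpha.alpha.shape or n_t.shape != alpha.alpha.shape:
        raise ValueError("trait-dimension mismatch")
    cov = np.asarray(alpha.covariance, dtype=float)
    eig_min = float(np.linalg.eigvalsh(cov)[0])
    if eig_min < -1e-10 * max(1.0, float(np.abs(cov).max())):
        raise ValueError("covariance of alpha is not positive semi-definite")
    quad = float(b_i @ cov @ b_i)
    cross = float(np.sum((alpha.alpha ** 2 + np.diag(cov)) / n_t))
    return quad + cross


def build_prior_table(tables: list[SumStatTable], loco_fits: dict,
                      outcome_variants: pd.DataFrame,
                      p_thresh: float = 1e-5) -> PriorTable:
    """Assemble the genome-wide prior table.

    Parameters
    ----------
    tables : list of SumStatTable
        Harmonized trait studies, one per trait used in the MR fit (order
        irrelevant; matched to the fits' ``selected_traits`` by trait_name).
    loco_fits : dict chromosome -> CausalEffectEstimate
        Leave-one-chromosome-out causal fits sharing one trait set.
    outcome_variants : DataFrame
        Columns snp, chr, pos; the variants to receive priors.
    p_thresh : float
        Trait-association threshold below which a variant's trait effect
        enters its prior; weaker effects are truncated to zero.
    """
    fits = {c: f for c, f in loco_fits.items()
            if isinstance(f, CausalEffectEstimate)}
    chroms_needed = set(outcome_variants["chr"].astype(int))
    missing = chroms_needed - set(fits)
    if missing:
        raise ValueError(f"no leave-out fit for chromosome(s) {sorted(missing)}")
    trait_sets = {tuple(f.selected_traits) for f in fits.values()}
    if len(trait_sets) != 1:
        raise ValueError("leave-out fits must share a single trait set")
    traits = list(trait_sets.pop())
    by_name = {t.trait_name: t for t in tables}

    ids = pd.Index(outcome_variants["snp"])
    m = len(ids)
    T = len(traits)
    Bmat = np.zeros((m, T))
    for t, name in enumerate(traits):
        tab = by_name[name]
        idx = ids.get_indexer(tab.df["snp"])
        hit = idx >= 0
        strong = tab.df["p"].to_numpy() <= p_thresh
        keep = hit & strong
        Bmat[idx[keep], t] = tab.df["b"].to_numpy()[keep]

    chrom_arr = outcome_variants["chr"].to_numpy(int)
    mu = np.empty(m)
    var = np.empty(m)
    for chrom in np.unique(chrom_arr):
        fit = fits[chrom]
        sel = chrom_arr == chrom
        Bc = Bmat[sel]
        mu[sel] = Bc @ fit.alpha
        cov = fit.covariance
        quad = np.einsum("ij,jk,ik->i", Bc, cov, Bc)
        cross = float(np.sum((fit.alpha ** 2 + np.diag(cov)) / fit.n_t))
        var[sel] = quad + cross

    contributing = [""] * m
    for i in np.flatnonzero(Bmat.any(axis=1)):
        contributing[i] = ",".join(traits[t] for t in np.flatnonzero(Bmat[i]))
    df = pd.DataFrame({"snp": outcome_variants["snp"].to_numpy(),
                       "chr": chrom_arr,
                       "pos": outcome_variants["pos"].to_numpy(int),
                       "mu": mu, "var_mu": var, "traits": contributing})
    return PriorTable(df)


def write_prior_table(table: PriorTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_prior_table(path) -> PriorTable:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    df["traits"] = df["traits"].fillna("")
    return PriorTable(df)
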