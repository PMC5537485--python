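"""Synthetic reference panels and multi-trait GWAS summary statistics.

The generator produces the study conditions every other module is exercised
against, with fully known truth:

* a reference genotype panel whose variants sit in LD blocks — within a
  block, latent Gaussian haplotypes follow an AR1 correlation and are
  thresholded at drawn minor-allele frequencies to Hardy-Weinberg
  genotypes; blocks are independent and separated by large base-pair gaps;
* per-trait causal architectures: ``n_causal`` variants per trait receive
  Gaussian standardized effects scaled to the trait's SNP heritability;
* an outcome whose true genetic effects are the linear combination
  ``sum_t alpha_t * beta_t`` of trait effects, plus direct (pleiotropic)
  effects on a small fraction of variants;
* observed Z-statistics per study: ``sqrt(n) * (C @ beta)`` (the
  LD-convolved marginal effects) plus correlated noise drawn MVN(0, C)
  blockwise, with ``C`` the panel's empirical block correlation.

Every draw is reproducible from the config seed, and a truth record keeps
all latent effects for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .ld import LDPanel
from .sumstats import SumStatTable

__all__ = ["SimulationConfig", "TruthRecord", "simulate_panel",
           "simulate_compendium", "simulate_null_outcome"]

#: non-ambiguous allele pairs cycled across variants
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class SimulationConfig:
    """Generative settings for a synthetic panel plus GWAS compendium.

    Defaults describe the standard study conditions used throughout the
    test-suite: 20,000 variants in blocks of 10 with adjacent latent
    correlation 0.5, five traits of which three causally affect the outcome
    (alpha = 0.2, -0.1, 0, 0.05, 0), 50 causal variants and 10% SNP
    heritability per trait, and 100,000 samples per study.
    """

    m: int = 20_000
    n_ref: int = 500
    block_len: int = 10
    rho_ar1: float = 0.5
    maf_range: tuple = (0.05, 0.5)
    T: int = 5
    true_alpha: tuple = (0.2, -0.1, 0.0, 0.05, 0.0)
    h2_t: float = 0.10
    n_causal_t: int = 50
    pleiotropy_frac: float = 0.01
    h2_direct: float = 0.001
    n_t: int = 100_000
    n_l: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if min(self.m, self.n_ref, self.block_len, self.T,
               self.n_causal_t, self.n_t, self.n_l) < 1:
            raise ValueError("all counts must be positive")
        if self.m % self.block_len:
            raise ValueError("m must be a multiple of block_len")
        if not 0 <= self.rho_ar1 < 1:
            raise ValueError("rho_ar1 must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        if len(self.true_alpha) != self.T:
            raise ValueError("true_alpha length must equal T")
        if not 0 <= self.h2_t < 1:
            raise ValueError("h2_t must lie in [0, 1)")
        implied = (sum(a * a for a in self.true_alpha) * self.h2_t
                   + self.h2_direct)
        if implied > 1:
            raise ValueError(
                f"infeasible architecture: implied outcome variance {implied:.3f} > 1")

    @property
    def n_blocks(self) -> int:
        return self.m // self.block_len

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("maf_range", "true_alpha"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthRecord:
    """Latent effects behind one simulated compendium."""

    alpha: np.ndarray                 # (T,) causal trait->outcome effects
    beta_traits: np.ndarray           # (m, T) causal standardized effects
    beta_outcome: np.ndarray          # (m,) total true outcome effects
    marginal_traits: np.ndarray       # (m, T) LD-convolved trait effects
    marginal_outcome: np.ndarray      # (m,) LD-convolved outcome effects
    causal_idx: list                  # per trait, causal variant indices
    direct_idx: np.ndarray            # variants with direct outcome effects

    def causal_outcome_variants(self, tol: float = 0.0) -> np.ndarray:
        """Indices whose true marginal outcome effect exceeds ``tol``."""
        return np.flatnonzero(np.abs(self.marginal_outcome) > tol)


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

def _ar1_cholesky(block_len: int, rho: float) -> np.ndarray:
    idx = np.arange(block_len)
    C = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(C)

#: base-pair spacing inside a block and gap between blocks; the gap exceeds
#: every window default so blocks are unlinked for windowed operations too
_INTRA_BP = 1_000
_BLOCK_GAP_BP = 400_000


def _variant_frame(config: SimulationConfig) -> pd.DataFrame:
    m, L = config.m, config.block_len
    nb = config.n_blocks
    block = np.arange(m) // L
    within = np.arange(m) % L
    chrom_of_block = 1 + (np.arange(nb) * 22) // nb
    chrom = chrom_of_block[block]
    # block index within its chromosome
    first_block = np.searchsorted(chrom_of_block, chrom_of_block)
    block_in_chr = block - first_block[block]
    pos = 1 + block_in_chr * _BLOCK_GAP_BP + within * _INTRA_BP
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    return pd.DataFrame({"snp": [f"rs{i + 1}" for i in range(m)],
                         "chr": chrom.astype(int), "pos": pos.astype(int),
                         "a1": [p[0] for p in pairs],
                         "a2": [p[1] for p in pairs]})


def simulate_panel(config: SimulationConfig) -> LDPanel:
    """Draw a reference genotype panel with block-AR1 LD structure."""
    rng = np.random.default_rng(config.seed)
    m, L, nb = config.m, config.block_len, config.n_blocks
    chol = _ar1_cholesky(L, config.rho_ar1)

    maf = rng.uniform(*config.maf_range, size=m)
    tau = _norm_isf(maf)  # threshold: latent > tau carries the effect allele

    # two latent haplotypes per individual, AR1 within block
    eps = rng.standard_normal((2 * config.n_ref, nb, L))
    latent = np.einsum("kl,nbl->nbk", chol, eps).reshape(2 * config.n_ref, m)
    hap = (latent > tau).astype(np.int8)
    dosages = (hap[: config.n_ref] + hap[config.n_ref:]).astype(float)

    # thresholded draws can (very rarely) come out monomorphic; nudge one
    # genotype so every column supports a correlation
    mono = dosages.std(axis=0) == 0
    if mono.any():
        cols = np.flatnonzero(mono)
        dosages[0, cols] = np.where(dosages[0, cols] > 0,
                                    dosages[0, cols] - 1,
                                    dosages[0, cols] + 1)

    return LDPanel(_variant_frame(config), dosages)


def _norm_isf(p):
    from scipy.stats import norm
    return norm.isf(p)


# ---------------------------------------------------------------------------
# Block machinery shared by the study generators
# ---------------------------------------------------------------------------

def block_correlations(panel: LDPanel, block_len: int) -> np.ndarray:
    """Stacked empirical correlation matrices, one per LD block."""
    m = panel.m
    if m % block_len:
        raise ValueError("panel size is not a multiple of block_len")
    Xn = panel._centered / panel._sd
    Xb = Xn.reshape(panel.n_ref, m // block_len, block_len)
    C = np.einsum("nbk,nbl->bkl", Xb, Xb) / panel.n_ref
    return C


def _block_cholesky(C: np.ndarray) -> np.ndarray:
    jitter = 1e-9 * np.eye(C.shape[-1])
    try:
        return np.linalg.cholesky(C + jitter)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(C + 1e-6 * np.eye(C.shape[-1]))


def _convolve(C: np.ndarray, beta: np.ndarray, block_len: int) -> np.ndarray:
    """Marginal (LD-convolved) effects C @ beta, blockwise."""
    shape = beta.shape
    nb = shape[0] // block_len
    bb = beta.reshape(nb, block_len, -1)
    out = np.einsum("bkl,blt->bkt", C, bb)
    return out.reshape(shape)


def _noise(C_chol: np.ndarray, n_draws: int, block_len: int,
           rng) -> np.ndarray:
    nb = C_chol.shape[0]
    eps = rng.standard_normal((n_draws, nb, block_len))
    z = np.einsum("bkl,nbl->nbk", C_chol, eps)
    return z.reshape(n_draws, nb * block_len)


# ---------------------------------------------------------------------------
# Compendium
# ---------------------------------------------------------------------------

def simulate_compendium(panel: LDPanel, config: SimulationConfig,
                        rng=None):
    """Simulate trait and outcome summary statistics with known truth.

    Returns ``(trait_tables, outcome_table, truth)`` where ``trait_tables``
    is a list of T SumStatTables, ``outcome_table`` the outcome study and
    ``truth`` a TruthRecord of every latent effect.
    """
    if panel.m != config.m:
        raise ValueError("panel inconsistent with config (variant count)")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    m, T, L = config.m, config.T, config.block_len

    beta = np.zeros((m, T))
    causal_idx = []
    for t in range(T):
        idx = rng.choice(m, size=config.n_causal_t, replace=False)
        raw = rng.standard_normal(config.n_causal_t)
        if config.h2_t > 0:
            raw *= np.sqrt(config.h2_t / np.sum(raw ** 2))
        else:
            raw[:] = 0.0
        beta[idx, t] = raw
        causal_idx.append(np.sort(idx))

    alpha = np.asarray(config.true_alpha, dtype=float)
    beta_out = beta @ alpha
    n_direct = int(round(config.pleiotropy_frac * m))
    direct_idx = rng.choice(m, size=n_direct, replace=False) if n_direct \
        else np.empty(0, dtype=int)
    if n_direct:
        direct = rng.standard_normal(n_direct)
        direct *= np.sqrt(config.h2_direct / np.sum(direct ** 2))
        beta_out[direct_idx] += direct

    C = block_correlations(panel, L)
    C_chol = _block_cholesky(C)
    marg_traits = _convolve(C, beta, L)
    marg_out = _convolve(C, beta_out[:, None], L)[:, 0]

    meta = panel.variants
    tables = []
    for t in range(T):
        z = (np.sqrt(config.n_t) * marg_traits[:, t]
             + _noise(C_chol, 1, L, rng)[0])
        df = meta.copy()
        df["z"] = z
        df["n"] = config.n_t
        tables.append(SumStatTable(df, study_id=f"trait{t + 1}",
                                   trait_name=f"trait{t + 1}"))
    z_out = np.sqrt(config.n_l) * marg_out + _noise(C_chol, 1, L, rng)[0]
    df = meta.copy()
    df["z"] = z_out
    df["n"] = config.n_l
    outcome = SumStatTable(df, study_id="outcome", trait_name="outcome")

    truth = TruthRecord(alpha=alpha, beta_traits=beta, beta_outcome=beta_out,
                        marginal_traits=marg_traits, marginal_outcome=marg_out,
                        causal_idx=causal_idx, direct_idx=np.sort(direct_idx))
    return tables, outcome, truth


def simulate_null_outcome(panel: LDPanel, n_l: int, seed: int) -> SumStatTable:
    """Outcome study with no genetic effect: a fresh standard-normal
    phenotype regressed on every standardized panel dosage column.

    The resulting Z-statistics are marginally ~N(0,1) and inherit the
    panel's LD correlation.
    """
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(panel.n_ref)
    y = (y - y.mean()) / y.std()
    Xn = panel._centered / panel._sd
    z = (y @ Xn) / np.sqrt(panel.n_ref)
    df = panel.variants.copy()
    df["z"] = z
    df["n"] = n_l
    return SumStatTable(df, study_id="null-outcome", trait_name="null")
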