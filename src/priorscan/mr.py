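"""Multivariable summary-statistic Mendelian randomization.

Traits (diseases, risk factors) are the exposures; the outcome is a second
GWAS (here, parental lifespan).  Instruments are LD-pruned variants strongly
associated with at least one trait.  With standardized effects ``B`` (|S| x T,
weak entries truncated to zero) and outcome effects ``b_y`` (length |S|), the
causal effects per standard deviation of each trait are estimated by a
zero-intercept least-squares fit:

    alpha_hat = (B'B)^-1 B' b_y
    Cov(alpha_hat) = (sigma2 / n_l) (B'B)^-1,   sigma2 = RSS * n_l / (|S| - k)

where ``n_l`` is the outcome sample size and ``sigma2`` the residual variance
of the outcome on the standardized scale (close to 1 when the traits explain
little of the outcome's per-variant effect variance).  Instruments are pruned
to low mutual LD so their correlation matrix is well approximated by the
identity, which is assumed throughout.

Trait selection is bidirectional stepwise search minimizing
``AIC = |S| * ln(RSS/|S|) + 2k``, followed by backward elimination of traits
with multivariate P > 0.05, refitting after each drop.  Leave-one-chromosome-
out (LOCO) re-estimation supplies, for every chromosome, causal effects that
are independent of that chromosome's own outcome statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDPanel
from .sumstats import SumStatTable

logger = logging.getLogger("priorscan")

__all__ = ["InstrumentSet", "CausalEffectEstimate", "select_instruments",
           "fit_mr", "stepwise_select", "loco_estimates",
           "mr_residual_diagnostics", "EmptyInstrumentError",
           "CollinearityError"]


class EmptyInstrumentError(ValueError):
    """No variant passed the instrument-strength threshold."""


class CollinearityError(ValueError):
    """Rank-deficient instrument-effect matrix."""


@dataclass
class InstrumentSet:
    """LD-pruned strong instruments with truncated per-trait effects.

    ``B[i, t]`` is the standardized effect of instrument i on trait t, set
    to exactly 0 where the trait association P value exceeded the instrument
    threshold (weak-instrument truncation).  ``b_y`` holds the outcome
    effects for the same variants.
    """

    variant_ids: list
    chromosomes: np.ndarray
    B: np.ndarray
    b_y: np.ndarray
    trait_names: list
    n_t: np.ndarray
    n_l: int

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        self.b_y = np.asarray(self.b_y, dtype=float)
        self.chromosomes = np.asarray(self.chromosomes, dtype=int)
        self.n_t = np.asarray(self.n_t, dtype=float)
        if self.B.shape != (len(self.variant_ids), len(self.trait_names)):
            raise ValueError("B shape inconsistent with ids/traits")

    def __len__(self):
        return len(self.variant_ids)

    def subset(self, mask) -> "InstrumentSet":
        mask = np.asarray(mask)
        ids = [v for v, keep in zip(self.variant_ids, mask) if keep] \
            if mask.dtype == bool else [self.variant_ids[i] for i in mask]
        return InstrumentSet(ids, self.chromosomes[mask], self.B[mask],
                             self.b_y[mask], self.trait_names, self.n_t,
                             self.n_l)


@dataclass
class CausalEffectEstimate:
    """Causal effects of traits on the outcome, SD outcome per SD trait."""

    alpha: np.ndarray
    covariance: np.ndarray
    sigma2: float
    selected_traits: list
    n_t: np.ndarray
    masked_chromosome: int = 0  # 0 = no mask
    rss: float = float("nan")
    n_instruments: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def z(self) -> np.ndarray:
        return self.alpha / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        """Per-trait effects table (trait, alpha, se, z, p)."""
        return pd.DataFrame({"trait": self.selected_traits,
                             "alpha": self.alpha, "se": self.se,
                             "z": self.z, "p": self.p})


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------

def select_instruments(tables: list[SumStatTable], outcome: SumStatTable,
                       panel: LDPanel, p_thresh: float = 1e-5,
                       r2_max: float = 0.2) -> InstrumentSet:
    """Greedy LD pruning of strong instruments across all traits.

    Candidates are variants with trait association P below ``p_thresh`` for
    at least one trait (F-statistic > 10 at the default threshold),
    present in the outcome study and the panel.  Starting from the smallest
    P value overall, each chosen instrument removes every remaining
    candidate with panel r-squared above ``r2_max`` against it.  Ties in P
    are broken by (chromosome, position).
    """
    base = outcome.df[outcome.df["snp"].isin(set(panel.variants["snp"]))]
    ids = pd.Index(base["snp"])
    chrom_arr = base["chr"].to_numpy()
    pos_arr = base["pos"].to_numpy()

    T = len(tables)
    P = np.ones((len(ids), T))
    Bfull = np.zeros((len(ids), T))
    for t, tab in enumerate(tables):
        idx = ids.get_indexer(tab.df["snp"])
        hit = idx >= 0
        P[idx[hit], t] = tab.df["p"].to_numpy()[hit]
        Bfull[idx[hit], t] = tab.df["b"].to_numpy()[hit]

    pmin = P.min(axis=1)
    cand = np.flatnonzero(pmin <= p_thresh)
    if cand.size == 0:
        raise EmptyInstrumentError(
            f"no variant passes the instrument threshold P <= {p_thresh:g}")
    # global greedy order: smallest P first, ties by (chromosome, position)
    order = cand[np.lexsort((pos_arr[cand], chrom_arr[cand], pmin[cand]))]

    # LD is confined within chromosomes, so correlations are only checked
    # among same-chromosome candidates (precomputed per chromosome)
    corr_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    alive = dict.fromkeys(order.tolist(), True)
    kept_idx = []
    for i in order:
        if not alive[i]:
            continue
        kept_idx.append(i)
        alive[i] = False
        chrom = chrom_arr[i]
        if chrom not in corr_cache:
            members = order[chrom_arr[order] == chrom]
            cols = panel.loc(ids[members])
            r2 = panel.correlation_by_index(cols) ** 2
            corr_cache[chrom] = (members, {m: k for k, m in enumerate(members)},
                                 r2)
        members, member_pos, r2 = corr_cache[chrom]
        row = r2[member_pos[i]]
        for j, r2v in zip(members, row):
            if alive.get(j, False) and r2v > r2_max:
                alive[j] = False

    kept_idx = sorted(kept_idx, key=lambda i: (chrom_arr[i], pos_arr[i]))
    kept_idx = np.asarray(kept_idx)
    kept = list(ids[kept_idx])
    B = np.where(P[kept_idx] <= p_thresh, Bfull[kept_idx], 0.0)
    b_y = base["b"].to_numpy()[kept_idx]
    n_l = int(base["n"].iloc[0])
    n_t = np.array([tab.df["n"].iloc[0] for tab in tables], dtype=float)
    logger.info("select_instruments: %d candidates -> %d pruned instruments",
                cand.size, len(kept))
    return InstrumentSet(kept, chrom_arr[kept_idx], B, b_y,
                         [tab.trait_name for tab in tables], n_t, n_l)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_mr(inst: InstrumentSet, trait_subset=None,
           masked_chromosome: int = 0) -> CausalEffectEstimate:
    """Zero-intercept least-squares fit of outcome effects on trait effects."""
    if trait_subset is None:
        trait_subset = list(inst.trait_names)
    tidx = [inst.trait_names.index(t) for t in trait_subset]
    B = inst.B[:, tidx]
    b_y = inst.b_y
    s, k = B.shape
    if s <= k:
        raise ValueError(f"need more instruments ({s}) than traits ({k})")

    rank = np.linalg.matrix_rank(B)
    if rank < k:
        # identify columns that add no rank, in order
        offenders = []
        r_prev = 0
        for j in range(k):
            r_now = np.linalg.matrix_rank(B[:, :j + 1])
            if r_now == r_prev:
                offenders.append(trait_subset[j])
            r_prev = r_now
        raise CollinearityError(
            f"collinear trait effects: {', '.join(offenders)}")

    alpha, _, _, _ = np.linalg.lstsq(B, b_y, rcond=None)
    resid = b_y - B @ alpha
    rss = float(resid @ resid)
    sigma2 = rss * inst.n_l / (s - k)
    btb_inv = np.linalg.inv(B.T @ B)
    cov = (sigma2 / inst.n_l) * btb_inv
    return CausalEffectEstimate(alpha=alpha, covariance=cov, sigma2=sigma2,
                                selected_traits=list(trait_subset),
                                n_t=inst.n_t[tidx],
                                masked_chromosome=masked_chromosome,
                                rss=rss, n_instruments=s)


def _aic(inst: InstrumentSet, subset) -> float:
    fit = fit_mr(inst, subset)
    s = fit.n_instruments
    return s * np.log(fit.rss / s) + 2 * len(subset)


def stepwise_select(inst: InstrumentSet,
                    p_drop: float = 0.05) -> CausalEffectEstimate:
    """Bidirectional stepwise trait selection, then backward P-value pruning.

    Starting from the empty trait set, traits are added or removed one at a
    time to minimize AIC of the zero-intercept regression until no move
    improves it.  Among the AIC-selected traits, the trait with the largest
    multivariate P value is then dropped (refitting each time) while any
    P exceeds ``p_drop``.
    """
    all_traits = list(inst.trait_names)
    current: list = []
    # RSS of the empty (null) model: predictions identically zero
    s = len(inst)
    current_aic = s * np.log(float(inst.b_y @ inst.b_y) / s)

    improved = True
    while improved:
        improved = False
        best_move, best_aic = None, current_aic
        for t in all_traits:
            trial = current + [t] if t not in current \
                else [x for x in current if x != t]
            if not trial:
                trial_aic = s * np.log(float(inst.b_y @ inst.b_y) / s)
            else:
                try:
                    trial_aic = _aic(inst, trial)
                except (CollinearityError, ValueError):
                    continue
            if trial_aic < best_aic - 1e-12:
                best_move, best_aic = trial, trial_aic
        if best_move is not None:
            current, current_aic = best_move, best_aic
            improved = True

    if not current:
        raise EmptyInstrumentError("stepwise selection retained no trait")

    fit = fit_mr(inst, current)
    while len(fit.selected_traits) > 1 and fit.p.max() > p_drop:
        worst = fit.selected_traits[int(np.argmax(fit.p))]
        current = [t for t in current if t != worst]
        fit = fit_mr(inst, current)
    if len(fit.selected_traits) == 1 and fit.p.max() > p_drop:
        logger.warning("stepwise_select: last remaining trait %s has P=%.3g",
                       fit.selected_traits[0], fit.p[0])
    logger.info("stepwise_select: retained traits %s", fit.selected_traits)
    return fit


def loco_estimates(inst: InstrumentSet, trait_subset=None) -> dict:
    """Leave-one-chromosome-out causal-effect estimates.

    Returns a dict mapping chromosome (1-22) to a CausalEffectEstimate fit
    on instruments excluding that chromosome, with the trait set fixed to
    ``trait_subset`` (default: all traits of ``inst``).  A mask leaving too
    few instruments maps to the error raised for it; other chromosomes are
    still estimated.
    """
    if len(set(inst.chromosomes)) < 2:
        raise ValueError("instruments must span at least 2 chromosomes")
    out = {}
    for chrom in range(1, 23):
        mask = inst.chromosomes != chrom
        try:
            fit = fit_mr(inst.subset(mask), trait_subset,
                         masked_chromosome=chrom)
        except (ValueError, CollinearityError) as exc:
            fit = exc
        out[chrom] = fit
    return out


def mr_residual_diagnostics(fit: CausalEffectEstimate, inst: InstrumentSet,
                            flag_threshold: float = 4.0) -> pd.DataFrame:
    """Standardized MR residuals per instrument.

    Residuals are standardized by sqrt(sigma2 / n_l), the model's residual
    SD on the standardized-effect scale.  Instruments with absolute
    standardized residual above ``flag_threshold`` indicate possible
    pleiotropy (a direct outcome effect not mediated by the traits).
    """
    tidx = [inst.trait_names.index(t) for t in fit.selected_traits]
    resid = inst.b_y - inst.B[:, tidx] @ fit.alpha
    scale = np.sqrt(fit.sigma2 / inst.n_l)
    std = resid / scale if scale > 0 else np.zeros_like(resid)
    return pd.DataFrame({"snp": inst.variant_ids,
                         "chr": inst.chromosomes,
                         "residual": resid,
                         "std_residual": std,
                         "flagged": np.abs(std) > flag_threshold})
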