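"""LD reference panels and conditional-Gaussian Z-statistic imputation.

Under the null, GWAS Z-statistics of nearby variants are correlated with the
same correlation structure as the genotypes themselves.  Given observed
Z-statistics ``w`` at a set M of variants and a reference panel supplying the
genotype correlations, an unobserved Z is imputed by the conditional mean of
a multivariate normal:

    z_hat   = c' (C + lambda I)^-1 w
    r2pred  = c' (C + lambda I)^-1 c

where ``C`` is the correlation matrix among the observed variants, ``c`` the
correlation vector between the target and the observed set, and ``lambda`` a
ridge term that keeps ``C`` invertible when the window holds more variants
than the panel has individuals.  ``r2pred`` is the usual imputation-quality
measure (the fraction of the target Z's variance explained).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SumStatTable, p_from_z, standardized_effect

__all__ = ["LDPanel", "ImputedZ", "impute_z", "impute_table",
           "read_panel", "write_panel", "DegenerateVariantError"]


class DegenerateVariantError(ValueError):
    """Correlation requested for a monomorphic variant."""


@dataclass
class ImputedZ:
    variant_id: str
    z_imputed: float
    r2pred: float


class LDPanel:
    """Reference genotype dosages with on-demand variant-variant correlation.

    Parameters
    ----------
    variants : DataFrame
        Columns snp, chr, pos, a1, a2; one row per variant, sorted by
        (chr, pos).
    dosages : ndarray, shape (n_ref, m)
        Allele counts in [0, 2], column j for variants row j.
    """

    def __init__(self, variants: pd.DataFrame, dosages: np.ndarray):
        variants = variants.reset_index(drop=True)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape[1] != len(variants):
            raise ValueError("dosages must be n_ref x m matching variants")
        if dosages.min() < 0 or dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        self.variants = variants
        self.dosages = dosages
        self.n_ref = dosages.shape[0]
        self._index = pd.Index(variants["snp"])
        sd = dosages.std(axis=0)
        #: monomorphic columns are flagged and excluded from correlation queries
        self.monomorphic = sd == 0.0
        self._sd = np.where(self.monomorphic, np.nan, sd)
        self._centered = dosages - dosages.mean(axis=0)

    @property
    def m(self) -> int:
        return len(self.variants)

    def __contains__(self, variant_id) -> bool:
        return variant_id in self._index

    def loc(self, variant_ids) -> np.ndarray:
        """Column indices for the given variant ids (raises on absence)."""
        idx = self._index.get_indexer(np.atleast_1d(variant_ids))
        if (idx < 0).any():
            missing = np.atleast_1d(variant_ids)[idx < 0][0]
            raise KeyError(f"variant {missing!r} not in panel")
        return idx

    def correlation(self, ids_a, ids_b=None) -> np.ndarray:
        """Pearson correlation block between two sets of panel variants."""
        ia = self.loc(ids_a)
        ib = ia if ids_b is None else self.loc(ids_b)
        return self.correlation_by_index(ia, ib)

    def correlation_by_index(self, ia, ib=None) -> np.ndarray:
        ia = np.atleast_1d(ia)
        ib = ia if ib is None else np.atleast_1d(ib)
        for idx in (ia, ib):
            if self.monomorphic[idx].any():
                bad = self.variants["snp"].iloc[idx[self.monomorphic[idx]][0]]
                raise DegenerateVariantError(
                    f"monomorphic variant {bad!r} has no defined correlation")
        xa = self._centered[:, ia]
        xb = self._centered[:, ib]
        r = (xa.T @ xb) / self.n_ref / np.outer(self._sd[ia], self._sd[ib])
        return np.clip(r, -1.0, 1.0)

    def default_ridge(self) -> float:
        """Default diagonal regularization, 2 / sqrt(n_ref)."""
        return 2.0 / np.sqrt(self.n_ref)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_z(target: str, observed: SumStatTable, panel: LDPanel,
             ridge: float = 0.0) -> ImputedZ:
    """Impute one Z-statistic from an observed window by the conditional rule.

    With ``ridge == 0`` and the target itself in the observed set this
    returns the observed z exactly (self-imputation identity).
    """
    if len(observed) == 0:
        raise ValueError("observed window M is empty")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    obs_ids = observed.df["snp"].to_numpy()
    it = panel.loc(target)
    io = panel.loc(obs_ids)
    chroms = set(panel.variants["chr"].iloc[io]) | set(panel.variants["chr"].iloc[it])
    if len(chroms) > 1:
        raise ValueError("target and observed set must share a chromosome")

    C = panel.correlation_by_index(io)
    c = panel.correlation_by_index(io, it)[:, 0]
    w = observed.df["z"].to_numpy()
    A = C + ridge * np.eye(len(C))
    try:
        solved = np.linalg.solve(A, np.column_stack([w, c]))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular LD matrix; use ridge > 0 (e.g. panel.default_ridge())"
        ) from exc
    z_hat = float(c @ solved[:, 0])
    r2 = float(c @ solved[:, 1])
    return ImputedZ(str(target), z_hat, r2)


def impute_table(targets: pd.DataFrame, observed: SumStatTable,
                 panel: LDPanel, window_bp: int = 250_000,
                 ridge: float | None = None,
                 min_r2pred: float = 0.3) -> SumStatTable:
    """Impute Z-statistics for every target variant not already observed.

    ``targets`` is a DataFrame with columns snp, chr, pos, a1, a2 (typically
    ``panel.variants`` or a subset).  Observed variants pass through
    unchanged; unobserved targets are imputed from observed variants within
    ``window_bp`` of their position on the same chromosome.  Targets with
    ``r2pred < min_r2pred`` (or with an empty window) are omitted from the
    output, i.e. marked missing.

    The imputed table inherits the observed study's sample size; imputed
    rows carry their ``r2pred`` in an extra column.
    """
    if ridge is None:
        ridge = panel.default_ridge()
    obs_df = observed.df
    obs_ids = set(obs_df["snp"])
    n_default = int(obs_df["n"].iloc[0]) if len(obs_df) else observed.n_default

    rows = []
    r2s = []
    for chrom, tchunk in targets.groupby("chr"):
        ochunk = obs_df[obs_df["chr"] == chrom]
        opos = ochunk["pos"].to_numpy()
        for row in tchunk.itertuples(index=False):
            if row.snp in obs_ids:
                continue
            lo = np.searchsorted(opos, row.pos - window_bp, side="left")
            hi = np.searchsorted(opos, row.pos + window_bp, side="right")
            if hi <= lo:
                continue
            window = SumStatTable(ochunk.iloc[lo:hi].copy(),
                                  observed.study_id, observed.trait_name)
            imp = impute_z(row.snp, window, panel, ridge=ridge)
            if imp.r2pred < min_r2pred:
                continue
            rows.append({"snp": row.snp, "chr": row.chr, "pos": row.pos,
                         "a1": row.a1, "a2": row.a2, "z": imp.z_imputed,
                         "n": n_default})
            r2s.append(imp.r2pred)

    passthrough = obs_df[obs_df["snp"].isin(set(targets["snp"]))].copy()
    passthrough["r2pred"] = 1.0
    if rows:
        new = pd.DataFrame(rows)
        new["p"] = p_from_z(new["z"].to_numpy())
        new["b"] = standardized_effect(new["z"].to_numpy(), new["n"].to_numpy())
        new["r2pred"] = r2s
        combined = pd.concat([passthrough, new], ignore_index=True)
    else:
        combined = passthrough
    out = SumStatTable(combined[[c for c in combined.columns if c != "r2pred"]],
                       observed.study_id, observed.trait_name,
                       n_default=n_default)
    r2map = dict(zip(combined["snp"], combined["r2pred"]))
    out.df["r2pred"] = out.df["snp"].map(r2map)
    return out


# ---------------------------------------------------------------------------
# Panel I/O (plain tab-separated dosage matrix)
# ---------------------------------------------------------------------------

def read_panel(path) -> LDPanel:
    """Read a tab-separated panel: snp, chr, pos, a1, a2, then one dosage
    column per reference individual."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    meta = df[["snp", "chr", "pos", "a1", "a2"]]
    dosages = df.drop(columns=["snp", "chr", "pos", "a1", "a2"]).to_numpy(float).T
    return LDPanel(meta, dosages)


def write_panel(panel: LDPanel, path) -> None:
    dose = pd.DataFrame(panel.dosages.T,
                        columns=[f"ind{i}" for i in range(panel.n_ref)])
    df = pd.concat([panel.variants.reset_index(drop=True), dose], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
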