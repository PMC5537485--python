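"""GWAS summary-statistic tables: reading, writing, allele harmonization.

A summary-statistic table carries, per variant, the association Z-statistic
``z``, its two-sided P value ``p``, the study sample size ``n`` and the
standardized effect ``b = z / sqrt(n)`` (effect of one allele, in phenotype
standard deviations, when both genotype and phenotype have unit variance).
All downstream modules (summary-statistic imputation, multivariable MR,
prior construction, the Bayes-factor scan) consume these tables.

Files are tab-separated with a header row.  The minimal column set is
``snp, chr, pos, a1, a2`` (``a1`` is the effect allele) plus one of

* ``z`` — the Z-statistic directly,
* ``beta, se`` — an effect estimate and its standard error (z = beta/se),
* ``p, dir`` — a two-sided P value and an effect direction (``+``/``-``),

and optionally ``n``.  Missing sample sizes fall back to a caller-supplied
default.  Only autosomal biallelic SNVs (chromosomes 1-22, single-base
alleles) are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("priorscan")

VALID_ALLELES = frozenset("ACGT")

#: Strand-ambiguous allele pairs: complement of one allele equals the other,
#: so strand cannot be resolved from the alleles alone.
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order of the on-disk dialect.
COLUMNS = ["snp", "chr", "pos", "a1", "a2", "z", "p", "n", "b"]


class SumStatError(ValueError):
    """Malformed or inconsistent summary-statistic input."""


# ---------------------------------------------------------------------------
# Z / P / standardized-effect arithmetic
# ---------------------------------------------------------------------------

def z_from_p_and_direction(p, direction):
    """Recover a Z-statistic from a two-sided P value and an effect direction.

    Parameters
    ----------
    p : float or array-like
        Two-sided P value in (0, 1].
    direction : int or array-like
        Sign of the effect, +1 or -1 (the sign of beta, or of log odds
        ratio for binary traits).

    Returns
    -------
    z : float or ndarray
        Z-statistic with ``2 * Phi(-|z|) = p`` and ``sign(z) = direction``.
    """
    p_arr = np.asarray(p, dtype=float)
    d_arr = np.sign(np.asarray(direction, dtype=float))
    if np.any(~np.isfinite(p_arr)) or np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise SumStatError("p values must lie in (0, 1]")
    z = d_arr * stats.norm.isf(p_arr / 2.0)
    if np.ndim(p) == 0 and np.ndim(direction) == 0:
        return float(z)
    return z


def p_from_z(z):
    """Two-sided normal P value, ``p = 2 * Phi(-|z|)``."""
    z_arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z_arr)):
        raise SumStatError("z must be finite")
    p = 2.0 * stats.norm.sf(np.abs(z_arr))
    return float(p) if np.ndim(z) == 0 else p


def standardized_effect(z, n):
    """Standardized per-allele effect ``b = z / sqrt(n)``.

    With genotype and phenotype standardized to unit variance the sampling
    variance of ``b`` is 1/n, so ``z = b * sqrt(n)``.
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise SumStatError("sample size n must be >= 1")
    b = np.asarray(z, dtype=float) / np.sqrt(n_arr)
    if np.ndim(z) == 0 and np.ndim(n) == 0:
        return float(b)
    return b


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass
class SumStatTable:
    """Per-variant association summary statistics for one study.

    ``df`` holds one row per variant with the canonical columns
    ``snp, chr, pos, a1, a2, z, p, n, b`` sorted by (chr, pos); ``snp``
    values are unique.
    """

    df: pd.DataFrame
    study_id: str = ""
    trait_name: str = ""
    n_default: int | None = None

    def __post_init__(self):
        self.df = _normalize_frame(self.df, self.n_default)

    def __len__(self):
        return len(self.df)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.df["snp"])

    def restrict(self, variant_ids) -> "SumStatTable":
        """Subset to the given variants (order re-sorted by position)."""
        sub = self.df[self.df["snp"].isin(set(variant_ids))]
        return SumStatTable(sub.copy(), self.study_id, self.trait_name)


def _normalize_frame(df: pd.DataFrame, n_default=None) -> pd.DataFrame:
    df = df.copy()
    required = ["snp", "a1", "a2"]
    for col in required:
        if col not in df.columns:
            raise SumStatError(f"missing required column {col!r}")
    if "chr" not in df.columns:
        raise SumStatError("missing required column 'chr'")
    if "pos" not in df.columns:
        raise SumStatError("missing required column 'pos'")

    df["chr"] = df["chr"].astype(int)
    df["pos"] = df["pos"].astype(int)
    if (df["chr"] < 1).any() or (df["chr"] > 22).any():
        raise SumStatError("chromosomes must be autosomes 1-22")

    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()
        bad = ~df[col].isin(VALID_ALLELES)
        if bad.any():
            raise SumStatError(f"invalid allele in column {col}: "
                               f"{df.loc[bad, col].iloc[0]!r}")
    if (df["a1"] == df["a2"]).any():
        raise SumStatError("effect allele equals other allele")

    # derive z from whatever statistic columns are present
    if "z" not in df.columns:
        if "beta" in df.columns and "se" in df.columns:
            df["z"] = df["beta"].astype(float) / df["se"].astype(float)
        elif "p" in df.columns and "dir" in df.columns:
            direction = df["dir"].map(_parse_direction)
            df["z"] = z_from_p_and_direction(df["p"].astype(float).to_numpy(),
                                             direction.to_numpy())
        else:
            raise SumStatError(
                "no usable statistic column: need z, beta+se, or p+dir")
    df["z"] = df["z"].astype(float)

    if "n" not in df.columns or (len(df) and df["n"].isna().all()):
        if n_default is None:
            raise SumStatError("no sample-size column and no n_default given")
        df["n"] = n_default
    elif df["n"].isna().any():
        if n_default is None:
            raise SumStatError("missing sample sizes and no n_default given")
        df["n"] = df["n"].fillna(n_default)
    df["n"] = df["n"].astype(int)

    # keep a provided P (it round-trips exactly) after checking it against
    # z; otherwise derive it
    p_check = p_from_z(df["z"].to_numpy())
    if "p" in df.columns and len(df):
        p_given = df["p"].astype(float).to_numpy()
        bad = np.abs(p_given - p_check) > 1e-4 * np.maximum(p_check, 1e-300)
        if bad.any():
            raise SumStatError(
                f"p inconsistent with z for {df['snp'].to_numpy()[bad][0]}")
        df["p"] = p_given
    else:
        df["p"] = p_check
    df["b"] = standardized_effect(df["z"].to_numpy(), df["n"].to_numpy())

    dup = df["snp"].duplicated()
    if dup.any():
        raise SumStatError(f"duplicated variant_id: {df.loc[dup, 'snp'].iloc[0]}")

    df = df[COLUMNS].sort_values(["chr", "pos"], kind="mergesort")
    return df.reset_index(drop=True)


def _parse_direction(d) -> float:
    s = str(d).strip()
    if s in ("+", "1", "+1"):
        return 1.0
    if s in ("-", "−", "-1"):
        return -1.0
    raise SumStatError(f"unparseable direction {d!r}")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def harmonize(study: SumStatTable, reference) -> SumStatTable:
    """Orient a study's effect alleles to a reference allele frame.

    For each variant shared with the reference: records already in the
    reference orientation pass through; records with effect/other alleles
    swapped have z, b negated and alleles swapped; strand-ambiguous pairs
    (A/T, C/G) are dropped, as are variants absent from the reference or
    with irreconcilable alleles.  Strand flips (A/G recorded as T/C) are
    resolved by complementing before matching.

    ``reference`` may be a SumStatTable or any object exposing a ``variants``
    DataFrame with columns snp, a1, a2 (e.g. an LD panel).
    """
    ref_df = reference.df if isinstance(reference, SumStatTable) else reference.variants
    ref = ref_df.set_index("snp")[["a1", "a2"]]

    df = study.df
    counts = {"kept": 0, "flipped": 0, "ambiguous": 0,
              "absent": 0, "irreconcilable": 0}

    in_ref = df["snp"].isin(ref.index)
    counts["absent"] = int((~in_ref).sum())
    df = df[in_ref].copy()

    amb = [(a, b) in AMBIGUOUS_PAIRS for a, b in zip(df["a1"], df["a2"])]
    amb = np.asarray(amb, dtype=bool)
    counts["ambiguous"] = int(amb.sum())
    df = df[~amb]

    ra1 = ref.loc[df["snp"], "a1"].to_numpy()
    ra2 = ref.loc[df["snp"], "a2"].to_numpy()
    a1 = df["a1"].to_numpy()
    a2 = df["a2"].to_numpy()
    ca1 = np.array([_COMPLEMENT[a] for a in a1])
    ca2 = np.array([_COMPLEMENT[a] for a in a2])

    same = ((a1 == ra1) & (a2 == ra2)) | ((ca1 == ra1) & (ca2 == ra2))
    swapped = ((a1 == ra2) & (a2 == ra1)) | ((ca1 == ra2) & (ca2 == ra1))
    swapped &= ~same
    bad = ~(same | swapped)
    counts["irreconcilable"] = int(bad.sum())
    if bad.any():
        logger.warning("harmonize: dropping %d variants with irreconcilable "
                       "alleles (e.g. %s)", bad.sum(), df["snp"].to_numpy()[bad][0])
    df = df[~bad].copy()
    swapped = swapped[~bad]

    df.loc[swapped, ["z", "b"]] *= -1.0
    df.loc[:, "a1"] = ref.loc[df["snp"], "a1"].to_numpy()
    df.loc[:, "a2"] = ref.loc[df["snp"], "a2"].to_numpy()
    df.loc[:, "p"] = p_from_z(df["z"].to_numpy())

    counts["flipped"] = int(swapped.sum())
    counts["kept"] = int(len(df)) - counts["flipped"]
    logger.info("harmonize[%s]: %s", study.study_id or study.trait_name, counts)

    out = SumStatTable(df, study.study_id, study.trait_name)
    out.harmonize_counts = counts
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sumstats(path, column_map=None, n_default=None,
                  study_id="", trait_name="") -> SumStatTable:
    """Read a tab-separated summary-statistic file.

    ``column_map`` renames file columns to the canonical names, e.g.
    ``{"rsid": "snp", "pval": "p"}``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    if column_map:
        df = df.rename(columns=column_map)
    return SumStatTable(df, study_id=study_id, trait_name=trait_name,
                        n_default=n_default)


def write_sumstats(table: SumStatTable, path) -> None:
    """Write the canonical dialect; floats carry 10 significant digits."""
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")
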