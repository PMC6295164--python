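"""Chromosome copy-number interaction (CCNI) scoring from colony sizes.

Double-disomic strains are constructed in two marker orientations (each
chromosome of a pair can carry either selection-marker set), giving a
row-chromosome x column-chromosome matrix of mean colony sizes. Row and
column effects capture the single-disome fitness costs and marker effects;
what remains after removing them is the pairwise interaction. A relative
fitness below 1 is a negative interaction (the double disome grows worse
than expected from the single disomes), above 1 a positive one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cooccurrence import CorrelationMatrix

__all__ = [
    "normalize_colony_matrix",
    "ccni_scores",
    "correlate_ccni_with_cooccurrence",
    "read_colony_matrix",
]


def normalize_colony_matrix(matrix: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """Remove row and column effects from a colony-size matrix.

    ``rel[a][b] = M[a][b] * G / (R_a * C_b)`` where ``R_a`` and ``C_b`` are
    the mean (default), median or geometric mean of the present cells in
    row ``a`` / column ``b`` and ``G`` is the same statistic over all
    present cells. Every variant is exact on interaction-free (rank-1
    multiplicative) complete matrices: any matrix of the form ``r_a * c_b``
    maps to all ones. The geometric variant is additionally exactly
    invariant to rescaling a single row or column of any complete matrix
    (arithmetic means are only first-order invariant once interactions are
    present). Missing cells stay missing.
    """
    if stat not in ("mean", "median", "geometric"):
        raise ValueError("stat must be 'mean', 'median' or 'geometric'")
    M = matrix.to_numpy(dtype=float)
    present = ~np.isnan(M)
    for axis, labels, what in ((1, matrix.index, "row"), (0, matrix.columns, "column")):
        counts = present.sum(axis=axis)
        for label, cnt in zip(labels, counts):
            if cnt == 0:
                raise ValueError(f"{what} {label!r} has no measured colony sizes")
    if np.nanmin(M) <= 0:
        raise ValueError("colony sizes must be positive")
    if stat == "mean":
        agg = np.nanmean
    elif stat == "median":
        agg = np.nanmedian
    else:
        def agg(x, axis=None):
            return np.exp(np.nanmean(np.log(x), axis=axis))
    row_eff = agg(M, axis=1)
    col_eff = agg(M, axis=0)
    grand = agg(M)
    rel = M * grand / np.outer(row_eff, col_eff)
    return pd.DataFrame(rel, index=matrix.index, columns=matrix.columns)


def ccni_scores(rel: pd.DataFrame) -> pd.DataFrame:
    """Per-pair interaction scores from a relative-fitness matrix.

    For each unordered chromosome pair {a, b} with at least one measured
    orientation, the score is the mean of ``rel[a][b]`` and ``rel[b][a]``
    (the two marker orientations); single-orientation pairs are flagged.
    Scores < 1 indicate negative interactions, > 1 positive.
    """
    chroms = list(dict.fromkeys(list(rel.index) + list(rel.columns)))
    rows = []
    for i, a in enumerate(chroms):
        for b in chroms[i + 1:]:
            vals = []
            ab = rel.loc[a, b] if (a in rel.index and b in rel.columns) else np.nan
            ba = rel.loc[b, a] if (b in rel.index and a in rel.columns) else np.nan
            for v in (ab, ba):
                if not np.isnan(v):
                    vals.append(float(v))
            if not vals:
                continue
            rows.append((a, b, float(np.mean(vals)),
                         float(ab) if not np.isnan(ab) else np.nan,
                         float(ba) if not np.isnan(ba) else np.nan,
                         len(vals) == 1))
    return pd.DataFrame(
        rows,
        columns=["chrom_a", "chrom_b", "score", "value_ab", "value_ba",
                 "single_orientation"],
    )


def correlate_ccni_with_cooccurrence(
    scores: pd.DataFrame,
    corr: CorrelationMatrix | pd.DataFrame,
) -> tuple[float, float]:
    """Pearson correlation between engineered-pair CCNI scores and cohort
    copy-number correlation coefficients over the shared chromosome pairs.

    Returns ``(r, p)`` with the two-tailed p-value from the t distribution
    with ``n_pairs - 2`` degrees of freedom. Requires >= 3 shared pairs.
    """
    r_matrix = corr.r if isinstance(corr, CorrelationMatrix) else corr
    xs, ys = [], []
    for _, row in scores.iterrows():
        a, b = row["chrom_a"], row["chrom_b"]
        if a in r_matrix.index and b in r_matrix.columns:
            r_ab = r_matrix.loc[a, b]
            if not np.isnan(r_ab):
                xs.append(row["score"])
                ys.append(float(r_ab))
    if len(xs) < 3:
        raise ValueError(f"need >= 3 shared pairs, got {len(xs)}")
    result = stats.pearsonr(xs, ys)
    return float(result.statistic), float(result.pvalue)


def read_colony_matrix(path) -> pd.DataFrame:
    """Read a colony-size matrix TSV (first column = row chromosome labels;
    blank cells = missing)."""
    return pd.read_csv(path, sep="\t", index_col=0)
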