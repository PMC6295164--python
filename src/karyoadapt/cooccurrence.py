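"""Cohort-level karyotype statistics.

Given a strains x chromosomes matrix of copy numbers (continuous estimates
or integer calls), this module computes per-chromosome aneuploidy
frequencies, DNA-content-change burden, pooled karyotype standard
deviation, pairwise Pearson correlations between chromosome copy numbers,
and the significance of event co-occurrence / mutual exclusivity by the
hypergeometric point probability — the statistic used to flag chromosome
copy-number interaction (CCNI) patterns in adapted CIN cohorts.

Events are direction-specific: a gain and a loss of the same chromosome
are distinct events. Haploid cohorts use gain-only events by default
(chromosome loss is lethal in haploids); diploid cohorts use both.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .genome import GenomeBuild, round_to_integer_copy

__all__ = [
    "binarize_matrix",
    "aneuploidy_frequency",
    "dna_content_change",
    "dna_content_change_matrix",
    "hypergeometric_point",
    "hypergeometric_tail",
    "event_matrix",
    "pairwise_cooccurrence",
    "CorrelationMatrix",
    "copy_correlation_matrix",
    "karyotype_pooled_sd",
    "GAIN",
    "LOSS",
]

GAIN = "+"
LOSS = "-"


def binarize_matrix(matrix: pd.DataFrame, ploidy: int) -> pd.DataFrame:
    """Round a continuous strains x chromosomes copy matrix to integer calls
    (ties at .5 away from the basal ploidy)."""
    values = round_to_integer_copy(matrix.to_numpy(dtype=float), ploidy)
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def aneuploidy_frequency(calls: pd.DataFrame, ploidy: int) -> pd.DataFrame:
    """Per-chromosome fraction of aneuploid strains.

    Parameters
    ----------
    calls
        Integer strains x chromosomes call matrix.
    ploidy
        Basal ploidy against which aneuploidy is defined.

    Returns a DataFrame indexed by chromosome with columns ``frequency``,
    ``gain_frequency`` and ``loss_frequency``.
    """
    if len(calls) < 1:
        raise ValueError("need at least one strain")
    values = calls.to_numpy()
    n = len(calls)
    return pd.DataFrame(
        {
            "frequency": (values != ploidy).mean(axis=0),
            "gain_frequency": (values > ploidy).mean(axis=0),
            "loss_frequency": (values < ploidy).mean(axis=0),
        },
        index=calls.columns,
    )


def dna_content_change(calls, genome: GenomeBuild, ploidy: int | None = None) -> float:
    """Ploidy-normalized DNA-content-change burden, in percent.

    ``100 * sum_i |c_i - p| * f_i / p`` where ``c_i`` is the integer copy
    call, ``p`` the basal ploidy and ``f_i`` the fraction of the genome on
    chromosome ``i``. For a haploid with no losses this reduces to the
    signed sum of ``(c_i - 1) * f_i``.
    """
    if ploidy is None:
        ploidy = genome.basal_ploidy
    if isinstance(calls, pd.Series):
        calls = calls.reindex(genome.names)
        if calls.isna().any():
            missing = calls.index[calls.isna()].tolist()
            raise ValueError(f"calls missing for chromosome(s): {missing}")
        c = calls.to_numpy(dtype=float)
    else:
        c = np.asarray(calls, dtype=float)
        if c.shape[-1] != len(genome.names):
            raise ValueError("calls and genome must share chromosomes")
    return float(100.0 * np.sum(np.abs(c - ploidy) * genome.fractions) / ploidy)


def dna_content_change_matrix(calls: pd.DataFrame, genome: GenomeBuild,
                              ploidy: int | None = None) -> pd.Series:
    """Per-strain DNA-content-change burden (percent) for a call matrix."""
    if ploidy is None:
        ploidy = genome.basal_ploidy
    mat = calls.reindex(columns=genome.names).to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("call matrix does not cover every genome chromosome")
    burden = 100.0 * (np.abs(mat - ploidy) @ genome.fractions) / ploidy
    return pd.Series(burden, index=calls.index, name="dna_content_change_pct")


def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _check_hypergeom_support(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"K and n must lie in [0, N]: N={N}, K={K}, n={n}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"k={k} outside hypergeometric support "
            f"[{max(0, K + n - N)}, {min(K, n)}] for N={N}, K={K}, n={n}"
        )


def hypergeometric_point(N: int, K: int, n: int, k: int) -> float:
    """Exact hypergeometric point probability P(X = k).

    ``X`` is the overlap between a fixed subset of size ``K`` and a random
    subset of size ``n`` drawn without replacement from a cohort of ``N``:
    ``P(X=k) = C(K,k) C(N-K,n-k) / C(N,n)``. Computed in log space, exact
    to double precision over the whole support; symmetric in ``K`` and
    ``n``. Raises ``ValueError`` outside the support.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    _check_hypergeom_support(N, K, n, k)
    return math.exp(
        _log_choose(K, k) + _log_choose(N - K, n - k) - _log_choose(N, n)
    )


def hypergeometric_tail(N: int, K: int, n: int, k: int,
                        direction: str) -> float:
    """Cumulative one-tailed probability: ``P(X <= k)`` for
    ``direction="exclusivity"``, ``P(X >= k)`` for ``"enrichment"``."""
    N, K, n, k = int(N), int(K), int(n), int(k)
    _check_hypergeom_support(N, K, n, k)
    lo, hi = max(0, K + n - N), min(K, n)
    if direction == "exclusivity":
        ks = range(lo, k + 1)
    elif direction == "enrichment":
        ks = range(k, hi + 1)
    else:
        raise ValueError("direction must be 'exclusivity' or 'enrichment'")
    return float(min(1.0, sum(hypergeometric_point(N, K, n, j) for j in ks)))


def event_matrix(calls: pd.DataFrame, ploidy: int,
                 include_losses: bool | None = None) -> pd.DataFrame:
    """Boolean strains x events matrix of direction-specific aneuploidy
    events, with column labels like ``"chrVIII+"`` and ``"chrIX-"``.

    ``include_losses`` defaults to False for haploid cohorts (losses are
    lethal) and True otherwise. Only events observed in >= 1 strain are
    kept.
    """
    if include_losses is None:
        include_losses = ploidy > 1
    values = calls.to_numpy()
    cols: dict[str, np.ndarray] = {}
    for j, chrom in enumerate(calls.columns):
        gains = values[:, j] > ploidy
        if gains.any():
            cols[f"{chrom}{GAIN}"] = gains
        if include_losses:
            losses = values[:, j] < ploidy
            if losses.any():
                cols[f"{chrom}{LOSS}"] = losses
    return pd.DataFrame(cols, index=calls.index, dtype=bool)


def _split_event(label: str) -> tuple[str, str]:
    return label[:-1], label[-1]


def pairwise_cooccurrence(
    calls: pd.DataFrame,
    ploidy: int,
    stat: str = "point",
    include_losses: bool | None = None,
    include_same_chromosome: bool = False,
) -> pd.DataFrame:
    """Hypergeometric co-occurrence test for every pair of observed events.

    For each unordered pair of aneuploidy events (A, B): ``N`` = cohort
    size, ``K`` and ``n`` = strains carrying each event, ``k`` = strains
    carrying both. ``direction`` is "enrichment" when ``k`` exceeds the
    independence expectation ``n*K/N``, "exclusivity" when below, "none"
    at equality. The p-value is the point probability at the observed
    overlap (``stat="point"``, default) or the corresponding one-sided
    tail (``stat="tail"``).

    Gain and loss of the same chromosome are trivially exclusive and are
    skipped unless ``include_same_chromosome=True``.
    """
    if len(calls) < 2:
        raise ValueError("need >= 2 strains")
    if stat not in ("point", "tail"):
        raise ValueError("stat must be 'point' or 'tail'")
    events = event_matrix(calls, ploidy, include_losses=include_losses)
    if events.shape[1] < 2:
        raise ValueError("need >= 2 events with nonzero frequency")
    N = len(calls)
    ev = events.to_numpy()
    labels = list(events.columns)
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            chrom_a, _ = _split_event(labels[a])
            chrom_b, _ = _split_event(labels[b])
            if chrom_a == chrom_b and not include_same_chromosome:
                continue
            K = int(ev[:, a].sum())
            n = int(ev[:, b].sum())
            k = int((ev[:, a] & ev[:, b]).sum())
            expected = n * K / N
            if k > expected:
                direction = "enrichment"
            elif k < expected:
                direction = "exclusivity"
            else:
                direction = "none"
            if stat == "point":
                p = hypergeometric_point(N, K, n, k)
            else:
                tail_dir = "enrichment" if k >= expected else "exclusivity"
                p = hypergeometric_tail(N, K, n, k, tail_dir)
            rows.append((labels[a], labels[b], N, K, n, k, expected, direction, p))
    return pd.DataFrame(
        rows,
        columns=["event_a", "event_b", "N", "K", "n", "k",
                 "expected_overlap", "direction", "p"],
    )


class CorrelationMatrix(NamedTuple):
    """Pairwise Pearson correlations with an inclusion mask.

    ``r`` is a symmetric chromosomes x chromosomes DataFrame (diagonal
    NaN); ``included`` marks pairs where both chromosomes carry at least
    one aneuploid call and neither column is constant.
    """

    r: pd.DataFrame
    included: pd.DataFrame

    def pair_r(self, a: str, b: str) -> float:
        return float(self.r.loc[a, b])


def copy_correlation_matrix(matrix: pd.DataFrame, ploidy: int) -> CorrelationMatrix:
    """Pearson correlation of copy numbers across strains for every
    chromosome pair where aneuploidy was observed.

    Correlations use the continuous copy values; the inclusion mask uses
    binarized calls (a pair is included only if both chromosomes have >= 1
    aneuploid strain). Constant columns have undefined correlation and are
    excluded.
    """
    if len(matrix) < 3:
        raise ValueError("need >= 3 strains for correlations")
    calls = binarize_matrix(matrix, ploidy)
    has_aneuploidy = (calls.to_numpy() != ploidy).any(axis=0)
    values = matrix.to_numpy(dtype=float)
    nonconstant = values.std(axis=0) > 0
    usable = has_aneuploidy & nonconstant
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    cols = matrix.columns
    r = pd.DataFrame(corr, index=cols, columns=cols)
    included = pd.DataFrame(np.outer(usable, usable), index=cols, columns=cols)
    np.fill_diagonal(r.values, np.nan)
    np.fill_diagonal(included.values, False)
    r = r.where(included)
    return CorrelationMatrix(r=r, included=included)


def karyotype_pooled_sd(matrix: pd.DataFrame) -> float:
    """Pooled standard deviation of a karyotype cohort: the square root of
    the mean per-chromosome sample variance (ddof=1) of copy numbers across
    strains. A homogeneity measure — 0 when every strain has an identical
    karyotype."""
    if len(matrix) < 2:
        raise ValueError("need >= 2 strains")
    variances = matrix.to_numpy(dtype=float).var(axis=0, ddof=1)
    return float(np.sqrt(variances.mean()))


def read_copy_matrix(path) -> pd.DataFrame:
    """Read a strains x chromosomes copy-number matrix TSV (first column =
    strain identifier)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_copy_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="strain")
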