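"""Chromosome copy-number estimation from aligned read positions.

Whole-chromosome aneuploidy is called from whole-genome sequencing read
densities: reads are assigned to chromosomes by midpoint, subtelomeric
windows are excluded to remove repeat-driven mapping bias, densities are
normalized to a baseline taken from the second-lowest quartile of
chromosomes (robust to the aneuploid chromosomes themselves, which sit in
the upper ranks, and to poorly covered outliers at the bottom), and
continuous copy estimates are rounded to integer copy-number calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "load_read_positions",
    "compute_chromosome_densities",
    "estimate_copy_numbers",
    "call_aneuploidy",
    "call_karyotype",
    "round_to_integer_copy",
    "write_karyotype",
    "read_karyotype",
]

DEFAULT_TELOMERE_EXCLUSION = 15_000


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome set with lengths, basal ploidy and telomere window.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs. Order is preserved in every
        downstream table.
    basal_ploidy
        Baseline chromosome set count (1 haploid, 2 diploid).
    telomere_exclusion
        Width in bp of the window at *each* chromosome end excluded from
        read counting (default 15 kb).
    """

    chromosomes: tuple[tuple[str, int], ...]
    basal_ploidy: int = 1
    telomere_exclusion: int = DEFAULT_TELOMERE_EXCLUSION

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes)
        )
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if self.basal_ploidy < 1:
            raise ValueError("basal_ploidy must be a positive integer")
        if self.telomere_exclusion < 0:
            raise ValueError("telomere_exclusion must be non-negative")
        for name, length in self.chromosomes:
            if length <= 2 * self.telomere_exclusion:
                raise ValueError(
                    f"chromosome {name!r} (length {length}) is not longer than "
                    f"2 x telomere_exclusion ({2 * self.telomere_exclusion})"
                )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([l for _, l in self.chromosomes], dtype=np.int64)

    @property
    def usable_lengths(self) -> np.ndarray:
        """Length remaining after excluding both telomeric windows."""
        return self.lengths - 2 * self.telomere_exclusion

    @property
    def fractions(self) -> np.ndarray:
        """Fraction of the genome represented by each chromosome (sums to 1)."""
        lengths = self.lengths.astype(float)
        return lengths / lengths.sum()

    def length_of(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(name)

    @classmethod
    def from_tsv(cls, path, basal_ploidy: int = 1,
                 telomere_exclusion: int = DEFAULT_TELOMERE_EXCLUSION) -> "GenomeBuild":
        """Read a two-column (name, length) TSV without header."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["name", "length"], dtype={"name": str})
        return cls(tuple(zip(df["name"], df["length"].astype(int))),
                   basal_ploidy=basal_ploidy, telomere_exclusion=telomere_exclusion)


def load_read_positions(path, genome: GenomeBuild | None = None) -> pd.DataFrame:
    """Parse a BED3+ file of aligned read positions.

    Coordinates are 0-based half-open. Intervals on chromosomes absent from
    ``genome`` (when given) are dropped with a single warning reporting how
    many were removed.

    Returns a DataFrame with columns ``chrom``, ``start``, ``end``.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start ({start}) must be < end ({end})"
                )
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
    if not chroms:
        raise ValueError(f"{path}: no intervals found")
    reads = pd.DataFrame({
        "chrom": pd.Series(chroms, dtype=str),
        "start": np.asarray(starts, dtype=np.int64),
        "end": np.asarray(ends, dtype=np.int64),
    })
    if genome is not None:
        known = reads["chrom"].isin(genome.names)
        n_dropped = int((~known).sum())
        if n_dropped:
            dropped = sorted(reads.loc[~known, "chrom"].unique())
            warnings.warn(
                f"dropped {n_dropped} interval(s) on chromosome(s) not in the "
                f"genome build: {', '.join(dropped)}"
            )
            reads = reads.loc[known].reset_index(drop=True)
    return reads


def compute_chromosome_densities(
    reads: pd.DataFrame,
    genome: GenomeBuild,
    subtelomeres_only: bool = False,
) -> pd.DataFrame:
    """Count reads per chromosome and convert to densities.

    A read is assigned to a chromosome if its midpoint lies inside the
    retained region: by default ``[telomere_exclusion, length −
    telomere_exclusion)``; with ``subtelomeres_only=True`` the rule is
    inverted and only the terminal windows are counted (alternative reading
    of the telomere rule, not the default).

    Returns a DataFrame with columns ``chromosome``, ``length``,
    ``usable_length``, ``read_count``, ``density`` in genome order.
    """
    unknown = set(reads["chrom"].unique()) - set(genome.names)
    if unknown:
        raise ValueError(f"reads on chromosomes not in genome build: {sorted(unknown)}")
    tel = genome.telomere_exclusion
    midpoints = (reads["start"].to_numpy() + reads["end"].to_numpy()) / 2.0
    chrom_arr = reads["chrom"].to_numpy()
    rows = []
    for name, length in genome.chromosomes:
        on_chrom = chrom_arr == name
        mid = midpoints[on_chrom]
        inside = (mid >= tel) & (mid < length - tel)
        if subtelomeres_only:
            inside = ~inside
            usable = 2 * tel
        else:
            usable = length - 2 * tel
        count = int(inside.sum())
        rows.append((name, length, usable, count, count / usable))
    return pd.DataFrame(
        rows, columns=["chromosome", "length", "usable_length", "read_count", "density"]
    )


def _baseline_ranks(n_chrom: int) -> tuple[int, int]:
    """1-based rank bounds (exclusive low, inclusive high) of the second-lowest
    quartile: ceil(C/4) < r <= ceil(C/2)."""
    low = math.ceil(n_chrom / 4)
    high = math.ceil(n_chrom / 2)
    return low, high


def estimate_copy_numbers(
    profile: pd.DataFrame,
    genome: GenomeBuild,
    baseline_stat: str = "mean",
) -> pd.DataFrame:
    """Normalize read densities to continuous chromosome copy numbers.

    Chromosomes are ranked by density ascending (ties broken by genome
    order); the baseline is the mean (or median, ``baseline_stat="median"``)
    density of the chromosomes in the second-lowest quartile of that
    ranking, and ``copy = basal_ploidy * density / baseline``.

    Returns the profile with added ``copy``, ``baseline_density`` and
    ``ploidy`` columns.
    """
    if len(profile) < 4:
        raise ValueError("copy-number estimation needs >= 4 chromosomes")
    if baseline_stat not in ("mean", "median"):
        raise ValueError("baseline_stat must be 'mean' or 'median'")
    density = profile["density"].to_numpy(dtype=float)
    if not np.all(np.isfinite(density)):
        raise ValueError("densities must be finite")
    if np.all(density == 0):
        raise ValueError("all chromosome densities are zero")
    order = np.argsort(density, kind="stable")  # ties keep input (genome) order
    low, high = _baseline_ranks(len(density))
    baseline_set = density[order[low:high]]  # ranks low+1 .. high, 1-based
    baseline = float(np.mean(baseline_set) if baseline_stat == "mean"
                     else np.median(baseline_set))
    if baseline == 0:
        raise ValueError("baseline density is zero; coverage too sparse to normalize")
    out = profile.copy()
    out["copy"] = genome.basal_ploidy * density / baseline
    out["baseline_density"] = baseline
    out["ploidy"] = genome.basal_ploidy
    return out


def round_to_integer_copy(copy, ploidy: int):
    """Round continuous copies to integers, ties at .5 going away from the
    basal ploidy (1.5 -> 2 in haploids; 1.5 -> 1 and 2.5 -> 3 in diploids),
    so borderline values are called aneuploid."""
    c = np.asarray(copy, dtype=float)
    up = np.floor(c + 0.5)       # half away from ploidy, upward branch
    down = np.ceil(c - 0.5)      # downward branch
    ic = np.where(c >= ploidy, up, down).astype(np.int64)
    return ic if ic.ndim else int(ic)


def call_aneuploidy(estimate: pd.DataFrame, ploidy: int | None = None) -> pd.DataFrame:
    """Binarize continuous copy estimates into integer calls.

    Adds ``integer_copy`` and ``aneuploid`` (integer_copy != basal ploidy)
    columns. A call of 0 copies is emitted with a warning, since nullisomy
    of any chromosome is lethal in vivo and usually indicates a coverage
    artifact.
    """
    if ploidy is None:
        ploidy = int(estimate["ploidy"].iloc[0])
    copy = estimate["copy"].to_numpy(dtype=float)
    if not np.all(np.isfinite(copy)) or np.any(copy < 0):
        raise ValueError("copy estimates must be finite and non-negative")
    integer_copy = round_to_integer_copy(copy, ploidy)
    if np.any(integer_copy == 0):
        zero = estimate.loc[integer_copy == 0, "chromosome"].tolist()
        warnings.warn(
            f"nullisomy called for chromosome(s) {', '.join(map(str, zero))}; "
            "zero-copy calls are lethal in vivo and usually reflect missing coverage"
        )
    out = estimate.copy()
    out["integer_copy"] = integer_copy
    out["aneuploid"] = integer_copy != ploidy
    return out


def call_karyotype(
    reads: pd.DataFrame,
    genome: GenomeBuild,
    baseline_stat: str = "mean",
    subtelomeres_only: bool = False,
) -> pd.DataFrame:
    """Full per-strain pipeline: reads -> densities -> copies -> calls."""
    profile = compute_chromosome_densities(reads, genome,
                                           subtelomeres_only=subtelomeres_only)
    estimate = estimate_copy_numbers(profile, genome, baseline_stat=baseline_stat)
    return call_aneuploidy(estimate)


_KARYOTYPE_COLUMNS = ["chromosome", "read_count", "usable_length", "density",
                      "copy", "integer_copy", "aneuploid"]


def write_karyotype(calls: pd.DataFrame, path) -> None:
    """Write a per-strain karyotype table as TSV."""
    calls.to_csv(path, sep="\t", index=False,
                 columns=[c for c in _KARYOTYPE_COLUMNS if c in calls.columns])


def read_karyotype(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
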