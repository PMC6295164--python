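"""Arm-level tumor karyotypes from copy-number segment tables.

Builds per-sample chromosome-arm copy-number profiles from SEG-format
segment tables (log2(copy/2) ratios by the GDC convention; a linear-ratio
mode is available), applies quality filters — samples whose arm-level
length-weighted mean and median disagree by more than a gap threshold are
dominated by focal events and are excluded — calls each arm gained (+1),
neutral (0) or lost (-1), and hands the resulting call matrix to the
co-occurrence machinery used for the yeast cohorts.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cooccurrence import pairwise_cooccurrence

__all__ = [
    "load_segments",
    "ArmModel",
    "build_arm_model",
    "summarize_arms",
    "filter_samples",
    "call_arm_aberrations",
    "filter_complex",
    "frequent_arms",
    "arm_cooccurrence",
]

_SEG_ALIASES = {
    "sample": ("sample", "id", "gdc_aliquot"),
    "chrom": ("chromosome", "chrom", "chr"),
    "start": ("start", "loc.start"),
    "end": ("end", "loc.end"),
    "value": ("segment_mean", "seg.mean", "value"),
}


def normalize_chrom(name: str) -> str:
    """Map "chr1" and "1" to the same key."""
    name = str(name)
    return name[3:] if name.lower().startswith("chr") else name


def load_segments(path, one_based: bool = False, linear: bool = False) -> pd.DataFrame:
    """Parse a SEG file (tab-separated, with header) into a segment table.

    Columns are matched case-insensitively against the common SEG dialects
    (Sample/ID, Chromosome, Start, End, Segment_Mean). Coordinates are
    normalized to 0-based half-open (``one_based=True`` shifts 1-based
    inclusive starts down by one); chromosome names are normalized so that
    "chr1" and "1" coincide. With ``linear=True`` segment values are linear
    copy ratios and are converted to log2.

    Raises on missing columns and on overlapping segments within one
    sample/chromosome, listing the offenders.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower(): c for c in df.columns}
    resolved = {}
    for key, aliases in _SEG_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[key] = lower[alias]
                break
        else:
            raise ValueError(
                f"segment file missing required column for {key!r} "
                f"(accepted: {', '.join(aliases)})"
            )
    seg = pd.DataFrame({
        "sample": df[resolved["sample"]].astype(str),
        "chrom": df[resolved["chrom"]].map(normalize_chrom),
        "start": df[resolved["start"]].astype(np.int64),
        "end": df[resolved["end"]].astype(np.int64),
        "value": df[resolved["value"]].astype(float),
    })
    if one_based:
        seg["start"] -= 1
    if (seg["start"] >= seg["end"]).any():
        bad = seg.index[seg["start"] >= seg["end"]].tolist()
        raise ValueError(f"segments with start >= end at rows {bad}")
    if linear:
        if (seg["value"] <= 0).any():
            raise ValueError("linear copy ratios must be positive")
        seg["value"] = np.log2(seg["value"])
    offenders = []
    for (sample, chrom), grp in seg.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if overlap.any():
            offenders.append(f"{sample}/{chrom}")
    if offenders:
        raise ValueError(
            "overlapping segments within sample/chromosome: " + ", ".join(offenders)
        )
    return seg.reset_index(drop=True)


class ArmInterval(NamedTuple):
    start: int
    end: int


class ArmModel:
    """p- and q-arm intervals per chromosome, derived from cytogenetic bands.

    ``arms`` maps chromosome -> {"p": ArmInterval | None, "q": ArmInterval}.
    Acrocentric chromosomes have no p-arm interval.
    """

    def __init__(self, arms: dict[str, dict[str, ArmInterval | None]]):
        self.arms = arms

    def arm_names(self) -> list[str]:
        out = []
        for chrom, d in self.arms.items():
            for arm in ("p", "q"):
                if d.get(arm) is not None:
                    out.append(f"{chrom}{arm}")
        return out

    def interval(self, arm_name: str) -> ArmInterval:
        chrom, arm = arm_name[:-1], arm_name[-1]
        iv = self.arms[chrom][arm]
        if iv is None:
            raise KeyError(f"{arm_name}: arm absent")
        return iv


def build_arm_model(path) -> ArmModel:
    """Build an ArmModel from a UCSC-style cytoband file.

    Five tab-separated columns without header: chrom, start, end, band
    name, Giemsa stain. The p-arm is the union of ``p*`` bands and the
    q-arm the union of ``q*`` bands; centromeric bands (stain ``acen``)
    belong to neither arm. A chromosome with no q bands is an error; a
    chromosome with only q bands is treated as acrocentric (p-arm absent).
    """
    bands = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str, "stain": str},
    )
    bands["chrom"] = bands["chrom"].map(normalize_chrom)
    arms: dict[str, dict[str, ArmInterval | None]] = {}
    for chrom, grp in bands.groupby("chrom", sort=False):
        grp = grp[grp["stain"] != "acen"]
        d: dict[str, ArmInterval | None] = {"p": None, "q": None}
        for arm in ("p", "q"):
            sub = grp[grp["band"].str.startswith(arm)]
            if len(sub):
                d[arm] = ArmInterval(int(sub["start"].min()), int(sub["end"].max()))
        if d["q"] is None:
            raise ValueError(f"chromosome {chrom}: no q bands in cytoband file")
        if d["p"] is not None and d["p"].end > d["q"].start:
            raise ValueError(f"chromosome {chrom}: p arm extends past q arm start")
        arms[chrom] = d
    return ArmModel(arms)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Length-weighted median; at an exact 50% cumulative boundary the lower
    value is taken."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half, side="left"))
    return float(v[idx])


def summarize_arms(segments: pd.DataFrame, arms: ArmModel) -> pd.DataFrame:
    """Length-weighted per-sample, per-arm segment summaries.

    Returns a DataFrame with one row per (sample, arm) holding
    ``weighted_mean``, ``weighted_median``, ``gap`` (their absolute
    difference — large when focal events dominate the arm),
    ``covered_fraction`` and ``missing`` (True when no segment overlaps
    the arm).
    """
    arm_list = arms.arm_names()
    rows = []
    for sample, sample_seg in segments.groupby("sample", sort=False):
        by_chrom = {c: g for c, g in sample_seg.groupby("chrom", sort=False)}
        for arm_name in arm_list:
            chrom = arm_name[:-1]
            iv = arms.interval(arm_name)
            arm_len = iv.end - iv.start
            grp = by_chrom.get(chrom)
            if grp is not None:
                starts = np.maximum(grp["start"].to_numpy(), iv.start)
                ends = np.minimum(grp["end"].to_numpy(), iv.end)
                overlap = (ends - starts).clip(min=0)
                mask = overlap > 0
            else:
                mask = np.zeros(0, dtype=bool)
            if grp is None or not mask.any():
                rows.append((sample, arm_name, np.nan, np.nan, np.nan, 0.0, True))
                continue
            values = grp["value"].to_numpy(dtype=float)[mask]
            weights = overlap[mask].astype(float)
            wmean = float(np.average(values, weights=weights))
            wmedian = _weighted_median(values, weights)
            rows.append((
                sample, arm_name, wmean, wmedian, abs(wmean - wmedian),
                float(weights.sum() / arm_len), False,
            ))
    return pd.DataFrame(
        rows,
        columns=["sample", "arm", "weighted_mean", "weighted_median", "gap",
                 "covered_fraction", "missing"],
    )


def filter_samples(
    profiles: pd.DataFrame, gap_threshold: float = 0.2
) -> tuple[list[str], pd.DataFrame]:
    """Exclude samples dominated by sub-arm events.

    A sample is excluded iff any of its arms has ``gap`` (|weighted mean −
    weighted median|) strictly greater than ``gap_threshold``. Returns the
    retained sample list (input order) and a report of offending
    (sample, arm, gap) rows.
    """
    measured = profiles[~profiles["missing"]]
    offending = measured[measured["gap"] > gap_threshold]
    excluded = set(offending["sample"])
    retained = [s for s in profiles["sample"].unique() if s not in excluded]
    report = offending[["sample", "arm", "gap"]].reset_index(drop=True)
    return retained, report


def call_arm_aberrations(
    profiles: pd.DataFrame, call_threshold: float = 0.2
) -> pd.DataFrame:
    """Call each arm gained/neutral/lost from its weighted mean.

    +1 when ``weighted_mean >= call_threshold``, −1 when ``<=
    -call_threshold`` (inclusive at both boundaries), else 0; arms with no
    coverage call 0. Returns a samples x arms integer matrix.
    """
    def call(m: float) -> int:
        if np.isnan(m):
            return 0
        if m >= call_threshold:
            return 1
        if m <= -call_threshold:
            return -1
        return 0

    table = profiles.pivot(index="sample", columns="arm", values="weighted_mean")
    arm_order = list(dict.fromkeys(profiles["arm"]))
    sample_order = list(dict.fromkeys(profiles["sample"]))
    table = table.reindex(index=sample_order, columns=arm_order)
    return table.map(call).astype(np.int64)


def filter_complex(calls: pd.DataFrame, min_aberrations: int = 2) -> pd.DataFrame:
    """Retain only complex karyotypes: samples with >= ``min_aberrations``
    nonzero arm calls."""
    keep = (calls.to_numpy() != 0).sum(axis=1) >= min_aberrations
    return calls.loc[keep]


def frequent_arms(calls: pd.DataFrame, min_fraction: float = 0.10) -> list[str]:
    """Arms with a nonzero call in strictly more than ``min_fraction`` of
    the samples (display filter)."""
    frac = (calls.to_numpy() != 0).mean(axis=0)
    return [arm for arm, f in zip(calls.columns, frac) if f > min_fraction]


def arm_cooccurrence(calls: pd.DataFrame, stat: str = "point") -> pd.DataFrame:
    """Run the pairwise hypergeometric co-occurrence test on an arm-call
    matrix (−1/0/+1), treating arm gain and loss as direction-specific
    events as in the diploid yeast analysis."""
    # shift to a pseudo-diploid copy scale so the shared event machinery applies
    pseudo = calls + 2
    return pairwise_cooccurrence(pseudo, ploidy=2, stat=stat, include_losses=True)
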