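"""Bespoke phenotype computations: growth doubling times and qPCR copy numbers."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DoublingTimeFit", "doubling_time", "qpcr_copy_number"]


class DoublingTimeFit(NamedTuple):
    doubling_time_h: float
    slope: float        # per hour, on ln(OD)
    r_squared: float


def doubling_time(time_h, od) -> DoublingTimeFit:
    """Doubling time from an optical-density growth curve.

    Least-squares fit of ``ln(OD)`` against time (exponential growth);
    doubling time is ``ln 2 / slope``. Requires >= 3 points with strictly
    increasing times and positive OD; a non-positive slope (no exponential
    growth) is an error.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("optical densities must be positive")
    fit = stats.linregress(t, np.log(y))
    if fit.slope <= 0:
        raise ValueError("no exponential growth: fitted slope is not positive")
    return DoublingTimeFit(
        doubling_time_h=float(np.log(2) / fit.slope),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
    )


def _delta_ct(strain_df: pd.DataFrame, target: str) -> float:
    """Mean target C_t minus mean reference C_t for one strain.

    Duplicate C_t values are averaged before any difference is taken.
    """
    targets = strain_df[(strain_df["primer"] == target)
                        & (strain_df["role"] == "target")]
    refs = strain_df[strain_df["role"] == "reference"]
    if refs.empty:
        raise ValueError("no reference-primer measurements for strain")
    if targets.empty:
        raise ValueError(f"no measurements for target primer {target!r}")
    return float(targets["ct"].mean() - refs["ct"].mean())


def qpcr_copy_number(
    measurements: pd.DataFrame,
    test_strain: str,
    reference_strain: str,
    basal_ploidy: int = 1,
) -> pd.Series:
    """Chromosome copy number by a modified ddCt scheme.

    For each target primer: ``dCt = mean Ct(target) − mean Ct(reference
    primer)`` per strain, ``fold = 2**(−dCt)``, and ``copy = basal_ploidy *
    fold(test) / fold(reference strain)``. The input table has columns
    ``strain``, ``primer``, ``role`` (``target`` | ``reference``), ``ct``,
    one row per technical replicate.

    Plate offsets (a constant added to every C_t of one strain) cancel in
    the dCt; the wild-type ratio then calibrates out primer efficiencies.
    """
    for col in ("strain", "primer", "role", "ct"):
        if col not in measurements.columns:
            raise ValueError(f"measurements table missing column {col!r}")
    test = measurements[measurements["strain"] == test_strain]
    wt = measurements[measurements["strain"] == reference_strain]
    if test.empty or wt.empty:
        raise ValueError("both test and reference strains must be measured")
    targets = sorted(test.loc[test["role"] == "target", "primer"].unique())
    copies = {}
    for primer in targets:
        d_test = _delta_ct(test, primer)
        d_wt = _delta_ct(wt, primer)
        fold_ratio = 2.0 ** (-(d_test - d_wt))
        copies[primer] = basal_ploidy * fold_ratio
    return pd.Series(copies, name="copy_number")
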