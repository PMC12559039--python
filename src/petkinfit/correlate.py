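"""Pearson-correlation method comparison.

Two comparisons are produced:

* Vt (from 1TCM, 2TCM and Logan) against windowed SUV, pooling all
  region-by-subject points — answers "can late SUV substitute for an
  arterial-input Vt?";
* regional mean SUVR-1 against an externally supplied region-wise target
  density vector (e.g. autoradiographic enzyme density) — answers "which
  window/reference combination best tracks the underlying target
  distribution?".  The density vector is user-supplied; it ships with no
  values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "pearson", "format_p",
           "build_vt_suv_table", "build_suvr_density_table"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("inputs must be finite (apply pairwise deletion first)")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def format_p(p: float, threshold: float = 1e-4) -> str:
    """Display formatting used in result tables: tiny p-values as '< 0.0001'."""
    return f"< {threshold:g}" if p < threshold else f"{p:.4f}"


def build_vt_suv_table(vts: pd.DataFrame, suvs: pd.DataFrame) -> pd.DataFrame:
    """Method x window matrix of correlations between Vt and windowed SUV.

    ``vts``: columns (subject, region, method, vt); ``suvs``: columns
    (subject, region, window, suv).  All region-by-subject points are pooled
    within each cell.  Output is long format with one row per
    (method, window) and columns r, p, n.
    """
    need_v = {"subject", "region", "method", "vt"} - set(vts.columns)
    need_s = {"subject", "region", "window", "suv"} - set(suvs.columns)
    if need_v or need_s:
        raise ValueError(f"missing columns: {sorted(need_v | need_s)}")
    vr = set(map(tuple, vts[["subject", "region"]].drop_duplicates().values))
    sr = set(map(tuple, suvs[["subject", "region"]].drop_duplicates().values))
    if vr - sr:
        raise ValueError(f"regions without SUVs: {sorted(vr - sr)}")
    rows = []
    for method, vgrp in vts.groupby("method", sort=False):
        for window, sgrp in suvs.groupby("window", sort=False):
            merged = vgrp.merge(sgrp, on=["subject", "region"])
            res = pearson(merged["suv"], merged["vt"])
            rows.append({"method": method, "window": window,
                         "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def build_suvr_density_table(suvrs: pd.DataFrame, density: pd.DataFrame,
                             target_regions=None) -> pd.DataFrame:
    """Window x reference matrix of correlations between SUVR-1 and density.

    ``suvrs``: columns (subject, region, reference, window, suvr_minus_one);
    ``density``: columns (region, density), the external region-wise target
    vector.  SUVR-1 is averaged over subjects per region before correlating
    (region means, not pooled points).  Reference regions themselves are not
    correlated against the density vector; ``target_regions`` restricts the
    rows further when given.
    """
    need = {"subject", "region", "reference", "window", "suvr_minus_one"} - set(suvrs.columns)
    if need or {"region", "density"} - set(density.columns):
        raise ValueError("suvr/density tables lack required columns")
    if density["density"].nunique() < 2:
        raise ValueError("density vector has zero variance")
    dens = dict(zip(density["region"], density["density"]))
    refs = set(suvrs["reference"])
    rows = []
    for (window, ref), grp in suvrs.groupby(["window", "reference"], sort=False):
        means = grp.groupby("region")["suvr_minus_one"].mean()
        regions = [r for r in means.index if r not in refs]
        if target_regions is not None:
            regions = [r for r in regions if r in set(target_regions)]
        unmapped = [r for r in regions if r not in dens]
        if unmapped:
            raise ValueError(f"regions without density values: {sorted(unmapped)}")
        res = pearson(means.loc[regions].to_numpy(),
                      np.array([dens[r] for r in regions]))
        rows.append({"window": window, "reference": ref,
                     "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
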