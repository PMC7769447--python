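"""Patch prioritization, area–importance correlations, and per-capita analysis.

Top-priority patches are the highest-dIIC fraction of the layer (the field's
usual map shows the top 20%).  The correlation matrix is the Spearman rank
matrix among patch area, dIIC and its three fractions, optionally masked at a
significance level.  The per-capita table intersects patches with districts,
credits each district with its share of every patch, and relates grassland
area per capita to population density on log scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.strtree import STRtree

from .io_geometry import PatchLayer
from .synthetic import DistrictLayer

__all__ = [
    "top_fraction",
    "correlation_matrix",
    "per_capita",
    "loglog_relation",
    "CorrelationMatrix",
]

_CORR_VARS = ["area_ha", "dIIC", "dIIC_intra", "dIIC_flux", "dIIC_connector"]


def top_fraction(table: pd.DataFrame, q: float) -> set[int]:
    """Ids of the ceil(q·n) patches with the highest dIIC.

    Uses the table's deterministic rank (descending dIIC; ties broken by
    descending area then ascending id).
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    k = math.ceil(q * len(table))
    chosen = table.nsmallest(k, "rank")
    return set(chosen["patch_id"].tolist())


@dataclass
class CorrelationMatrix:
    """Spearman rho among area, dIIC and its fractions at one threshold.

    ``rho`` and ``p_values`` are symmetric DataFrames over the variables;
    ``masked`` is rho with entries at p >= alpha (or undefined, e.g. constant
    columns) reported as NaN, mirroring tables that print only significant
    correlations.
    """

    threshold: float
    rho: pd.DataFrame
    p_values: pd.DataFrame
    masked: pd.DataFrame
    alpha: float


def correlation_matrix(table: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """Spearman rank correlations (average ranks for ties, two-sided p).

    Requires at least 5 patches.  A constant column gives NaN rho with NaN p
    (undefined, not zero); such entries stay masked.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 patches for a correlation matrix")
    x = table[_CORR_VARS].to_numpy()
    k = len(_CORR_VARS)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(x[:, i]) == 0 or np.ptp(x[:, j]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x[:, i], x[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    rho_df = pd.DataFrame(rho, index=_CORR_VARS, columns=_CORR_VARS)
    p_df = pd.DataFrame(pval, index=_CORR_VARS, columns=_CORR_VARS)
    masked = rho_df.where(~(p_df >= alpha))
    thr = table.attrs.get("threshold", float("nan"))
    return CorrelationMatrix(thr, rho_df, p_df, masked, alpha)


def per_capita(patches: PatchLayer, districts: DistrictLayer) -> pd.DataFrame:
    """Grassland area per capita and population density per district.

    Patch-to-district assignment is by geometric intersection: a patch split
    across districts contributes each part to its district, so district
    grassland areas are exactly additive.  Districts with zero population but
    nonzero grassland get ``area_per_capita`` NaN (flagged undefined) and are
    excluded from any density relation.
    """
    tree = STRtree(patches.geometries)
    grass = np.zeros(len(districts))
    for di, dg in enumerate(districts.geometries):
        hits = tree.query(dg, predicate="intersects")
        for pi in hits.tolist():
            grass[di] += patches.geometries[pi].intersection(dg).area
    areas = districts.areas
    pops = districts.populations
    with np.errstate(divide="ignore", invalid="ignore"):
        apc = np.where(pops > 0, grass / np.maximum(pops, 1e-300), np.nan)
    return pd.DataFrame(
        {
            "district_id": districts.ids,
            "grassland_area_m2": grass,
            "population": pops,
            "area_per_capita_m2": apc,
            "density_per_km2": pops / (areas / 1e6),
        }
    )


def loglog_relation(table: pd.DataFrame) -> tuple[float, float]:
    """(Spearman rho, log–log OLS slope) of per-capita area vs density.

    Both quantities are restricted to rows where they are positive and
    defined; the slope is from an ordinary least-squares fit of
    log10(area per capita) on log10(density).
    """
    t = table.dropna(subset=["area_per_capita_m2"])
    t = t[(t["area_per_capita_m2"] > 0) & (t["density_per_km2"] > 0)]
    if len(t) < 3:
        raise ValueError("need at least 3 districts with positive values")
    x = np.log10(t["density_per_km2"].to_numpy())
    y = np.log10(t["area_per_capita_m2"].to_numpy())
    rho, _ = stats.spearmanr(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return float(rho), slope
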