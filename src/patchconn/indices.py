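"""Integral Index of Connectivity and node-removal patch importance.

The IIC of a threshold graph is

    IIC = [ Σ_i Σ_j a_i a_j / (1 + nl_ij) ] / A_L²

summed over ordered patch pairs including i = j, where a_i is patch area,
nl_ij the number of links on the shortest topological path (0 on the
diagonal), pairs in different components contribute 0, and A_L is the total
landscape area.  Because A_L is a normalization constant that cancels from
every importance ratio, the numerator (in ha²) is the primary quantity here
and the normalized index is filled in only when A_L is supplied.

A patch's importance is the percentage drop in IIC when it and its links are
removed, dIIC_k = 100 (IIC − IIC_remove,k) / IIC.  It splits exactly into
three additive fractions:

    intra_k     = 100 a_k² / IICnum                      (within-patch area)
    flux_k      = 100 · 2 Σ_{j≠k} a_k a_j/(1+nl_kj) / IICnum   (patch as endpoint)
    connector_k = 100 Σ_{i,j≠k} a_i a_j [1/(1+nl_ij) − 1/(1+nl'_ij)] / IICnum

with nl' the link counts after removing k (pairs that become unreachable
contribute their full original term).  connector is nonzero only where the
patch is a stepping stone whose loss lengthens or severs other pairs' paths.

Node removal only changes nl_ij for pairs with a shortest path through k
(nl_ik + nl_kj = nl_ij), so the expensive re-computation is restricted to
those source rows, inside k's component only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import SinglePatchError
from .graph_core import ThresholdGraph
from .io_geometry import M2_PER_HA

__all__ = ["IICResult", "iic", "node_importance", "fraction_profile"]


@dataclass
class IICResult:
    """IIC numerator (ha²) and, when A_L is given, the normalized index."""

    threshold: float
    iic_num: float
    a_l: float | None = None
    iic: float | None = None


def _component_blocks(g: ThresholdGraph):
    """Yield (indices, areas_ha, adjacency-sub, nl-matrix) per component."""
    adj = g.adjacency()
    n = g.n_nodes
    areas_ha = g.areas_vector() / M2_PER_HA
    _, labels = connected_components(adj, directed=False)
    for c in range(int(labels.max()) + 1 if n else 0):
        idx = np.nonzero(labels == c)[0]
        sub = adj[idx][:, idx]
        if len(idx) == 1:
            d = np.zeros((1, 1))
        else:
            d = shortest_path(sub, method="D", directed=False, unweighted=True)
        yield idx, areas_ha[idx], sub, d


def _iic_num_from_blocks(blocks) -> float:
    total = 0.0
    for _, a, _, d in blocks:
        r = 1.0 / (1.0 + d)  # d finite within a component
        total += float(a @ r @ a)
    return total


def iic(g: ThresholdGraph, a_l: float | None = None) -> IICResult:
    """Compute the IIC numerator (ha²) and optionally the normalized IIC.

    ``a_l`` is the total landscape area in ha.  Unreachable pairs contribute
    zero.  If the numerator exceeds A_L² (habitat exceeding landscape), a
    warning is emitted rather than an error.
    """
    if np.any(g.areas_vector() <= 0):
        raise ValueError("all patch areas must be positive")
    num = _iic_num_from_blocks(_component_blocks(g))
    if a_l is None:
        return IICResult(g.threshold, num)
    if a_l <= 0:
        raise ValueError("A_L must be positive")
    if num > a_l * a_l:
        warnings.warn(
            "IIC numerator exceeds A_L²: habitat area exceeds landscape area",
            stacklevel=2,
        )
    return IICResult(g.threshold, num, a_l, num / (a_l * a_l))


def _stepping_stone_candidates(sub, d: np.ndarray) -> np.ndarray:
    """Positions k that can possibly carry a nonzero connector fraction.

    A shortest path with interior node k enters and leaves k through two
    neighbors h1, h2 at link distance 2 from each other.  If every such
    neighbor pair has a second common neighbor c != k, any shortest path
    through k reroutes via c at equal length, so removing k changes no
    pair's link count and connector_k = 0.  The test is exact and cheap
    (common-neighbor counts are entries of A²).
    """
    m = sub.shape[0]
    if m < 3:
        return np.array([], int)
    a2 = (sub @ sub).toarray()
    flagged = []
    for k in range(m):
        nbrs = sub.indices[sub.indptr[k]: sub.indptr[k + 1]]
        if len(nbrs) < 2:
            continue  # a leaf is no stepping stone
        dn = d[np.ix_(nbrs, nbrs)]
        if np.any((dn == 2) & (a2[np.ix_(nbrs, nbrs)] == 1)):
            flagged.append(k)
    return np.asarray(flagged, int)


def _path_counts(sub, d: np.ndarray) -> np.ndarray:
    """All-pairs counts of distinct shortest paths, by BFS-level recursion.

    sigma_ii = 1 and, for pairs at link distance L, sigma_ij sums sigma_ih
    over neighbors h of j at distance L−1 from i.  Counts are float64; they
    are only ever used in the factorization test below, which tolerates the
    ~1e-12 relative rounding their accumulation can reach.
    """
    m = d.shape[0]
    sigma = np.eye(m)
    for level in range(1, int(d.max()) + 1):
        prev = np.where(d == level - 1, sigma, 0.0)
        t = prev @ sub  # dense @ csr
        lev = d == level
        sigma[lev] = np.asarray(t)[lev]
    return sigma


# Relative slack for the float path-count factorization test.  True counts
# are integers with sigma_ij >= sigma_ik * sigma_kj; accumulated float64
# rounding stays orders of magnitude below this slack, so a pair whose every
# shortest path runs through k is never missed (a false positive merely
# triggers a redundant BFS, which is harmless).
_SIGMA_RTOL = 1e-9


def _connector_and_removed(
    sub, d_int: np.ndarray, sigma: np.ndarray, sigma_tol: np.ndarray,
    a: np.ndarray, k: int
) -> float:
    """Connector numerator for node k of one component (ha² units).

    ``sub``: component adjacency (csr); ``d_int``: its nl matrix (int16);
    ``sigma``/``sigma_tol``: shortest-path counts and counts scaled by the
    tolerance; ``a``: areas; ``k``: node position within the component.

    Only pairs whose *every* shortest path passes through k change when k is
    removed (detected by the path-count factorization sigma_ik·sigma_kj =
    sigma_ij).  Of those, pairs that fall into different components of G−k
    lose their whole term with no search needed; BFS re-runs only from rows
    that keep an affected pair inside one surviving component.
    """
    m = len(a)
    via = d_int[:, k][:, None] + d_int[k, :]
    on_path = via == d_int  # exact: link counts are small integers
    on_path[k, :] = False
    on_path[:, k] = False
    np.fill_diagonal(on_path, False)
    ii, jj = np.nonzero(on_path)
    if len(ii) == 0:
        return 0.0
    through = sigma[ii, k] * sigma[k, jj] >= sigma_tol[ii, jj]
    ii, jj = ii[through], jj[through]
    if len(ii) == 0:
        return 0.0

    keep = np.concatenate([np.arange(k), np.arange(k + 1, m)])
    sub_k = sub[keep][:, keep]
    _, labels_k = connected_components(sub_k, directed=False)
    pos = np.searchsorted(keep, np.arange(m).clip(0, m - 1))
    li, lj = labels_k[pos[ii]], labels_k[pos[jj]]
    severed = li != lj

    r_old_pairs = 1.0 / (1.0 + d_int[ii, jj].astype(float))
    total = 0.0

    bfs_rows = np.unique(ii[~severed])
    if len(bfs_rows):
        d_new = shortest_path(
            sub_k, method="auto", directed=False, unweighted=True,
            indices=pos[bfs_rows],
        )
        r_old = 1.0 / (1.0 + d_int[np.ix_(bfs_rows, keep)].astype(float))
        with np.errstate(divide="ignore"):
            r_new = np.where(np.isinf(d_new), 0.0, 1.0 / (1.0 + d_new))
        total += float(a[bfs_rows] @ ((r_old - r_new) @ a[keep]))
    # severed pairs in rows not re-searched lose their full term
    if np.any(severed):
        in_bfs = np.isin(ii, bfs_rows)
        rest = severed & ~in_bfs
        total += float(np.sum(a[ii[rest]] * a[jj[rest]] * r_old_pairs[rest]))
    return total


def node_importance(g: ThresholdGraph, a_l: float | None = None) -> pd.DataFrame:
    """Per-patch dIIC (%) with its intra/flux/connector partition and ranks.

    Returns a DataFrame with one row per patch: ``patch_id``, ``area_ha``,
    ``dIIC``, ``dIIC_intra``, ``dIIC_flux``, ``dIIC_connector`` (all percent
    of total IIC), ``rank`` (1 = most important; ties broken by descending
    area then ascending id) and ``normalized_rank`` (dIIC / max dIIC).

    The three fractions sum exactly to dIIC, and none depends on A_L —
    importance is a ratio of IIC numerators, so ``a_l`` only tags the result.
    """
    n = g.n_nodes
    if n < 2:
        raise SinglePatchError("node importance needs at least 2 patches")

    blocks = list(_component_blocks(g))
    iic_num = _iic_num_from_blocks(blocks)

    ids = np.asarray(g.node_ids)
    intra = np.zeros(n)
    flux = np.zeros(n)
    connector = np.zeros(n)
    for idx, a, sub, d in blocks:
        r = 1.0 / (1.0 + d)
        row_sums = r @ a  # includes the diagonal a_k
        intra[idx] = a * a
        flux[idx] = 2.0 * a * (row_sums - a)
        stones = _stepping_stone_candidates(sub, d)
        if len(stones):
            sigma = _path_counts(sub, d)
            sigma_tol = sigma * (1.0 - _SIGMA_RTOL)
            d_int = d.astype(np.int16)
            for pos in stones.tolist():
                connector[idx[pos]] = _connector_and_removed(
                    sub, d_int, sigma, sigma_tol, a, pos
                )

    scale = 100.0 / iic_num
    diic = (intra + flux + connector) * scale
    table = pd.DataFrame(
        {
            "patch_id": ids,
            "area_ha": g.areas_vector() / M2_PER_HA,
            "dIIC": diic,
            "dIIC_intra": intra * scale,
            "dIIC_flux": flux * scale,
            "dIIC_connector": connector * scale,
        }
    )
    order = np.lexsort((table["patch_id"], -table["area_ha"], -table["dIIC"]))
    rank = np.empty(n, int)
    rank[order] = np.arange(1, n + 1)
    table["rank"] = rank
    dmax = table["dIIC"].max()
    table["normalized_rank"] = table["dIIC"] / dmax if dmax > 0 else 0.0
    table.attrs["threshold"] = g.threshold
    table.attrs["iic_num"] = iic_num
    if a_l is not None:
        table.attrs["a_l"] = a_l
    return table.sort_values("rank", ignore_index=True)


def fraction_profile(tables: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Mean intra/flux/connector shares of dIIC per dispersal threshold.

    For each patch the three fractions are recast as percentages of that
    patch's own dIIC (summing to 100); the unweighted mean share across
    patches is then taken per threshold.  Patches with dIIC = 0 have no
    defined shares and are excluded.  Rows are sorted by threshold.
    """
    rows = []
    for d, table in sorted(tables.items()):
        t = table[table["dIIC"] > 0]
        shares = (
            t[["dIIC_intra", "dIIC_flux", "dIIC_connector"]].to_numpy()
            / t["dIIC"].to_numpy()[:, None]
            * 100.0
        )
        mean = shares.mean(axis=0)
        rows.append(
            {
                "threshold": d,
                "intra_share": mean[0],
                "flux_share": mean[1],
                "connector_share": mean[2],
                "n_patches": len(t),
            }
        )
    out = pd.DataFrame(rows)
    if len(out) and not np.allclose(
        out[["intra_share", "flux_share", "connector_share"]].sum(axis=1), 100.0
    ):
        raise AssertionError("fraction shares must sum to 100% per threshold")
    return out
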