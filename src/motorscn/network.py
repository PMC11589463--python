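"""Structural covariance network construction.

Per group: ordinary-least-squares residualisation of ROI volumes on age, sex
and TIV, across-subject Pearson correlation of the residuals for every node
pair, Fisher r-to-z transform, and density thresholding of the z-matrix into
a nested family of binary undirected graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import COVARIATES, CohortTable

logger = logging.getLogger("motorscn")

_R_CLIP = 1.0 - 1e-12   # keeps atanh finite on degenerate (collinear) pairs


@dataclass
class ResidualMatrix:
    """Covariate-adjusted volumes for one group (subjects x nodes)."""
    group: str
    subjects: list[str]
    nodes: list[str]
    values: np.ndarray
    covariates_used: list[str]


@dataclass
class CovarianceNetwork:
    """One group's structural covariance network (Pearson r and Fisher z)."""
    group: str
    nodes: list[str]
    r_matrix: np.ndarray
    z_matrix: np.ndarray
    n_subjects: int
    df_adjustment: int    # number of covariates removed upstream


@dataclass
class ThresholdedGraphSet:
    """Nested binary graphs of one network across a density grid."""
    group: str
    nodes: list[str]
    densities: np.ndarray
    graphs: np.ndarray          # (n_densities, N, N) boolean
    edge_rank: list[tuple[int, int]]


def _design_matrix(cov: np.ndarray, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns; constant covariates are dropped with a
    warning instead of failing (e.g. single-sex subgroup)."""
    cols, used = [np.ones(cov.shape[0])], []
    for j, name in enumerate(covariates):
        if np.ptp(cov[:, j]) == 0:
            logger.warning("covariate %r constant within scope; dropped", name)
            continue
        cols.append(cov[:, j])
        used.append(name)
    return np.column_stack(cols), used


def residualize(cohort: CohortTable,
                covariates: Sequence[str] = COVARIATES,
                scope: str = "pooled",
                groups: Sequence[str] | None = None,
                include_extras: bool = False) -> dict[str, ResidualMatrix]:
    """OLS residuals of every volume column on the covariates.

    ``scope='pooled'`` fits one group-blind design across all selected
    subjects (default: group differences in covariance are not absorbed by
    group-specific covariate fits); ``scope='per-group'`` fits within group.
    """
    if scope not in ("pooled", "per-group"):
        raise ValueError("scope must be 'pooled' or 'per-group'")
    df = cohort.data
    groups = list(groups) if groups is not None else sorted(df["group"].unique())
    df = df[df["group"].isin(groups)]
    node_cols = cohort.atlas.names + (cohort.extra_nodes if include_extras else [])
    Y_all = df[node_cols].to_numpy(dtype=float)
    C_all = df[list(covariates)].to_numpy(dtype=float)
    labels = df["group"].to_numpy()
    ids = df["subject_id"].to_numpy()

    def _fit(Y: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, list[str]]:
        X, used = _design_matrix(C, covariates)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return Y - X @ beta, used

    out: dict[str, ResidualMatrix] = {}
    if scope == "pooled":
        resid, used = _fit(Y_all, C_all)
        for g in groups:
            mask = labels == g
            out[g] = ResidualMatrix(g, list(ids[mask]), node_cols,
                                    resid[mask], used)
    else:
        for g in groups:
            mask = labels == g
            resid, used = _fit(Y_all[mask], C_all[mask])
            out[g] = ResidualMatrix(g, list(ids[mask]), node_cols, resid, used)
    return out


def build_group_network(res: ResidualMatrix) -> CovarianceNetwork:
    """Pearson correlation across subjects for every node pair, Fisher
    transformed.  r is clipped to +/-(1 - 1e-12) before atanh so that exactly
    collinear pairs yield a finite (large) z with a warning."""
    n = res.values.shape[0]
    if n < 4:
        raise ValueError(f"group {res.group!r} has fewer than 4 subjects")
    sd = res.values.std(axis=0)
    if (sd == 0).any():
        bad = [res.nodes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance node(s): {bad}")
    r = np.corrcoef(res.values, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    if (np.abs(r[off]) >= _R_CLIP).any():
        logger.warning("group %s: |r|=1 pair(s) clipped before Fisher transform",
                       res.group)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    np.fill_diagonal(r, 1.0)
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return CovarianceNetwork(res.group, list(res.nodes), r, z, n,
                             len(res.covariates_used))


# ---------------------------------------------------------------------------
# Density thresholding
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    """round() with exact halves away from zero, for bit-exact edge counts."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def rank_edges(z: np.ndarray, ranking: str = "signed") -> list[tuple[int, int]]:
    """Upper-triangle edges ranked by z descending (``signed``) or by \\|z\\|
    descending (``absolute``); ties broken by (smaller i, then smaller j)."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    key = z[iu, ju] if ranking == "signed" else np.abs(z[iu, ju])
    # stable sort on -key keeps (i, j) lexicographic order within ties
    order = np.argsort(-key, kind="stable")
    return list(zip(iu[order].tolist(), ju[order].tolist()))


def threshold_by_density(net: CovarianceNetwork, density: float,
                         ranking: str = "signed") -> np.ndarray:
    """Binary adjacency keeping the top round(d * N(N-1)/2) ranked edges."""
    if not (0 < density < 1):
        raise ValueError("density must lie in (0, 1)")
    n = len(net.nodes)
    m = _round_half_away(density * n * (n - 1) / 2)
    if m == 0:
        raise ValueError(f"density {density} yields zero edges for N={n}")
    edges = rank_edges(net.z_matrix, ranking)[:m]
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return adj


def sweep_densities(net: CovarianceNetwork, grid: np.ndarray,
                    ranking: str = "signed") -> ThresholdedGraphSet:
    """Nested graph family over the density grid (shared edge ranking)."""
    n = len(net.nodes)
    order = rank_edges(net.z_matrix, ranking)
    graphs = np.zeros((len(grid), n, n), dtype=bool)
    adj = np.zeros((n, n), dtype=bool)
    placed = 0
    for k, d in enumerate(np.sort(np.asarray(grid, dtype=float))):
        m = _round_half_away(float(d) * n * (n - 1) / 2)
        if m == 0:
            raise ValueError(f"density {d} yields zero edges for N={n}")
        while placed < m:
            i, j = order[placed]
            adj[i, j] = adj[j, i] = True
            placed += 1
        graphs[k] = adj
    return ThresholdedGraphSet(net.group, list(net.nodes),
                               np.sort(np.asarray(grid, dtype=float)), graphs, order)
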