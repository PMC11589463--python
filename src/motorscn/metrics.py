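"""Graph-theory measures on binary undirected graphs.

Global: global efficiency, mean local efficiency, assortativity, mean
clustering coefficient, characteristic path length, mean nodal and mean edge
betweenness, and the small-world triplet gamma/lambda/sigma against a
degree-preserving rewired null ensemble.  Nodal: degree, betweenness,
clustering, local efficiency and (given a partition) participation
coefficient.

All measures are implemented directly on numpy adjacency matrices (BFS via
boolean matrix products, Brandes betweenness) so that permutation inference,
which re-evaluates a 41-density sweep thousands of times, stays fast.  The
test-suite checks every measure against networkx and against brute-force
enumeration oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger("motorscn")

GLOBAL_METRIC_NAMES = (
    "global_efficiency", "mean_local_efficiency", "assortativity",
    "mean_clustering", "char_path_length", "mean_nodal_betweenness",
    "mean_edge_betweenness",
)
NODAL_METRIC_NAMES = (
    "degree", "betweenness", "clustering", "local_efficiency", "participation",
)


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    adj = adj.astype(bool)
    if np.diag(adj).any():
        raise ValueError("adjacency must be hollow (no self-loops)")
    if not (adj == adj.T).all():
        raise ValueError("adjacency must be symmetric")
    return adj


def shortest_path_lengths(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by BFS over boolean matrix products.

    Returns a float matrix with inf for disconnected pairs and 0 diagonal.
    """
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    D = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    reach = adj | np.eye(n, dtype=bool)
    frontier = adj.copy()
    d = 1
    a8 = adj.astype(np.uint8)
    while frontier.any():
        nxt = (frontier.astype(np.uint8) @ a8) > 0
        new = nxt & ~reach
        if not new.any():
            break
        d += 1
        D[new] = d
        reach |= new
        frontier = new
    return D


def global_efficiency(adj: np.ndarray) -> float:
    """Mean over ordered node pairs of 1/shortest-path (0 if disconnected)."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    D = shortest_path_lengths(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & off, 1.0 / np.where(D > 0, D, np.inf), 0.0)
    return float(inv[off].mean())


def char_path_length(adj: np.ndarray) -> float:
    """Mean shortest path over connected ordered pairs; NaN if no edges."""
    n = adj.shape[0]
    D = shortest_path_lengths(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        logger.warning("graph has no connected pairs; path length undefined")
        return float("nan")
    return float(D[finite].mean())


def clustering_coefficients(adj: np.ndarray) -> np.ndarray:
    """Per-node triangle density; 0 for nodes of degree < 2."""
    a = np.asarray(adj, dtype=float)
    deg = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)   # 2 x triangles per node... (=2T)
    possible = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, tri2 / possible, 0.0)
    return c


def degree_assortativity(adj: np.ndarray) -> float:
    """Pearson correlation of degrees across edge endpoints (both orders)."""
    adj = np.asarray(adj, dtype=bool)
    deg = adj.sum(axis=1)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    if len(iu) == 0:
        return float("nan")
    x = np.concatenate([deg[iu], deg[ju]]).astype(float)
    y = np.concatenate([deg[ju], deg[iu]]).astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def local_efficiencies(adj: np.ndarray) -> np.ndarray:
    """Per node: global efficiency of the subgraph induced by its neighbours
    (0 for degree < 2)."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if len(nb) < 2:
            continue
        out[i] = global_efficiency(adj[np.ix_(nb, nb)])
    return out


def betweenness(adj: np.ndarray) -> tuple[np.ndarray, dict[tuple[int, int], float]]:
    """Unnormalised node and edge betweenness (Brandes, unweighted).

    Shortest-path multiplicity is split evenly; each unordered pair is
    counted once (undirected convention: accumulate over all sources, halve).
    """
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    nbrs = [np.flatnonzero(adj[i]) for i in range(n)]
    cb = np.zeros(n)
    ceb: dict[tuple[int, int], float] = {}
    for s in range(n):
        # single-source BFS with path counting
        dist = np.full(n, -1)
        sigma = np.zeros(n)
        dist[s], sigma[s] = 0, 1.0
        order = [s]
        preds: list[list[int]] = [[] for _ in range(n)]
        head = 0
        while head < len(order):
            v = order[head]
            head += 1
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    order.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                c = sigma[v] / sigma[w] * (1.0 + delta[w])
                e = (v, w) if v < w else (w, v)
                ceb[e] = ceb.get(e, 0.0) + c
                delta[v] += c
            if w != s:
                cb[w] += delta[w]
    cb /= 2.0
    ceb = {e: v / 2.0 for e, v in ceb.items()}
    return cb, ceb


def participation_coefficients(adj: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """1 - sum_m (k_im / k_i)^2 over modules m; 0 for isolated nodes."""
    adj = np.asarray(adj, dtype=float)
    partition = np.asarray(partition)
    deg = adj.sum(axis=1)
    out = np.zeros(adj.shape[0])
    mask = deg > 0
    for mod in np.unique(partition):
        k_im = adj[:, partition == mod].sum(axis=1)
        out[mask] += (k_im[mask] / deg[mask]) ** 2
    return np.where(mask, 1.0 - out, 0.0)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class GlobalMetrics:
    density: float
    global_efficiency: float
    mean_local_efficiency: float
    assortativity: float
    mean_clustering: float
    char_path_length: float
    mean_nodal_betweenness: float
    mean_edge_betweenness: float
    gamma: float = float("nan")
    lam: float = float("nan")
    sigma: float = float("nan")


@dataclass
class NodalMetrics:
    nodes: list[str]
    degree: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    participation: np.ndarray | None = None


def global_metrics(adj: np.ndarray,
                   metrics: tuple[str, ...] = GLOBAL_METRIC_NAMES) -> GlobalMetrics:
    """Un-normalised global measures on one binary graph."""
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    density = float(adj.sum() / 2) / (n * (n - 1) / 2) if n > 1 else 0.0
    want = set(metrics)
    nan = float("nan")
    ge = global_efficiency(adj) if "global_efficiency" in want else nan
    le = float(local_efficiencies(adj).mean()) if "mean_local_efficiency" in want else nan
    asr = degree_assortativity(adj) if "assortativity" in want else nan
    mc = float(clustering_coefficients(adj).mean()) if "mean_clustering" in want else nan
    cpl = char_path_length(adj) if "char_path_length" in want else nan
    mnb = menb = nan
    if "mean_nodal_betweenness" in want or "mean_edge_betweenness" in want:
        cb, ceb = betweenness(adj)
        mnb = float(cb.mean())
        menb = float(np.mean(list(ceb.values()))) if ceb else nan
    return GlobalMetrics(density, ge, le, asr, mc, cpl, mnb, menb)


def nodal_metrics(adj: np.ndarray, nodes: list[str] | None = None,
                  partition: np.ndarray | None = None) -> NodalMetrics:
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    nodes = nodes or [str(i) for i in range(n)]
    cb, _ = betweenness(adj)
    part = None
    if partition is not None:
        part = participation_coefficients(adj, partition)
    return NodalMetrics(nodes=nodes,
                        degree=adj.sum(axis=1).astype(float),
                        betweenness=cb,
                        clustering=clustering_coefficients(adj),
                        local_efficiency=local_efficiencies(adj),
                        participation=part)


# ---------------------------------------------------------------------------
# Small-world normalisation
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """Degree-preserving rewired ensemble (Maslov-Sneppen double-edge swaps,
    10x|E| swaps per null; rewires that disconnect a connected original are
    retried up to ``max_retries``)."""
    n_null: int
    c_null: np.ndarray
    l_null: np.ndarray
    seed: int | None = None

    @property
    def c_rand(self) -> float:
        return float(self.c_null.mean())

    @property
    def l_rand(self) -> float:
        return float(self.l_null.mean())


def null_ensemble(adj: np.ndarray, n_null: int = 100,
                  rng: np.random.Generator | int | None = None,
                  max_retries: int = 50) -> NullEnsemble:
    adj = _check_adjacency(adj)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    G = nx.from_numpy_array(adj.astype(int))
    n_edges = G.number_of_edges()
    was_connected = nx.is_connected(G) if len(G) else False
    cs, ls = np.empty(n_null), np.empty(n_null)
    for k in range(n_null):
        ok = False
        for _ in range(max_retries):
            H = G.copy()
            seed = int(rng.integers(0, 2**31 - 1))
            try:
                nx.double_edge_swap(H, nswap=10 * n_edges,
                                    max_tries=200 * n_edges, seed=seed)
            except nx.NetworkXError:
                continue
            if was_connected and not nx.is_connected(H):
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"null graph generation failed after {max_retries} retries "
                f"(|V|={len(G)}, |E|={n_edges})")
        a = nx.to_numpy_array(H, dtype=bool)
        cs[k] = clustering_coefficients(a).mean()
        ls[k] = char_path_length(a)
    return NullEnsemble(n_null=n_null, c_null=cs, l_null=ls)


def small_world_normalize(adj: np.ndarray,
                          ens: NullEnsemble) -> tuple[float, float, float]:
    """gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda."""
    adj = _check_adjacency(adj)
    D = shortest_path_lengths(adj)
    n = adj.shape[0]
    off = ~np.eye(n, dtype=bool)
    n_unreached = int((~np.isfinite(D[off])).sum()) // 2
    if n_unreached > 0.1 * n * (n - 1) / 2:
        logger.warning("graph largely disconnected (%d unreachable pairs); "
                       "small-world indices unreliable", n_unreached)
    c = float(clustering_coefficients(adj).mean())
    l = char_path_length(adj)
    gamma = c / ens.c_rand if ens.c_rand > 0 else float("nan")
    lam = l / ens.l_rand if ens.l_rand > 0 else float("nan")
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else float("nan")
    return gamma, lam, sigma


# ---------------------------------------------------------------------------
# AUC aggregation over the density sweep
# ---------------------------------------------------------------------------

def auc_over_densities(values: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal integral of a metric curve divided by the grid span
    (a density-averaged value).  Non-finite points are excluded pairwise;
    returns NaN if fewer than two finite points remain."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() == 0:
        logger.warning("all-non-finite metric curve; AUC flagged missing")
        return float("nan")
    if finite.sum() == 1:
        return float(values[finite][0])
    if not finite.all():
        logger.info("AUC: excluded %d non-finite point(s)", int((~finite).sum()))
    v, g = values[finite], grid[finite]
    span = g[-1] - g[0]
    if span == 0:
        return float(v.mean())
    return float(np.trapezoid(v, g) / span)


def global_metric_curves(graphs: np.ndarray, grid: np.ndarray,
                         metrics: tuple[str, ...] = GLOBAL_METRIC_NAMES
                         ) -> dict[str, np.ndarray]:
    """One value per density for each requested global metric."""
    out = {m: np.empty(len(grid)) for m in metrics}
    for k in range(len(grid)):
        gm = global_metrics(graphs[k], metrics=tuple(metrics))
        for m in metrics:
            out[m][k] = getattr(gm, m)
    return out


def nodal_metric_curves(graphs: np.ndarray, grid: np.ndarray,
                        partition: np.ndarray | None = None,
                        metrics: tuple[str, ...] = NODAL_METRIC_NAMES
                        ) -> dict[str, np.ndarray]:
    """(n_densities, N) array per requested nodal metric."""
    n = graphs.shape[1]
    wanted = [m for m in metrics if m != "participation" or partition is not None]
    out = {m: np.empty((len(grid), n)) for m in wanted}
    for k in range(len(grid)):
        nm = nodal_metrics(graphs[k], partition=partition)
        for m in wanted:
            out[m][k] = getattr(nm, m)
    return out


def auc_global_metrics(graphs: np.ndarray, grid: np.ndarray,
                       metrics: tuple[str, ...] = GLOBAL_METRIC_NAMES
                       ) -> dict[str, float]:
    curves = global_metric_curves(graphs, grid, metrics)
    return {m: auc_over_densities(v, grid) for m, v in curves.items()}


def auc_nodal_metrics(graphs: np.ndarray, grid: np.ndarray,
                      partition: np.ndarray | None = None,
                      metrics: tuple[str, ...] = NODAL_METRIC_NAMES
                      ) -> dict[str, np.ndarray]:
    curves = nodal_metric_curves(graphs, grid, partition, metrics)
    return {m: np.array([auc_over_densities(v[:, i], grid)
                         for i in range(v.shape[1])])
            for m, v in curves.items()}
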