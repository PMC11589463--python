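"""Brute-force oracles, independent of the package implementation.

Distances by Floyd-Warshall; clustering by triple enumeration; betweenness by
exhaustive simple-path enumeration; components by union-find; chi-square by
the four-cell textbook formula.  Intended for tiny graphs (<= 7 nodes).
"""

from itertools import combinations, permutations

import numpy as np


def floyd_warshall(adj):
    n = len(adj)
    D = [[0 if i == j else (1 if adj[i][j] else float("inf"))
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    return D


def global_efficiency(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    D = floyd_warshall(adj)
    total = sum(1.0 / D[i][j] for i in range(n) for j in range(n)
                if i != j and D[i][j] < float("inf"))
    return total / (n * (n - 1))


def char_path_length(adj):
    n = len(adj)
    D = floyd_warshall(adj)
    vals = [D[i][j] for i in range(n) for j in range(n)
            if i != j and D[i][j] < float("inf")]
    return sum(vals) / len(vals) if vals else float("nan")


def clustering(adj):
    """Per-node clustering by explicit triple enumeration."""
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        tri = sum(1 for a, b in combinations(nbrs, 2) if adj[a][b])
        out.append(tri / (k * (k - 1) / 2))
    return out


def local_efficiency(adj):
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        out.append(global_efficiency(sub))
    return out


def assortativity(adj):
    n = len(adj)
    deg = [sum(adj[i]) for i in range(n)]
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i][j]:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
    if not xs:
        return float("nan")
    x, y = np.array(xs, float), np.array(ys, float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def betweenness_by_path_enumeration(adj):
    """Node and edge betweenness from exhaustive simple-path enumeration.

    For every unordered pair (s, t): enumerate all simple paths, keep the
    shortest ones, and credit each interior node / each edge with
    (paths through it) / (number of shortest paths).
    """
    n = len(adj)
    nodes = list(range(n))
    cb = [0.0] * n
    ceb = {}
    for s, t in combinations(nodes, 2):
        paths = []
        others = [v for v in nodes if v not in (s, t)]
        for k in range(len(others) + 1):
            for mid in permutations(others, k):
                seq = (s, *mid, t)
                if all(adj[a][b] for a, b in zip(seq, seq[1:])):
                    paths.append(seq)
            if paths:
                break  # shorter paths found; longer ones are not shortest
        if not paths:
            continue
        w = 1.0 / len(paths)
        for seq in paths:
            for v in seq[1:-1]:
                cb[v] += w
            for a, b in zip(seq, seq[1:]):
                e = (a, b) if a < b else (b, a)
                ceb[e] = ceb.get(e, 0.0) + w
    return cb, ceb


def participation(adj, part):
    n = len(adj)
    out = []
    for i in range(n):
        k = sum(adj[i])
        if k == 0:
            out.append(0.0)
            continue
        s = 0.0
        for mod in set(part):
            k_im = sum(adj[i][j] for j in range(n) if part[j] == mod)
            s += (k_im / k) ** 2
        out.append(1.0 - s)
    return out


def union_find_components(mask):
    """Edge lists of connected components of a boolean adjacency matrix."""
    n = len(mask)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if mask[i][j]]
    for i, j in edges:
        parent[find(i)] = find(j)
    comps = {}
    for i, j in edges:
        comps.setdefault(find(i), []).append((i, j))
    return sorted(comps.values(), key=len, reverse=True)


def chi_square_four_cell(a, b, c, d):
    """Pearson chi-square from the explicit O/E loop over the four cells."""
    obs = [[a, b], [c, d]]
    total = a + b + c + d
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / total
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def trapezoid_average(values, grid):
    total = 0.0
    for k in range(len(grid) - 1):
        total += (values[k] + values[k + 1]) / 2.0 * (grid[k + 1] - grid[k])
    span = grid[-1] - grid[0]
    return total / span if span else sum(values) / len(values)


def partial_corr_inverse_matrix(x, y, covars):
    """Partial correlation via the inverse-correlation-matrix identity."""
    M = np.column_stack([x, y, covars])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


def random_graph(n, p, rng):
    """Symmetric hollow boolean adjacency as nested lists."""
    a = np.triu(rng.random((n, n)) < p, 1)
    a = a | a.T
    return a.astype(bool)
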