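"""Independent brute-force reference implementations for tests.

Deliberately naive: triangle enumeration, Floyd-Warshall distances with
shortest-path counting, direct definition of each statistic.  These share no
code with the package and serve as oracles for the vectorised routines.
"""

from itertools import combinations

import numpy as np

INF = float("inf")


def lengths(adj: np.ndarray, mode: str) -> np.ndarray:
    n = adj.shape[0]
    L = np.full((n, n), INF)
    for i in range(n):
        L[i, i] = 0.0
        for j in range(n):
            if i != j and adj[i, j] > 0:
                L[i, j] = 1.0 if mode == "binary" else 1.0 / adj[i, j]
    return L


def floyd_warshall(adj: np.ndarray, mode: str) -> np.ndarray:
    d = lengths(adj, mode)
    n = adj.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(adj: np.ndarray, mode: str) -> np.ndarray:
    """Per-node clustering: binary triangle count or Onnela geometric mean."""
    n = adj.shape[0]
    mx = adj.max()
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        t = 0.0
        for u, v in combinations(nbrs, 2):
            if adj[u, v] > 0:
                if mode == "binary":
                    t += 1.0
                else:
                    t += (adj[i, u] / mx * adj[i, v] / mx * adj[u, v] / mx) ** (1 / 3)
        out[i] = 2 * t / (k * (k - 1))
    return out


def brute_lp_eglob_nodal(adj: np.ndarray, mode: str):
    d = floyd_warshall(adj, mode)
    n = adj.shape[0]
    dists, invs = [], []
    nodal = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i == j:
                continue
            if d[i, j] < INF:
                dists.append(d[i, j])
                invs.append(1.0 / d[i, j])
                acc += 1.0 / d[i, j]
            else:
                invs.append(0.0)
        nodal[i] = acc / (n - 1) if n > 1 else 0.0
    lp = float(np.mean(dists)) if dists else INF
    eglob = float(np.mean(invs)) if invs else 0.0
    return lp, eglob, nodal


def brute_local_efficiency(adj: np.ndarray, mode: str) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        _, eg, _ = brute_lp_eglob_nodal(sub, mode)
        out[i] = eg
    return out


def brute_betweenness(adj: np.ndarray, mode: str) -> np.ndarray:
    """Floyd-Warshall with shortest-path counting, then the pair-sum
    definition of (unnormalised, undirected) betweenness."""
    n = adj.shape[0]
    d = lengths(adj, mode)
    sigma = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < INF:
                sigma[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if i == j or i == k or j == k:
                    continue
                via = d[i, k] + d[k, j]
                if via == INF:
                    continue
                if via < d[i, j] - 1e-12:
                    d[i, j] = via
                    sigma[i, j] = sigma[i, k] * sigma[k, j]
                elif d[i, j] < INF and abs(via - d[i, j]) <= 1e-12:
                    sigma[i, j] += sigma[i, k] * sigma[k, j]
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or d[s, t] == INF or sigma[s, t] == 0:
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) <= 1e-12:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def brute_bh(p: np.ndarray, q: float):
    """Benjamini-Hochberg step-up straight from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def brute_partial_r(x, y, cov):
    """Partial correlation by explicit residualisation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    design = np.column_stack([np.ones(len(x)), cov])
    proj = design @ np.linalg.pinv(design)
    rx, ry = x - proj @ x, y - proj @ y
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_kls(p: np.ndarray, q: np.ndarray, floor: float = 1e-10) -> float:
    """Direct-summation KLS on raw mass vectors."""
    pf = np.maximum(np.asarray(p, float), floor)
    qf = np.maximum(np.asarray(q, float), floor)
    pf, qf = pf / pf.sum(), qf / qf.sum()
    d = 0.0
    for pi, qi in zip(pf, qf):
        d += pi * np.log(pi / qi) + qi * np.log(qi / pi)
    return float(np.exp(-d))
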