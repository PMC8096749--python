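"""Sparsity thresholding and graph-theoretic network metrics.

Weighted similarity networks are thresholded over a sparsity range (the
fraction of strongest possible edges retained) and characterised by:

* global metrics — clustering coefficient ``Cp``, characteristic path length
  ``Lp``, global and local efficiency ``Eglob``/``Eloc``, and the small-world
  indices ``gamma = Cp / Cp_random``, ``lambda = Lp / Lp_random`` and
  ``sigma = gamma / lambda`` against degree-preserving rewired null networks;
* nodal metrics — betweenness, degree (strength), and nodal efficiency.

Each metric's curve over the sparsity window is summarised by its trapezoidal
area under the curve (AUC).  Path-based metrics use the distance transform
``length = 1 / weight``; disconnected pairs are excluded from ``Lp`` and
contribute zero to efficiencies.

Most routines are vectorised over the dense 90x90 adjacency (matrix-product
triangle counts, ``scipy.sparse.csgraph`` Dijkstra) because the null-model
ensemble — subjects x sparsities x 100 rewired graphs — dominates runtime.
Betweenness uses networkx's Brandes algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse.csgraph import shortest_path

from .network import MorphNetwork

#: default sparsity window: 0.10 to 0.34 in steps of 0.01
DEFAULT_SPARSITIES = np.round(np.arange(0.10, 0.34 + 1e-9, 0.01), 2)
GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = ("betweenness", "degree", "efficiency")


@dataclass
class ThresholdedGraph:
    """A network restricted to its K strongest edges at sparsity S."""

    sparsity: float
    adjacency: np.ndarray  # symmetric weighted, zero diagonal

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency) // 2)


def threshold_by_sparsity(
    net: MorphNetwork | np.ndarray, sparsity: float
) -> ThresholdedGraph:
    """Retain the K = round(S * n_pairs) strongest off-diagonal edges.

    Rounding is round-half-even; ties in weight are broken deterministically
    by ascending (i, j) node-index pair.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    w = net.weights if isinstance(net, MorphNetwork) else np.asarray(net, float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    k = round(sparsity * vals.size)
    order = np.lexsort((ju, iu, -vals))[:k]
    adj = np.zeros_like(w)
    adj[iu[order], ju[order]] = vals[order]
    adj += adj.T
    return ThresholdedGraph(sparsity, adj)


# ---------------------------------------------------------------------------
# individual metrics
# ---------------------------------------------------------------------------


def clustering_coefficient(
    g: ThresholdedGraph | np.ndarray, mode: str = "weighted"
) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean Cp.

    binary mode: c_i = 2 t_i / (k_i (k_i - 1)) with t_i the number of
    triangles around node i; nodes with degree < 2 contribute 0.
    weighted mode: Onnela's generalisation — triangle counts are replaced by
    geometric means of triangle weights after scaling by the maximum weight.
    """
    adj = g.adjacency if isinstance(g, ThresholdedGraph) else np.asarray(g, float)
    a = (adj > 0).astype(float)
    k = a.sum(axis=1)
    if mode == "binary":
        t = np.diag(a @ a @ a) / 2.0
    elif mode == "weighted":
        mx = adj.max()
        w = np.cbrt(adj / mx) if mx > 0 else adj
        t = np.diag(w @ w @ w) / 2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2 * t / denom, 0.0)
    return c, float(c.mean())


def _length_matrix(adj: np.ndarray, mode: str) -> np.ndarray:
    """Edge length matrix for path metrics (0 = no edge)."""
    if mode == "binary":
        return (adj > 0).astype(float)
    with np.errstate(divide="ignore"):
        return np.where(adj > 0, 1.0 / adj, 0.0)


def _distances(adj: np.ndarray, mode: str) -> np.ndarray:
    return shortest_path(_length_matrix(adj, mode), method="D", directed=False)


def path_length_and_efficiency(
    g: ThresholdedGraph | np.ndarray, mode: str = "weighted"
) -> tuple[float, float, np.ndarray]:
    """(Lp, Eglob, per-node efficiency) from shortest-path distances.

    Lp averages distances over connected ordered pairs only; efficiencies
    average 1/distance over all ordered pairs with disconnected pairs
    contributing zero.
    """
    adj = g.adjacency if isinstance(g, ThresholdedGraph) else np.asarray(g, float)
    n = adj.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    d = _distances(adj, mode)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = float(d[finite].mean()) if finite.any() else np.inf
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / d, 0.0)
    eglob = float(inv[off].mean()) if n > 1 else 0.0
    nodal_eff = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    return lp, eglob, nodal_eff


def _subgraph_efficiency(adj: np.ndarray, mode: str) -> float:
    m = adj.shape[0]
    if m < 2:
        return 0.0
    d = _distances(adj, mode)
    off = ~np.eye(m, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(
    g: ThresholdedGraph | np.ndarray, mode: str = "weighted"
) -> tuple[np.ndarray, float]:
    """Per-node and mean local efficiency.

    The local efficiency of node i is the global efficiency of the subgraph
    induced by i's neighbours (i itself removed).
    """
    adj = g.adjacency if isinstance(g, ThresholdedGraph) else np.asarray(g, float)
    n = adj.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i] > 0)
        if nb.size >= 2:
            eloc[i] = _subgraph_efficiency(adj[np.ix_(nb, nb)], mode)
    return eloc, float(eloc.mean())


def betweenness(
    g: ThresholdedGraph | np.ndarray, mode: str = "weighted"
) -> np.ndarray:
    """Unnormalised shortest-path betweenness (Brandes) on 1/weight lengths."""
    adj = g.adjacency if isinstance(g, ThresholdedGraph) else np.asarray(g, float)
    n = adj.shape[0]
    graph = nx.from_numpy_array(_length_matrix(adj, mode))
    bc = nx.betweenness_centrality(
        graph, normalized=False, weight=None if mode == "binary" else "weight"
    )
    return np.array([bc[i] for i in range(n)])


def nodal_degree(
    g: ThresholdedGraph | np.ndarray, mode: str = "weighted"
) -> np.ndarray:
    """Binary degree (edge count) or weighted degree (strength)."""
    adj = g.adjacency if isinstance(g, ThresholdedGraph) else np.asarray(g, float)
    if mode == "binary":
        return (adj > 0).sum(axis=1).astype(float)
    return adj.sum(axis=1)


# ---------------------------------------------------------------------------
# degree-preserving null networks
# ---------------------------------------------------------------------------


@njit(cache=True)
def _swap_edges(u, v, adj, n_attempts, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    m = u.shape[0]
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        u[e1], v[e1] = a, d
        u[e2], v[e2] = c, b


def rewired_null(
    g: ThresholdedGraph, seed: int, swap_factor: int = 10
) -> np.ndarray:
    """One Maslov-Sneppen rewired adjacency: degrees preserved exactly,
    weights carried with the swapped edges (same weight multiset)."""
    adj = g.adjacency
    iu, ju = np.nonzero(np.triu(adj, k=1))
    w = adj[iu, ju].copy()
    if iu.size < 2:
        raise ValueError("too few edges to rewire")
    u = iu.astype(np.int64).copy()
    v = ju.astype(np.int64).copy()
    mask = adj > 0
    _swap_edges(u, v, mask.copy(), swap_factor * u.size, seed % (2**31 - 1))
    out = np.zeros_like(adj)
    out[u, v] = w
    out[v, u] = w
    return out


def random_reference(
    g: ThresholdedGraph,
    n_null: int = 100,
    seed: int = 0,
    mode: str = "weighted",
    swap_factor: int = 10,
) -> tuple[float, float]:
    """Null-ensemble means (Cp_random, Lp_random) over rewired networks."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    cps, lps = np.empty(n_null), np.empty(n_null)
    for i in range(n_null):
        null = rewired_null(g, int(rng.integers(2**31 - 1)), swap_factor)
        _, cps[i] = clustering_coefficient(null, mode)
        lps[i], _, _ = path_length_and_efficiency(null, mode)
    return float(cps.mean()), float(lps.mean())


def small_world_indices(
    cp: np.ndarray, lp: np.ndarray, cp_random: np.ndarray, lp_random: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gamma, lambda, sigma) = (Cp/Cp_rand, Lp/Lp_rand, gamma/lambda)."""
    gamma = np.asarray(cp, float) / np.asarray(cp_random, float)
    lam = np.asarray(lp, float) / np.asarray(lp_random, float)
    return gamma, lam, gamma / lam


# ---------------------------------------------------------------------------
# curves, AUC, sparsity selection, hubs
# ---------------------------------------------------------------------------


def global_metric_curves(
    net: MorphNetwork,
    sparsities: np.ndarray = DEFAULT_SPARSITIES,
    mode: str = "weighted",
    n_null: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """All seven global metric curves for one subject (rows = sparsity)."""
    rows = []
    for s_i, s in enumerate(sparsities):
        g = threshold_by_sparsity(net, float(s))
        _, cp = clustering_coefficient(g, mode)
        lp, eglob, _ = path_length_and_efficiency(g, mode)
        _, eloc = local_efficiency(g, mode)
        cpr, lpr = random_reference(g, n_null, seed + 1000 * s_i, mode)
        gamma, lam, sigma = small_world_indices(cp, lp, cpr, lpr)
        rows.append(dict(sparsity=float(s), Cp=cp, Lp=lp, Eglob=eglob,
                         Eloc=eloc, gamma=float(gamma), **{"lambda": float(lam)},
                         sigma=float(sigma)))
    return pd.DataFrame(rows).set_index("sparsity")


def nodal_metric_curves(
    net: MorphNetwork,
    sparsities: np.ndarray = DEFAULT_SPARSITIES,
    mode: str = "weighted",
) -> dict[str, np.ndarray]:
    """Nodal betweenness/degree/efficiency, each (n_nodes, n_sparsities)."""
    n = net.n_nodes
    out = {m: np.zeros((n, len(sparsities))) for m in NODAL_METRICS}
    for s_i, s in enumerate(sparsities):
        g = threshold_by_sparsity(net, float(s))
        out["betweenness"][:, s_i] = betweenness(g, mode)
        out["degree"][:, s_i] = nodal_degree(g, mode)
        _, _, ne = path_length_and_efficiency(g, mode)
        out["efficiency"][:, s_i] = ne
    return out


def auc(values: np.ndarray, sparsities: np.ndarray = DEFAULT_SPARSITIES) -> float:
    """Trapezoidal area under a metric curve over the sparsity window."""
    values = np.asarray(values, float)
    sparsities = np.asarray(sparsities, float)
    if values.shape[-1] != sparsities.size or sparsities.size < 2:
        raise ValueError("need >= 2 curve points matching the sparsity grid")
    return np.trapezoid(values, sparsities, axis=-1)


def select_sparsity_range(
    networks: list[MorphNetwork],
    sparsities: np.ndarray = DEFAULT_SPARSITIES,
    degree_rule: float | None = None,
    sigma_min: float = 1.1,
    mode: str = "weighted",
    n_null: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Smallest and largest sparsity satisfying both admissibility criteria.

    (a) the mean binary degree of every thresholded network exceeds
    ``degree_rule`` (default 2 ln N); (b) small-worldness sigma exceeds
    ``sigma_min`` for every subject.  ``sigma_min=0`` disables criterion (b)
    and no null networks are built.
    """
    if not networks:
        raise ValueError("need at least one subject network")
    n = networks[0].n_nodes
    if degree_rule is None:
        degree_rule = 2 * np.log(n)
    n_pairs = n * (n - 1) // 2
    ok = np.ones(len(sparsities), dtype=bool)
    for s_i, s in enumerate(sparsities):
        k = round(float(s) * n_pairs)
        if 2 * k / n <= degree_rule:
            ok[s_i] = False
    if sigma_min > 0:
        for net in networks:
            for s_i, s in enumerate(sparsities):
                if not ok[s_i]:
                    continue
                g = threshold_by_sparsity(net, float(s))
                _, cp = clustering_coefficient(g, mode)
                lp, _, _ = path_length_and_efficiency(g, mode)
                cpr, lpr = random_reference(g, n_null, seed + 1000 * s_i, mode)
                _, _, sigma = small_world_indices(cp, lp, cpr, lpr)
                if not sigma > sigma_min:
                    ok[s_i] = False
    if not ok.any():
        raise ValueError("no admissible sparsity in the grid")
    idx = np.flatnonzero(ok)
    return float(sparsities[idx[0]]), float(sparsities[idx[-1]])


def hub_scores(
    nodal_aucs: dict[str, np.ndarray],
    node_labels: list[str] | None = None,
    top_fraction: float = 0.10,
    hub_threshold: int = 2,
) -> pd.DataFrame:
    """Hub table from group-level nodal AUCs.

    For each of the three nodal metrics the top 10% of nodes (9 of 90) by
    group-mean AUC are flagged; a node's hub score (0-3) counts the metrics
    in which it is flagged.  Rank-9 ties are broken by ascending node index.
    """
    means = {}
    for m in NODAL_METRICS:
        v = np.asarray(nodal_aucs[m], float)
        means[m] = v.mean(axis=0) if v.ndim == 2 else v
    n = means[NODAL_METRICS[0]].size
    n_top = int(round(top_fraction * n))
    score = np.zeros(n, dtype=int)
    flags = {}
    for m, v in means.items():
        order = np.lexsort((np.arange(n), -v))[:n_top]
        f = np.zeros(n, dtype=bool)
        f[order] = True
        flags[m] = f
        score += f
    labels = node_labels or [f"R{i + 1:02d}" for i in range(n)]
    df = pd.DataFrame({"region": labels, "hub_score": score,
                       "is_hub": score >= hub_threshold})
    for m in NODAL_METRICS:
        df[f"top_{m}"] = flags[m]
    return df


# ---------------------------------------------------------------------------
# cohort-level AUC tables
# ---------------------------------------------------------------------------


def cohort_global_aucs(
    networks: list[MorphNetwork],
    sparsities: np.ndarray = DEFAULT_SPARSITIES,
    mode: str = "weighted",
    n_null: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject AUC of each of the 7 global metrics (rows = subjects)."""
    rows = {}
    for i, net in enumerate(networks):
        curves = global_metric_curves(net, sparsities, mode, n_null, seed + i)
        rows[net.subject_id] = {m: auc(curves[m].to_numpy(), sparsities)
                                for m in GLOBAL_METRICS}
    return pd.DataFrame.from_dict(rows, orient="index")[list(GLOBAL_METRICS)]


def cohort_nodal_aucs(
    networks: list[MorphNetwork],
    sparsities: np.ndarray = DEFAULT_SPARSITIES,
    mode: str = "weighted",
) -> dict[str, pd.DataFrame]:
    """Per-subject nodal AUCs: metric -> (subjects x regions) DataFrame."""
    out = {m: [] for m in NODAL_METRICS}
    ids = []
    for net in networks:
        curves = nodal_metric_curves(net, sparsities, mode)
        ids.append(net.subject_id)
        for m in NODAL_METRICS:
            out[m].append(auc(curves[m], sparsities))
    labels = networks[0].node_labels
    return {m: pd.DataFrame(np.vstack(v), index=ids, columns=labels)
            for m, v in out.items()}
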