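"""Group-level inference on network metrics.

Implements the statistical battery used to compare patient and control
cohorts: nonparametric permutation tests on AUC metrics (5000 label
permutations by default), Benjamini-Hochberg FDR across regions for the
nodal metrics, Cohen's d effect sizes, partial correlation between nodal
metrics and clinical scores adjusting for age/gender/education, and a
network-based statistic (NBS) that localises altered connections via the
permutation null distribution of the maximal suprathreshold component size
(size = number of connections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .metrics import GLOBAL_METRICS, NODAL_METRICS


def _perm_group_masks(
    n_total: int, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_total) boolean masks assigning subjects to permuted group A."""
    u = rng.random((n_perm, n_total))
    idx = np.argpartition(u, n_a - 1, axis=1)[:, :n_a]
    masks = np.zeros((n_perm, n_total), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


def permutation_test_matrix(
    a: np.ndarray, b: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-tailed permutation tests of group mean differences.

    Statistic per column: mean(a) - mean(b).  Two-tailed p with add-one
    correction: (1 + #{|perm diff| >= |observed|}) / (n_perm + 1).
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    x = np.vstack([a, b])
    n_a, n = a.shape[0], x.shape[0]
    obs = a.mean(axis=0) - b.mean(axis=0)
    rng = np.random.default_rng(seed)
    masks = _perm_group_masks(n, n_a, n_perm, rng)
    tot = x.sum(axis=0)
    sum_a = masks.astype(float) @ x
    diffs = sum_a / n_a - (tot - sum_a) / (n - n_a)
    exceed = (np.abs(diffs) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return obs, p


def permutation_test(
    values_a, values_b, n_perm: int = 5000, seed: int = 0
) -> tuple[float, float]:
    """Two-tailed permutation test of the difference of group means."""
    d, p = permutation_test_matrix(
        np.asarray(values_a, float)[:, None],
        np.asarray(values_b, float)[:, None],
        n_perm,
        seed,
    )
    return float(d[0]), float(p[0])


def cohens_d(values_a, values_b) -> float:
    """(mean_a - mean_b) / pooled standard deviation."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted q-values)."""
    p = np.asarray(p_values, float)
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj


@dataclass
class PartialCorrelation:
    """Residual Pearson correlation after covariate adjustment."""

    r: float
    p: float
    n: int
    n_covariates: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def partial_correlation(x, y, covariates=None) -> PartialCorrelation:
    """Pearson correlation of x and y residualised on covariates.

    Both variables are regressed (least squares, with intercept) on the
    covariate matrix; the correlation of the residuals is tested against a
    t distribution with n - n_covariates - 2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if rx.std() == 0 or ry.std() == 0:
        # a variable fully explained by the covariates has no residual signal
        return PartialCorrelation(r=0.0, p=1.0, n=n, n_covariates=k)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) >= 1.0:
        p = 0.0
    else:
        t = r_c * np.sqrt(df / (1 - r_c**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r=r_c, p=p, n=n, n_covariates=k)


# ---------------------------------------------------------------------------
# network-based statistic
# ---------------------------------------------------------------------------


@dataclass
class NBSComponent:
    edges: list[tuple[int, int]]  # 0-based node index pairs
    size: int  # number of connections
    p_corrected: float


@dataclass
class NBSResult:
    direction: str
    primary_p: float
    components: list[NBSComponent] = field(default_factory=list)
    t_stats: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list[NBSComponent]:
        return [c for c in self.components if c.p_corrected < alpha]


def _edge_tstats(x: np.ndarray, masks: np.ndarray, n_a: int) -> np.ndarray:
    """Pooled-variance two-sample t statistics (A - B) for each permutation.

    x: (n_subjects, n_edges); masks: (n_perm, n_subjects) group-A selectors.
    """
    n = x.shape[0]
    n_b = n - n_a
    m = masks.astype(float)
    sum_a = m @ x
    sumsq_a = m @ (x**2)
    tot = x.sum(axis=0)
    totsq = (x**2).sum(axis=0)
    mean_a = sum_a / n_a
    mean_b = (tot - sum_a) / n_b
    ss_a = sumsq_a - n_a * mean_a**2
    ss_b = (totsq - sumsq_a) - n_b * mean_b**2
    sp2 = (ss_a + ss_b) / (n - 2)
    se = np.sqrt(np.maximum(sp2, 1e-300) * (1 / n_a + 1 / n_b))
    return (mean_a - mean_b) / se


def _components_from_edges(
    iu: np.ndarray, ju: np.ndarray, mask: np.ndarray, n_nodes: int
) -> list[list[int]]:
    """Connected components of the suprathreshold edge graph; returns lists
    of edge indices (into the upper-triangle order)."""
    e = np.flatnonzero(mask)
    if e.size == 0:
        return []
    g = coo_matrix(
        (np.ones(e.size), (iu[e], ju[e])), shape=(n_nodes, n_nodes)
    )
    n_comp, labels = connected_components(g, directed=False)
    comp_of_edge = labels[iu[e]]
    return [list(e[comp_of_edge == c]) for c in np.unique(comp_of_edge)]


def _max_component_sizes(
    tmat: np.ndarray, thresh: float, iu: np.ndarray, ju: np.ndarray, n_nodes: int
) -> np.ndarray:
    """Max suprathreshold component edge count for each row of t statistics."""
    out = np.zeros(tmat.shape[0], dtype=int)
    for i in range(tmat.shape[0]):
        comps = _components_from_edges(iu, ju, tmat[i] > thresh, n_nodes)
        if comps:
            out[i] = max(len(c) for c in comps)
    return out


def nbs(
    edges_a: np.ndarray,
    edges_b: np.ndarray,
    n_nodes: int,
    primary_p: float = 0.05,
    n_perm: int = 5000,
    direction: str = "decreased",
    seed: int = 0,
) -> NBSResult:
    """Network-based statistic over upper-triangle edge-weight matrices.

    Three steps: (1) edgewise pooled two-sample t tests thresholded at the
    one-tailed ``primary_p`` critical value in the requested direction
    ('decreased': group A < group B, 'increased': group A > group B);
    (2) connected components of the suprathreshold graph, sized by their
    number of connections; (3) for a component of size N, corrected
    p = proportion of permutations whose maximal component size is >= N.
    """
    if direction not in ("decreased", "increased"):
        raise ValueError("direction must be 'decreased' or 'increased'")
    if not 0 < primary_p < 1:
        raise ValueError("primary_p must be in (0, 1)")
    a = np.asarray(edges_a, float)
    b = np.asarray(edges_b, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("edge matrices must be 2-D with a shared edge axis")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    iu, ju = np.triu_indices(n_nodes, k=1)
    if iu.size != a.shape[1]:
        raise ValueError("edge axis does not match n_nodes upper triangle")
    sign = -1.0 if direction == "decreased" else 1.0
    x = np.vstack([a, b]) * sign
    n_a, n = a.shape[0], a.shape[0] + b.shape[0]
    t_crit = stats.t.isf(primary_p, df=n - 2)

    obs_mask = np.zeros((1, n), dtype=bool)
    obs_mask[0, :n_a] = True
    t_obs = _edge_tstats(x, obs_mask, n_a)[0]
    comps = _components_from_edges(iu, ju, t_obs > t_crit, n_nodes)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    block = 500
    done = 0
    while done < n_perm:
        nb_ = min(block, n_perm - done)
        masks = _perm_group_masks(n, n_a, nb_, rng)
        tmat = _edge_tstats(x, masks, n_a)
        null_max[done:done + nb_] = _max_component_sizes(
            tmat, t_crit, iu, ju, n_nodes)
        done += nb_

    components = []
    for comp in sorted(comps, key=len, reverse=True):
        size = len(comp)
        p_corr = float((null_max >= size).mean())
        edges = [(int(iu[e]), int(ju[e])) for e in comp]
        components.append(NBSComponent(edges=edges, size=size, p_corrected=p_corr))
    return NBSResult(direction=direction, primary_p=primary_p,
                     components=components, t_stats=t_obs * sign)


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------


@dataclass
class GroupComparisonReport:
    """Permutation tests + effect sizes for global and nodal AUC metrics."""

    global_table: pd.DataFrame  # 7 rows: metric, diff, p, d
    nodal_table: pd.DataFrame  # 270 rows: region x metric, p, q, d, significant
    altered_regions: pd.DataFrame  # regions significant in >= 1 nodal metric


def compare_groups(
    global_aucs_a: pd.DataFrame,
    global_aucs_b: pd.DataFrame,
    nodal_aucs_a: dict[str, pd.DataFrame],
    nodal_aucs_b: dict[str, pd.DataFrame],
    n_perm: int = 5000,
    seed: int = 0,
    q: float = 0.05,
    pool_fdr: bool = False,
) -> GroupComparisonReport:
    """Full group comparison: 7 global and 3 x 90 nodal permutation tests.

    FDR correction is applied per nodal metric across regions by default
    (``pool_fdr=True`` pools all 270 nodal tests instead); a region is
    listed as altered if it is significant in at least one nodal metric.
    """
    ga = global_aucs_a[list(GLOBAL_METRICS)].to_numpy()
    gb = global_aucs_b[list(GLOBAL_METRICS)].to_numpy()
    diffs, ps = permutation_test_matrix(ga, gb, n_perm, seed)
    ds = [cohens_d(ga[:, j], gb[:, j]) for j in range(ga.shape[1])]
    global_table = pd.DataFrame({
        "metric": list(GLOBAL_METRICS), "diff": diffs, "p": ps, "cohens_d": ds,
    }).set_index("metric")

    rows = []
    pvals = {}
    for m_i, m in enumerate(NODAL_METRICS):
        na = nodal_aucs_a[m].to_numpy()
        nbm = nodal_aucs_b[m].to_numpy()
        regions = list(nodal_aucs_a[m].columns)
        diffs, ps = permutation_test_matrix(na, nbm, n_perm, seed + 7919 * (m_i + 1))
        pvals[m] = ps
        for j, reg in enumerate(regions):
            rows.append(dict(region=reg, metric=m, diff=diffs[j], p=ps[j],
                             cohens_d=cohens_d(na[:, j], nbm[:, j])))
    nodal_table = pd.DataFrame(rows)
    if pool_fdr:
        rej, adj = fdr_correct(nodal_table["p"].to_numpy(), q)
        nodal_table["q"] = adj
        nodal_table["significant"] = rej
    else:
        nodal_table["q"] = np.nan
        nodal_table["significant"] = False
        for m in NODAL_METRICS:
            sel = nodal_table["metric"] == m
            rej, adj = fdr_correct(nodal_table.loc[sel, "p"].to_numpy(), q)
            nodal_table.loc[sel, "q"] = adj
            nodal_table.loc[sel, "significant"] = rej

    sig = nodal_table[nodal_table["significant"]]
    altered = (
        sig.groupby("region", sort=False)
        .agg(n_significant_metrics=("metric", "size"),
             metrics=("metric", lambda s: ",".join(s)))
        .reset_index()
    )
    return GroupComparisonReport(global_table, nodal_table, altered)
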