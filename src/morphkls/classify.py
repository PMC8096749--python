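"""Single-subject classification with a linear SVM.

Feature sets are either a subject's vectorised network (the 4005 upper-
triangle KLS weights) or the graph-metric AUC vector (7 global + 3 x 90
nodal values).  Classification uses a nested, stratified cross-validation:
an outer 5-fold split for evaluation and an inner grid search over the soft
margin parameter C in {1e-3 .. 1e4}.  Feature standardisation and C
selection happen strictly inside each outer training fold.  Significance is
assessed by repeating the whole procedure with permuted labels; region
importance by the mean absolute SVM weight across outer folds, aggregated to
regions for edge features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import GLOBAL_METRICS, NODAL_METRICS
from .network import MorphNetwork

DEFAULT_C_GRID = tuple(10.0**k for k in range(-3, 5))


@dataclass
class FeatureSet:
    """Subjects x features matrix plus a feature-to-region incidence map."""

    kind: str  # matrix_upper_triangle | graph_metric_aucs
    matrix: np.ndarray
    labels: np.ndarray
    feature_regions: list[tuple[int, ...]]  # region indices touched by a feature
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.labels = np.asarray(self.labels, int)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.labels.size:
            raise ValueError("matrix rows must match labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("features contain missing values")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(self.feature_regions) != self.matrix.shape[1]:
            raise ValueError("feature_regions must map every feature")


def features_from_networks(
    networks: list[MorphNetwork], labels: np.ndarray
) -> FeatureSet:
    """Upper-triangle edge weights (4005 features for 90 nodes)."""
    x = np.vstack([net.upper_triangle() for net in networks])
    n = networks[0].n_nodes
    iu, ju = np.triu_indices(n, k=1)
    regions = [(int(i), int(j)) for i, j in zip(iu, ju)]
    return FeatureSet("matrix_upper_triangle", x, labels, regions,
                      list(networks[0].node_labels))


def features_from_metric_aucs(
    global_aucs: pd.DataFrame,
    nodal_aucs: dict[str, pd.DataFrame],
    labels: np.ndarray,
) -> FeatureSet:
    """7 global + 270 nodal AUC features per subject."""
    blocks = [global_aucs[list(GLOBAL_METRICS)].to_numpy()]
    regions: list[tuple[int, ...]] = [() for _ in GLOBAL_METRICS]
    region_labels = list(nodal_aucs[NODAL_METRICS[0]].columns)
    for m in NODAL_METRICS:
        blocks.append(nodal_aucs[m].to_numpy())
        regions.extend((j,) for j in range(len(region_labels)))
    return FeatureSet("graph_metric_aucs", np.hstack(blocks), labels, regions,
                      region_labels)


@dataclass
class ClassifierConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    outer_folds: int = 5
    inner_folds: int = 5
    n_label_perms: int = 1000
    seed: int = 0
    add_one: bool = False  # add-one permutation p-value variant

    def __post_init__(self) -> None:
        if not self.c_grid:
            raise ValueError("C grid must be non-empty")


@dataclass
class ClassificationResult:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    fold_balanced_accuracy: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    fold_best_c: np.ndarray
    mean_abs_weights: np.ndarray
    permutation_p: float | None = None


def _fold_model(config: ClassifierConfig) -> GridSearchCV:
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="linear")),
    ])
    inner = StratifiedKFold(config.inner_folds, shuffle=True,
                            random_state=config.seed)
    return GridSearchCV(pipe, {"svc__C": list(config.c_grid)}, cv=inner,
                        scoring="balanced_accuracy", n_jobs=None)


def nested_cv_svm(
    features: FeatureSet, config: ClassifierConfig | None = None,
    labels: np.ndarray | None = None,
) -> ClassificationResult:
    """Nested stratified cross-validation of a linear SVM.

    Per outer fold: standardise on the training data, grid-search C by inner
    stratified CV, fit, and evaluate on the held-out fold.  Reported metrics
    are fold means; balanced accuracy = (sensitivity + specificity) / 2.
    """
    config = config or ClassifierConfig()
    y = features.labels if labels is None else np.asarray(labels, int)
    x = features.matrix
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.outer_folds:
        raise ValueError("need at least outer_folds subjects per class")
    outer = StratifiedKFold(config.outer_folds, shuffle=True,
                            random_state=config.seed)
    bacc, sens, spec, best_c = [], [], [], []
    weights = []
    for train, test in outer.split(x, y):
        gs = _fold_model(config)
        gs.fit(x[train], y[train])
        pred = gs.predict(x[test])
        yt = y[test]
        se = float((pred[yt == 1] == 1).mean())  # sensitivity: recall of class 1
        sp = float((pred[yt == 0] == 0).mean())  # specificity: recall of class 0
        sens.append(se)
        spec.append(sp)
        bacc.append((se + sp) / 2)
        best_c.append(gs.best_params_["svc__C"])
        weights.append(np.abs(gs.best_estimator_["svc"].coef_.ravel()))
    return ClassificationResult(
        balanced_accuracy=float(np.mean(bacc)),
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        fold_balanced_accuracy=np.array(bacc),
        fold_sensitivity=np.array(sens),
        fold_specificity=np.array(spec),
        fold_best_c=np.array(best_c),
        mean_abs_weights=np.mean(weights, axis=0),
    )


def permutation_significance(
    features: FeatureSet,
    config: ClassifierConfig | None = None,
    observed: ClassificationResult | None = None,
) -> tuple[float, np.ndarray]:
    """Label-permutation p-value for the classifier's balanced accuracy.

    The whole nested-CV procedure is repeated ``n_label_perms`` times on
    shuffled labels; p = (# permuted runs with balanced accuracy higher than
    the real one) / n_label_perms, or the add-one variant if configured.
    Returns (p, permuted balanced accuracies).
    """
    config = config or ClassifierConfig()
    if observed is None:
        observed = nested_cv_svm(features, config)
    rng = np.random.default_rng(config.seed)
    null = np.empty(config.n_label_perms)
    for i in range(config.n_label_perms):
        perm = rng.permutation(features.labels)
        null[i] = nested_cv_svm(features, config, labels=perm).balanced_accuracy
    higher = int((null > observed.balanced_accuracy).sum())
    if config.add_one:
        p = (higher + 1) / (config.n_label_perms + 1)
    else:
        p = higher / config.n_label_perms
    return float(p), null


@dataclass
class RegionRanking:
    table: pd.DataFrame  # rank, region, score
    degenerate: bool  # all weights zero


def region_contributions(
    result: ClassificationResult, features: FeatureSet, k: int = 20
) -> RegionRanking:
    """Top-k regions by fold-mean absolute SVM weight.

    Graph-metric features map directly to their region (global metrics carry
    no region); edge features contribute their weight to both incident
    regions (sum aggregation).
    """
    n_regions = len(features.region_labels)
    if k > n_regions:
        raise ValueError(f"k={k} exceeds {n_regions} regions")
    w = result.mean_abs_weights
    score = np.zeros(n_regions)
    for f, regs in enumerate(features.feature_regions):
        for r in regs:
            score[r] += w[f]
    degenerate = bool(np.allclose(w, 0))
    order = np.lexsort((np.arange(n_regions), -score))[:k]
    table = pd.DataFrame({
        "rank": np.arange(1, k + 1),
        "region": [features.region_labels[i] for i in order],
        "score": score[order],
    })
    return RegionRanking(table=table, degenerate=degenerate)
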