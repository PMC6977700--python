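"""Biomarker panel selection.

Two stages mirror a wrapper feature-selection design: (1) iterative
random-forest reduction — fit a bagged-tree ensemble, rank features by
out-of-bag (OOB) permutation importance, drop the lowest-scoring third,
repeat until a target count remains; (2) exhaustive subset search — every
non-empty subset of the survivors is evaluated by stratified 5-fold
cross-validated accuracy of an RBF-kernel support-vector classifier, and
the best subset is reported with its pooled-decision-value ROC AUC.
Sample structure is inspected independently by cutting a
complete-linkage hierarchical clustering at two clusters and reporting
label composition per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MAX_EXHAUSTIVE_FEATURES = 16


@dataclass
class PanelResult:
    features: list[str]
    cv_accuracy: float
    auc: float
    fold_assignments: np.ndarray
    classifier_params: dict
    n_subsets_evaluated: int
    subset_scores: pd.DataFrame = field(repr=False, default=None)


def _as_frame(X, feature_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_ids))


def oob_permutation_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int = 500, seed: int = 0
) -> np.ndarray:
    """Mean OOB-accuracy decrease per feature under column permutation.

    A hand-rolled bagged ensemble of decision trees (bootstrap per tree,
    sqrt-feature splits) is used so that each tree's out-of-bag samples
    are available: per tree, the OOB accuracy drop after permuting one
    feature column among the OOB rows is averaged across trees.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    counts = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size < 2 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        base = float(np.mean(tree.predict(X[oob]) == y[oob]))
        for j in range(p):
            perm = rng.permutation(oob.size)
            Xp = X[oob].copy()
            Xp[:, j] = Xp[perm, j]
            acc = float(np.mean(tree.predict(Xp) == y[oob]))
            drops[j] += base - acc
            counts[j] += 1
    return np.divide(drops, counts, out=np.zeros(p), where=counts > 0)


def importance_reduction(
    X,
    y: Sequence,
    target_k: int,
    seed: int = 0,
    n_trees: int = 500,
    feature_ids: Optional[Sequence[str]] = None,
) -> list[str]:
    """Iteratively drop the lowest-importance third until target_k remain.

    Each round fits a fresh ensemble on the surviving features, ranks them
    by OOB permutation importance, and removes the floor(current/3)
    lowest-scoring ones (never past target_k; always at least one while
    above target). Returns the surviving feature ids in their original
    order.
    """
    df = _as_frame(X, feature_ids)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain two classes")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    surviving = list(df.columns)
    rng = np.random.default_rng(seed)
    while len(surviving) > target_k:
        imp = oob_permutation_importance(
            df[surviving].to_numpy(), y, n_trees=n_trees,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        n_drop = min(max(len(surviving) // 3, 1), len(surviving) - target_k)
        order = np.argsort(imp, kind="stable")  # ascending importance
        drop = {surviving[i] for i in order[:n_drop]}
        surviving = [f for f in surviving if f not in drop]
    return surviving


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, fold_assignments: np.ndarray, params: dict
) -> tuple[float, np.ndarray]:
    """Pooled CV accuracy and pooled decision values over the test folds."""
    decision = np.empty(len(y))
    correct = 0
    for f in np.unique(fold_assignments):
        test = fold_assignments == f
        clf = SVC(**params)
        clf.fit(X[~test], y[~test])
        pred = clf.predict(X[test])
        correct += int(np.sum(pred == y[test]))
        decision[test] = clf.decision_function(X[test])
    return correct / len(y), decision


def exhaustive_panel_search(
    X,
    y: Sequence,
    features: Optional[Sequence[str]] = None,
    folds: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
    C: float = 1.0,
    force: bool = False,
) -> PanelResult:
    """Evaluate every non-empty feature subset by stratified k-fold CV.

    2^k - 1 subsets of the k candidate features are scored by pooled CV
    accuracy of an SVC (RBF kernel, C=1, kernel width gamma = 1/#subset
    features, matching the defaults of the classical SVM package family);
    ties are broken toward fewer features, then lexicographically. The
    returned panel carries the ROC AUC computed from decision values
    pooled across the test folds. Fold assignment is stratified, seeded,
    and shared by every subset.
    """
    df = _as_frame(X, None)
    y = np.asarray(y)
    feats = list(features) if features is not None else list(df.columns)
    if not feats:
        raise ValueError("no candidate features")
    if len(feats) > MAX_EXHAUSTIVE_FEATURES and not force:
        raise ValueError(
            f"{len(feats)} features would need 2^{len(feats)}-1 subsets; "
            f"pass force=True to exceed {MAX_EXHAUSTIVE_FEATURES}"
        )
    missing = [f for f in feats if f not in df.columns]
    if missing:
        raise ValueError(f"features absent from X: {missing[:5]}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_assignments = np.empty(len(y), dtype=int)
    for i, (_, test) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        fold_assignments[test] = i

    col_index = {f: i for i, f in enumerate(df.columns)}
    values = df.to_numpy(dtype=float)
    records = []
    best: Optional[tuple] = None  # (-accuracy, size, subset)
    for size in range(1, len(feats) + 1):
        for subset in combinations(feats, size):
            cols = [col_index[f] for f in subset]
            params = {"kernel": kernel, "C": C, "gamma": 1.0 / len(subset)}
            acc, _ = _cv_accuracy(values[:, cols], y, fold_assignments, params)
            records.append({"features": ",".join(subset), "size": size, "cv_accuracy": acc})
            key = (-acc, size, subset)
            if best is None or key < best:
                best = key

    assert best is not None
    best_subset = list(best[2])
    cols = [col_index[f] for f in best_subset]
    params = {"kernel": kernel, "C": C, "gamma": 1.0 / len(best_subset)}
    acc, decision = _cv_accuracy(values[:, cols], y, fold_assignments, params)
    pos_label = np.unique(y)[-1]
    auc = float(roc_auc_score(y == pos_label, decision))
    table = (
        pd.DataFrame(records)
        .sort_values(["cv_accuracy", "size", "features"], ascending=[False, True, True],
                     kind="stable")
        .reset_index(drop=True)
    )
    return PanelResult(
        features=best_subset,
        cv_accuracy=float(acc),
        auc=auc,
        fold_assignments=fold_assignments,
        classifier_params=params,
        n_subsets_evaluated=len(records),
        subset_scores=table,
    )


def two_cluster_composition(
    X_panel, true_labels: Sequence
) -> tuple[np.ndarray, dict[int, dict[str, float]]]:
    """Two-cluster hierarchical grouping with per-cluster label composition.

    Complete-linkage agglomerative clustering (Euclidean) is cut at two
    clusters; for each cluster the fraction of samples carrying each true
    label is reported (e.g. the rate of cases in the predicted case
    group). Cluster 0 is the larger cluster (ties: the one containing
    sample 0).
    """
    X = _as_frame(X_panel).to_numpy(dtype=float)
    y = np.asarray(true_labels)
    if len(X) < 2:
        raise ValueError("need at least 2 samples to cluster")
    labels = AgglomerativeClustering(
        n_clusters=2, metric="euclidean", linkage="complete"
    ).fit_predict(X)
    # canonical cluster numbering, independent of library label order
    n0 = int(np.sum(labels == 0))
    n1 = len(labels) - n0
    if n1 > n0 or (n1 == n0 and labels[0] == 1):
        labels = 1 - labels
    composition: dict[int, dict[str, float]] = {}
    for c in (0, 1):
        members = y[labels == c]
        composition[c] = {
            str(lab): float(np.mean(members == lab)) for lab in np.unique(y)
        }
    return labels, composition
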