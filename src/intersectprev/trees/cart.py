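"""CART: greedy Gini splitting with cost-complexity pruning.

The tree is grown with the Gini impurity criterion and a minimum node size
to split of 20, then pruned along the cost-complexity path, with the
complexity parameter chosen by ten-fold cross-validation minimising the
misclassification error (the error measure the reference classification
implementation cross-validates by default).  Ties in cross-validated error
are broken toward the strongest pruning, so when no subtree improves
classification — typical when the outcome is too rare for any leaf to reach
a majority of events — the selected tree is the root alone and every
intersection estimate falls back to the sample prevalence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from ..simulate import SimulatedDataset
from .common import FEATURES, TreeModel, TreeNode

__all__ = ["fit_cart"]


def _sklearn_to_node(tree, features, node_id: int = 0) -> TreeNode:
    t = tree.tree_
    counts = t.value[node_id][0] * t.weighted_n_node_samples[node_id]
    n = int(round(t.weighted_n_node_samples[node_id]))
    total = counts.sum()
    if tree.n_classes_ == 2:
        rate = float(counts[1] / total)
    else:  # single observed class
        rate = float(tree.classes_[0])
    node = TreeNode(n=n, event_rate=rate)
    if t.children_left[node_id] != -1:
        node.split_var = features[t.feature[node_id]]
        node.split_kind = "threshold"
        node.threshold = float(t.threshold[node_id])
        node.children = [
            _sklearn_to_node(tree, features, t.children_left[node_id]),
            _sklearn_to_node(tree, features, t.children_right[node_id]),
        ]
    return node


def fit_cart(dataset: SimulatedDataset | pd.DataFrame, cv_folds: int = 10,
             random_state: int = 0, min_samples_split: int = 20,
             features: list[str] | None = None) -> TreeModel:
    """Fit a cost-complexity-pruned classification tree.

    A root-only tree is a valid result.  ``random_state`` seeds the
    cross-validation fold assignment (the greedy growth is deterministic
    up to feature ties).
    """
    df = dataset.data if isinstance(dataset, SimulatedDataset) else dataset
    features = list(features) if features is not None else list(FEATURES)
    X = df[features].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=int)

    base_kwargs = dict(
        criterion="gini",
        min_samples_split=min_samples_split,
        random_state=0,
    )
    full = DecisionTreeClassifier(**base_kwargs).fit(X, y)
    path = full.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    # geometric midpoints of the pruning path, as candidate penalties
    if alphas.size > 1:
        candidates = np.concatenate([
            [0.0], np.sqrt(alphas[1:] * np.maximum(alphas[:-1], 1e-12)),
            [alphas[-1] * 1.0000001],
        ])
        candidates = np.unique(candidates)
    else:
        candidates = np.array([0.0])

    if y.min() == y.max() or alphas.size == 1:
        best_alpha = float(candidates[-1])
        cv_errors = np.zeros(candidates.size)
    else:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=random_state)
        errors = np.zeros(candidates.size)
        for train, test in skf.split(X, y):
            for j, a in enumerate(candidates):
                clf = DecisionTreeClassifier(ccp_alpha=float(a), **base_kwargs)
                clf.fit(X[train], y[train])
                errors[j] += float(np.mean(clf.predict(X[test]) != y[test]))
        cv_errors = errors / cv_folds
        # minimal CV error; ties broken toward the largest penalty
        best = np.flatnonzero(cv_errors <= cv_errors.min() + 1e-12)
        best_alpha = float(candidates[best[-1]])

    final = DecisionTreeClassifier(ccp_alpha=best_alpha, **base_kwargs).fit(X, y)
    root = _sklearn_to_node(final, features)
    used = {features[f] for f in final.tree_.feature if f >= 0}
    return TreeModel(
        method="cart",
        root=root,
        variables_used=used,
        tuning={
            "ccp_alpha": best_alpha,
            "cv_criterion": "misclassification",
            "cv_folds": cv_folds,
            "candidate_alphas": candidates.tolist(),
            "cv_errors": cv_errors.tolist(),
        },
    )
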