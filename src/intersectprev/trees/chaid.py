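"""CHAID: chi-square automatic interaction detection (Kass-style).

CHAID applies only to categorical predictors.  For each variable at a node,
the least-significantly-different pair of category groups (largest
chi-square p-value of their 2x2 outcome table) is merged repeatedly while
that p-value exceeds the merge threshold, until every remaining pair
differs significantly or only two groups remain.  The reduced table's
chi-square p-value is then Bonferroni-adjusted by the number of ways the
original categories can be partitioned into the reduced group count, and
the variable with the smallest adjusted p-value splits the node — multiway,
one child per merged group — if that p-value is at most ``alpha`` and the
node holds at least ``minsplit`` individuals.
"""

from __future__ import annotations

from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from ..config import InputType
from ..simulate import SimulatedDataset
from .common import FEATURES, TreeModel, TreeNode

__all__ = ["fit_chaid", "bonferroni_multiplier"]


def bonferroni_multiplier(c: int, r: int) -> float:
    """Number of ways to partition c nominal categories into r groups.

    Kass's multiplier for nominal predictors: the Stirling number of the
    second kind S(c, r) = sum_{i=0}^{r-1} (-1)^i (r-i)^c / (i! (r-i)!).
    """
    if r <= 0 or r > c:
        return 1.0
    total = 0.0
    for i in range(r):
        total += (-1) ** i * (r - i) ** c / (factorial(i) * factorial(r - i))
    return max(total, 1.0)


def _pair_pvalue(e1, n1, e2, n2) -> float:
    """Chi-square p of the 2x2 table comparing two groups' outcome rates."""
    table = np.array([[e1, n1 - e1], [e2, n2 - e2]], dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 1.0
    expected = np.outer(rows, cols) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, 1))


def _table_pvalue(events: np.ndarray, counts: np.ndarray) -> float:
    table = np.column_stack([events, counts - events]).astype(float)
    keep = table.sum(axis=1) > 0
    table = table[keep]
    if table.shape[0] < 2:
        return 1.0
    cols = table.sum(axis=0)
    if (cols == 0).any():
        return 1.0
    expected = np.outer(table.sum(axis=1), cols) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, table.shape[0] - 1))


def merge_categories(x: np.ndarray, y: np.ndarray, alpha_merge: float = 0.05):
    """Greedy Kass merge: returns (groups, adjusted_p).

    ``groups`` is a list of frozensets of original levels; ``adjusted_p`` is
    the Bonferroni-adjusted chi-square p-value of the merged table.
    """
    levels = np.unique(x)
    groups = [frozenset([l]) for l in levels.tolist()]
    counts = {frozenset([l]): float((x == l).sum()) for l in levels.tolist()}
    events = {frozenset([l]): float(y[x == l].sum()) for l in levels.tolist()}
    while len(groups) > 2:
        worst_p, worst_pair = -1.0, None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i], groups[j]
                p = _pair_pvalue(events[gi], counts[gi], events[gj], counts[gj])
                if p > worst_p:
                    worst_p, worst_pair = p, (i, j)
        if worst_p <= alpha_merge:
            break
        i, j = worst_pair
        gi, gj = groups[i], groups[j]
        merged = gi | gj
        counts[merged] = counts[gi] + counts[gj]
        events[merged] = events[gi] + events[gj]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
    groups = sorted(groups, key=lambda g: min(g))
    ev = np.array([events[g] for g in groups])
    ct = np.array([counts[g] for g in groups])
    p = _table_pvalue(ev, ct)
    p_adj = min(1.0, p * bonferroni_multiplier(len(levels), len(groups)))
    return groups, p_adj


def fit_chaid(dataset: SimulatedDataset | pd.DataFrame, alpha: float = 0.05,
              alpha_merge: float = 0.05, minsplit: int = 20,
              max_depth: int = 30,
              features: list[str] | None = None) -> TreeModel:
    """Fit a CHAID tree on all-categorical predictors.

    Raises
    ------
    ValueError
        If any predictor is continuous (CHAID is chi-square based and
        requires categorical inputs).
    """
    if isinstance(dataset, SimulatedDataset):
        if dataset.scenario.input_type is not InputType.CATEGORICAL:
            raise ValueError(
                "CHAID is based on chi-squared contingency analysis and can "
                "only be applied to categorical inputs"
            )
        df = dataset.data
    else:
        df = dataset
    features = list(features) if features is not None else list(FEATURES)
    for v in features:
        col = df[v]
        if not (pd.api.types.is_integer_dtype(col) or isinstance(col.dtype, pd.CategoricalDtype)):
            raise ValueError(
                f"CHAID requires categorical predictors; column {v!r} has "
                f"dtype {col.dtype}"
            )

    cols = {v: df[v].to_numpy() for v in features}
    y_all = df["y"].to_numpy(dtype=int)
    used: set[str] = set()

    def grow(rows: np.ndarray, depth: int) -> TreeNode:
        y = y_all[rows]
        node = TreeNode(n=rows.size, event_rate=float(y.mean()))
        if rows.size < minsplit or depth >= max_depth or y.min() == y.max():
            return node
        best = None
        for v in features:
            x = cols[v][rows]
            if np.unique(x).size < 2:
                continue
            groups, p_adj = merge_categories(x, y, alpha_merge)
            if len(groups) < 2:
                continue
            if best is None or p_adj < best[1]:
                best = (v, p_adj, groups)
        if best is None or best[1] > alpha:
            return node
        v, p_adj, groups = best
        node.split_var = v
        node.split_kind = "groups"
        node.groups = groups
        node.p_value = p_adj
        used.add(v)
        x = cols[v][rows]
        node.children = [
            grow(rows[np.isin(x, list(g))], depth + 1) for g in groups
        ]
        return node

    root = grow(np.arange(len(df)), 0)
    return TreeModel(
        method="chaid", root=root, variables_used=used,
        tuning={"alpha": alpha, "alpha_merge": alpha_merge, "minsplit": minsplit},
    )
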