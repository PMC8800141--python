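"""CTree: conditional-inference-style recursive partitioning.

At each node the association between every candidate variable and the
binary outcome is tested with the asymptotic chi-square form of the
permutation-test statistic — a contingency-table chi-square for categorical
variables, the squared-correlation (trend) statistic for continuous ones.
P-values are Bonferroni-adjusted across the candidate variables; splitting
stops when the smallest adjusted p-value exceeds ``alpha`` (default 0.05) or
the node is smaller than ``minsplit`` (default 20).  The most significant
variable is split at its best binary partition, chosen to maximise the
two-sample chi-square statistic of the induced split; ties between equally
significant variables go to the smallest variable index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..config import InputType
from ..simulate import SimulatedDataset
from .common import FEATURES, TreeModel, TreeNode

__all__ = ["fit_ctree"]


def _chi2_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson chi-square p for a categorical variable vs binary y."""
    levels, codes = np.unique(x, return_inverse=True)
    k = levels.size
    if k < 2:
        return 1.0
    table = np.bincount(codes * 2 + y, minlength=2 * k).reshape(k, 2).astype(float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (cols == 0).any():
        return 1.0
    expected = np.outer(rows, cols) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, (k - 1)))


def _trend_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Squared-correlation chi-square(1) p for a continuous variable."""
    n = x.size
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    stat = n * r * r
    return float(stats.chi2.sf(stat, 1))


def _two_sample_stat(n_left, s_left, n, s) -> float:
    """Chi-square statistic of the 2x2 table (split side vs outcome)."""
    n_right = n - n_left
    if n_left == 0 or n_right == 0:
        return -np.inf
    p = s / n
    if p in (0.0, 1.0):
        return 0.0
    num = s_left - n_left * p
    return float(num * num * n / (n_left * n_right * p * (1 - p)))


def _best_subset_split(x: np.ndarray, y: np.ndarray, minbucket: int):
    """Best binary partition of category levels by two-sample chi-square."""
    levels = np.unique(x)
    n, s = x.size, float(y.sum())
    counts = np.array([(x == l).sum() for l in levels], dtype=float)
    events = np.array([y[x == l].sum() for l in levels], dtype=float)
    best_stat, best_subset = -np.inf, None
    k = levels.size
    # enumerate proper subsets that contain the first level (dedupes complements)
    for mask in range(0, 1 << (k - 1)):
        members = [0] + [j + 1 for j in range(k - 1) if (mask >> j) & 1]
        if len(members) == k:
            continue
        n_left = counts[members].sum()
        if n_left < minbucket or n - n_left < minbucket:
            continue
        stat = _two_sample_stat(n_left, events[members].sum(), n, s)
        if stat > best_stat:
            best_stat = stat
            best_subset = frozenset(levels[members].tolist())
    return best_subset, best_stat


def _best_threshold_split(x: np.ndarray, y: np.ndarray, minbucket: int):
    """Best cutpoint for a continuous variable by two-sample chi-square."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n, s = x.size, float(y.sum())
    cum = np.cumsum(ys)
    n_left = np.arange(1, n)
    valid = (xs[1:] != xs[:-1]) & (n_left >= minbucket) & (n - n_left >= minbucket)
    if not valid.any():
        return None, -np.inf
    p = s / n
    if p in (0.0, 1.0):
        return None, -np.inf
    num = cum[:-1] - n_left * p
    stat = num * num * n / (n_left * (n - n_left) * p * (1 - p))
    stat = np.where(valid, stat, -np.inf)
    j = int(np.argmax(stat))
    thr = float((xs[j] + xs[j + 1]) / 2.0)
    return thr, float(stat[j])


def fit_ctree(dataset: SimulatedDataset | pd.DataFrame,
              input_type: InputType | None = None, alpha: float = 0.05,
              minsplit: int = 20, minbucket: int = 7, max_depth: int = 30,
              features: list[str] | None = None,
              continuous: set[str] | None = None) -> TreeModel:
    """Fit a conditional-inference-style tree.

    ``input_type`` decides which features are treated as continuous (x1 and
    x6 in the mixed model); it is inferred from a :class:`SimulatedDataset`.
    """
    if isinstance(dataset, SimulatedDataset):
        df = dataset.data
        input_type = dataset.scenario.input_type
    else:
        df = dataset
        if input_type is None and features is None:
            raise ValueError("input_type or features required with a plain DataFrame")
    features = list(features) if features is not None else list(FEATURES)
    if continuous is None:
        input_type = InputType(input_type)
        continuous = {"x1", "x6"} if input_type is InputType.MIXED else set()

    cols = {v: df[v].to_numpy() for v in features}
    y_all = df["y"].to_numpy(dtype=int)
    used: set[str] = set()

    def grow(rows: np.ndarray, depth: int) -> TreeNode:
        y = y_all[rows]
        node = TreeNode(n=rows.size, event_rate=float(y.mean()))
        if rows.size < minsplit or depth >= max_depth or y.min() == y.max():
            return node
        pvals = {}
        for v in features:
            x = cols[v][rows]
            if v in continuous:
                pvals[v] = _trend_pvalue(x, y)
            else:
                pvals[v] = _chi2_pvalue(x, y)
        m = len(pvals)
        best_var = min(pvals, key=lambda v: (pvals[v], features.index(v)))
        p_adj = min(1.0, pvals[best_var] * m)
        if p_adj > alpha:
            return node
        x = cols[best_var][rows]
        if best_var in continuous:
            thr, stat = _best_threshold_split(x, y, minbucket)
            if thr is None:
                return node
            node.split_kind = "threshold"
            node.threshold = thr
            masks = [x <= thr, x > thr]
        else:
            subset, stat = _best_subset_split(x, y, minbucket)
            if subset is None:
                return node
            node.split_kind = "subset"
            node.left_levels = subset
            inmask = np.isin(x, list(subset))
            masks = [inmask, ~inmask]
        node.split_var = best_var
        node.p_value = p_adj
        used.add(best_var)
        node.children = [grow(rows[mk], depth + 1) for mk in masks]
        return node

    root = grow(np.arange(len(df)), 0)
    return TreeModel(
        method="ctree", root=root, variables_used=used,
        tuning={"alpha": alpha, "minsplit": minsplit, "minbucket": minbucket},
    )
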