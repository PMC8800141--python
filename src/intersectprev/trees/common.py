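"""Shared tree structure and per-intersection prediction.

All four tree methods reduce to the same prediction rule: route an
individual to a leaf and report the leaf's training event proportion.  The
node structure supports the three split kinds that occur here: a numeric
threshold (CART on ordinal/continuous features, CTree on continuous), a
binary category subset (CTree on categorical features) and a multiway
grouped split (CHAID).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..regression import PrevalenceEstimates
from ..simulate import SimulatedDataset

__all__ = ["TreeNode", "TreeModel", "predict_tree_intersections"]

FEATURES = ["x1", "x2", "x3", "x4", "x5", "x6"]


@dataclass
class TreeNode:
    n: int
    event_rate: float
    split_var: str | None = None
    split_kind: str | None = None          # 'threshold' | 'subset' | 'groups'
    threshold: float | None = None
    left_levels: frozenset | None = None   # subset split: levels going left
    groups: list[frozenset] | None = None  # multiway split: one child per group
    p_value: float | None = None           # adjusted p of the split test
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        d = {"n": self.n, "event_rate": self.event_rate}
        if not self.is_leaf:
            d["split_var"] = self.split_var
            d["split_kind"] = self.split_kind
            if self.split_kind == "threshold":
                d["threshold"] = self.threshold
            elif self.split_kind == "subset":
                d["left_levels"] = sorted(self.left_levels)
            else:
                d["groups"] = [sorted(g) for g in self.groups]
            if self.p_value is not None:
                d["p_value"] = self.p_value
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class TreeModel:
    """A fitted single tree with its tuning record."""

    method: str
    root: TreeNode
    variables_used: set[str] = field(default_factory=set)
    tuning: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else sum(count(c) for c in node.children)

        return count(self.root)

    def predict_rates(self, df: pd.DataFrame) -> np.ndarray:
        """Leaf event proportion for every row of ``df``."""
        out = np.empty(len(df), dtype=float)
        idx = np.arange(len(df))

        def route(node: TreeNode, rows: np.ndarray) -> None:
            if node.is_leaf or rows.size == 0:
                out[rows] = node.event_rate
                return
            col = df[node.split_var].to_numpy()[rows]
            if node.split_kind == "threshold":
                mask = col <= node.threshold
                route(node.children[0], rows[mask])
                route(node.children[1], rows[~mask])
            elif node.split_kind == "subset":
                mask = np.isin(col, list(node.left_levels))
                route(node.children[0], rows[mask])
                route(node.children[1], rows[~mask])
            else:  # groups
                assigned = np.zeros(rows.size, dtype=bool)
                for child, levels in zip(node.children, node.groups):
                    mask = np.isin(col, list(levels))
                    route(child, rows[mask])
                    assigned |= mask
                # unseen levels fall back to the node's own rate
                out[rows[~assigned]] = node.event_rate

        route(self.root, idx)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "variables_used": sorted(self.variables_used),
                "tuning": {k: v for k, v in self.tuning.items()
                           if isinstance(v, (int, float, str, bool, list))},
                "tree": self.root.to_dict(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def predict_tree_intersections(model, dataset,
                               n_intersections: int | None = None,
                               ) -> PrevalenceEstimates:
    """Average per-individual tree predictions within each intersection.

    ``model`` is a :class:`TreeModel` or a fitted random-forest wrapper —
    anything with ``predict_rates`` and a ``method`` tag.  ``dataset`` is a
    :class:`SimulatedDataset` (estimates reindexed to the full 192-cell
    design) or anything exposing ``.data`` with an ``intersection_id``
    column.
    """
    from ..config import N_INTERSECTIONS

    if n_intersections is None and isinstance(dataset, SimulatedDataset):
        n_intersections = N_INTERSECTIONS
    rates = model.predict_rates(dataset.data)
    est = (
        pd.Series(rates, index=dataset.data["intersection_id"])
        .groupby(level=0)
        .mean()
    )
    return PrevalenceEstimates(
        method=model.method, estimates=est, converged=True,
        fit_metadata={"tuning": dict(model.tuning)},
        n_intersections=n_intersections,
    )
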