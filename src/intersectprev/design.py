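"""Design-matrix construction for the regression estimators.

Treatment (reference-level) coding throughout, built directly with numpy so
that column order — and therefore the deterministic dropping of aliased
columns — is fully under our control.  Three specifications:

* ``main_effects`` — intercept + main effects only.
* ``correct_spec`` — main effects plus the interaction structure of the
  generating model as a practitioner would write it: X1:X2, X3:X4, X4:X5,
  X3:X5 and X3:X4:X5 (simulation schema only).
* ``saturated`` — all products of main-effect columns across the variables
  (the full factorial expansion; 192 columns for the categorical simulation
  schema, 64 for mixed where continuous variables enter linearly).

A *schema* is a list of ``(column, kind, levels)`` tuples (kind
``categorical`` or ``continuous``; ``levels`` lists the categories, first
one the reference).  The simulation schemas for x1..x6 are built in; the
real-data path supplies its own.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd

from .config import InputType

__all__ = [
    "build_design",
    "drop_aliased_columns",
    "simulation_schema",
    "schema_from_frame",
    "SPEC_NAMES",
]

SPEC_NAMES = ("main_effects", "correct_spec", "saturated")

Schema = list[tuple[str, str, list | None]]


def simulation_schema(input_type: InputType) -> Schema:
    """The x1..x6 variable schema of the two simulation models."""
    if InputType(input_type) is InputType.CATEGORICAL:
        x1 = ("x1", "categorical", [0, 1, 2, 3])
        x6 = ("x6", "categorical", [0, 1, 2])
    else:
        x1 = ("x1", "continuous", None)
        x6 = ("x6", "continuous", None)
    mid = [(v, "categorical", [0, 1]) for v in ("x2", "x3", "x4", "x5")]
    return [x1, *mid, x6]


def schema_from_frame(df: pd.DataFrame, columns: list[str]) -> Schema:
    """All-categorical schema with levels as observed (sorted) values."""
    return [(c, "categorical", sorted(df[c].dropna().unique().tolist()))
            for c in columns]


def _variable_blocks(df: pd.DataFrame, schema: Schema):
    """Per-variable design column blocks (name, vector), constant excluded."""
    blocks: dict[str, list[tuple[str, np.ndarray]]] = {}
    for name, kind, levels in schema:
        if kind == "continuous":
            blocks[name] = [(name, df[name].to_numpy(dtype=float))]
        else:
            col = df[name].to_numpy()
            blocks[name] = [
                (f"{name}[{lv}]", (col == lv).astype(float)) for lv in levels[1:]
            ]
    return blocks


def _interact(a: list[tuple[str, np.ndarray]], b: list[tuple[str, np.ndarray]]):
    return [(f"{na}:{nb}", ca * cb) for (na, ca), (nb, cb) in product(a, b)]


def build_design(df: pd.DataFrame, spec: str,
                 input_type: InputType | None = None,
                 schema: Schema | None = None):
    """Return (X, names) for one model specification.

    X always carries a leading intercept column named ``const``.  Either
    ``input_type`` (simulation schema) or an explicit ``schema`` must be
    given.
    """
    if spec not in SPEC_NAMES:
        raise ValueError(f"spec must be one of {SPEC_NAMES}, got {spec!r}")
    if schema is None:
        if input_type is None:
            raise ValueError("either input_type or schema is required")
        schema = simulation_schema(input_type)
    elif spec == "correct_spec":
        raise ValueError("correct_spec is defined only for the simulation schema")
    blocks = _variable_blocks(df, schema)
    order = [name for name, _, _ in schema]
    cols: list[tuple[str, np.ndarray]] = [("const", np.ones(len(df)))]
    for v in order:
        cols.extend(blocks[v])
    if spec == "correct_spec":
        cols.extend(_interact(blocks["x1"], blocks["x2"]))
        cols.extend(_interact(blocks["x3"], blocks["x4"]))
        cols.extend(_interact(blocks["x4"], blocks["x5"]))
        cols.extend(_interact(blocks["x3"], blocks["x5"]))
        cols.extend(_interact(_interact(blocks["x3"], blocks["x4"]), blocks["x5"]))
    elif spec == "saturated":
        # every product choosing, per variable, either nothing or one of its
        # dummy/linear columns; subset order follows schema order
        for k in range(2, len(order) + 1):
            for subset in combinations(order, k):
                terms = blocks[subset[0]]
                for v in subset[1:]:
                    terms = _interact(terms, blocks[v])
                cols.extend(terms)
    names = [n for n, _ in cols]
    X = np.column_stack([c for _, c in cols])
    return X, names


def drop_aliased_columns(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Drop linearly dependent columns, keeping the earliest columns.

    A modified Gram–Schmidt sweep in column order: a column is dropped when
    its residual against the kept basis falls below ``tol`` times its norm.
    Returns (X_kept, names_kept, names_dropped).
    """
    n, p = X.shape
    basis: list[np.ndarray] = []
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(p):
        v = X[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        if norm0 <= tol:
            dropped.append(names[j])
            continue
        for q in basis:
            v -= (q @ v) * q
        # second orthogonalisation pass for numerical stability
        for q in basis:
            v -= (q @ v) * q
        norm = np.linalg.norm(v)
        if norm <= tol * norm0:
            dropped.append(names[j])
        else:
            basis.append(v / norm)
            keep.append(j)
    return X[:, keep], [names[k] for k in keep], dropped
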