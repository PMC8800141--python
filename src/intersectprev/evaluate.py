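"""Accuracy and variable-selection evaluation.

The headline accuracy metric is the mean absolute deviation / mean ratio::

    MAD = (1/n) * sum_i |Phat_i - P_i| / p

where the sum runs over intersections (each weighted equally, so accuracy
is judged at the subpopulation level rather than favouring populous
intersections), P_i is the true prevalence in intersection i, Phat_i the
method's estimate, and p the overall sample prevalence.  MAD is 0 exactly
when every intersection is estimated perfectly.  Intersections empty in the
realised sample carry no estimate for most methods; they are excluded from
the average with n reduced accordingly, and the exclusion count recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import N_INTERSECTIONS
from .regression import PrevalenceEstimates
from .trees.common import TreeModel

__all__ = [
    "MADResult",
    "compute_mad",
    "summarize_convergence",
    "splitting_percentages",
    "bias_variance_by_intersection",
]


@dataclass
class MADResult:
    method: str
    mad: float
    n_intersections_used: int
    n_excluded: int


def _as_series(x, name) -> pd.Series:
    if isinstance(x, pd.Series):
        return x.astype(float)
    return pd.Series(dict(x), name=name, dtype=float)


def compute_mad(estimates: PrevalenceEstimates | pd.Series | Mapping,
                truth: pd.Series | Mapping,
                overall_prevalence: float,
                counts: pd.Series | Mapping | None = None) -> MADResult:
    """Evaluate the MAD accuracy metric for one fitted method.

    ``counts`` (members per intersection) marks which intersections are
    realised; when omitted, intersections with a defined truth value are
    used.  A missing estimate for a realised intersection is an error — it
    distinguishes a method that genuinely failed from an empty cell.
    """
    if overall_prevalence is None or not overall_prevalence > 0:
        raise ValueError("overall prevalence p must be > 0 to evaluate MAD")
    if isinstance(estimates, PrevalenceEstimates):
        method = estimates.method
        if not estimates.converged or estimates.estimates is None:
            raise ValueError(f"method {method} did not converge; MAD undefined")
        est = estimates.estimates
    else:
        method = "estimates"
        est = _as_series(estimates, "estimate")
    truth = _as_series(truth, "truth")
    include = truth.notna()
    if counts is not None:
        counts = _as_series(counts, "n")
        include &= counts.reindex(truth.index).fillna(0) > 0
    ids = truth.index[include]
    est = est.reindex(ids)
    if est.isna().any():
        missing = est.index[est.isna()].tolist()[:5]
        raise ValueError(
            f"method {method} has no estimate for realised intersections "
            f"{missing}"
        )
    mad = float(np.mean(np.abs(est.to_numpy() - truth[ids].to_numpy()))
                / overall_prevalence)
    return MADResult(
        method=method,
        mad=mad,
        n_intersections_used=int(len(ids)),
        n_excluded=int(N_INTERSECTIONS - len(ids)),
    )


def summarize_convergence(results: pd.DataFrame,
                          by: tuple[str, ...] = ("scenario", "n_individuals", "method"),
                          ) -> pd.DataFrame:
    """Percentage of converged fits per cell of the run grid.

    ``results`` needs one row per (scenario, iteration, method) with a
    boolean ``converged`` column — the shape the experiment runner emits.
    """
    cols = [c for c in by if c in results.columns]
    out = (
        results.groupby(cols)["converged"]
        .agg(percent_converged=lambda s: 100.0 * s.mean(), n_iterations="size")
        .reset_index()
    )
    return out


def splitting_percentages(models: Iterable[TreeModel] | pd.DataFrame,
                          variables: tuple[str, ...] = ("x1", "x2", "x3", "x4", "x5", "x6"),
                          ) -> pd.DataFrame:
    """Percent of fitted trees that split on each variable.

    Accepts fitted tree models or a DataFrame with ``method`` and
    ``variable`` columns of per-iteration usage flags (column ``used``).
    """
    if isinstance(models, pd.DataFrame):
        out = (
            models.groupby(["method", "variable"])["used"]
            .agg(splitting_percentage=lambda s: 100.0 * s.mean(), n_iterations="size")
            .reset_index()
        )
        return out
    models = list(models)
    if not models:
        raise ValueError("need at least one fitted model")
    rows = []
    for v in variables:
        pct = 100.0 * np.mean([v in m.variables_used for m in models])
        rows.append({
            "method": models[0].method, "variable": v,
            "splitting_percentage": pct, "n_iterations": len(models),
        })
    return pd.DataFrame(rows)


def bias_variance_by_intersection(estimates: pd.DataFrame,
                                  truth: pd.Series | Mapping,
                                  coefficient_ids: pd.Series | Mapping | None = None,
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bias and variance of each intersection's estimate across iterations.

    ``estimates`` is long format with columns iteration, intersection_id,
    estimate (one method).  All iterations must share one coefficient draw —
    pass ``coefficient_ids`` (iteration -> draw fingerprint) to enforce it.
    Bias is reported in percentage points (x100) and variance in squared
    percentage points (x100^2).  Returns (per-intersection table, summary
    with median/min/max over the non-empty intersections).
    """
    if coefficient_ids is not None:
        vals = pd.Series(dict(coefficient_ids)) if not isinstance(coefficient_ids, pd.Series) else coefficient_ids
        if vals.nunique() > 1:
            raise ValueError(
                "bias/variance across iterations requires a single fixed "
                f"coefficient draw; found {vals.nunique()} distinct draws"
            )
    truth = _as_series(truth, "truth")
    grouped = estimates.groupby("intersection_id")["estimate"]
    mean_est = grouped.mean()
    bias = 100.0 * (mean_est - truth.reindex(mean_est.index))
    variance = (100.0**2) * grouped.var(ddof=1)
    per = pd.DataFrame({
        "bias": bias,
        "variance": variance,
        "n_iterations": grouped.size(),
    }).dropna(subset=["bias"])
    summary = pd.DataFrame({
        "median": per[["bias", "variance"]].median(),
        "min": per[["bias", "variance"]].min(),
        "max": per[["bias", "variance"]].max(),
    })
    return per, summary
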