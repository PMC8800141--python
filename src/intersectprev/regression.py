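"""Single-level estimators: cross-classification and modified Poisson.

Modified Poisson regression fits a Poisson likelihood with log link to a
binary outcome, which makes the exponentiated coefficients relative risks,
and replaces the model-based covariance with the robust sandwich estimator
A^-1 B A^-1 (bread = expected information, meat = sum of score outer
products) so that inference remains valid despite the working-likelihood
misspecification.

Fitting is iteratively reweighted least squares with step-halving.  A fit
is *converged* when the relative deviance change falls below ``tol`` within
``max_iter`` iterations with finite coefficients; step-halving exhaustion or
divergence marks the fit non-converged (recorded, never raised).  For
all-categorical datasets the IRLS runs on rows aggregated by unique
(covariate pattern, y) with frequency weights, which is exact and makes
saturated fits at large N cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import InputType, N_INTERSECTIONS
from .design import Schema, build_design, drop_aliased_columns, SPEC_NAMES
from .simulate import SimulatedDataset, intersection_patterns

__all__ = [
    "PrevalenceEstimates",
    "RobustFit",
    "NotConvergedError",
    "cross_classify",
    "fit_modified_poisson",
    "predict_intersections",
    "poisson_irls",
]

METHODS = (
    "cross_classification", "main_effects", "correct_spec", "saturated",
    "maihda", "cart", "ctree", "chaid", "random_forest",
)


class NotConvergedError(RuntimeError):
    """Prediction was requested from a fit that did not converge."""


@dataclass
class PrevalenceEstimates:
    """Per-intersection estimated prevalence from one fitted method.

    ``estimates`` is indexed by intersection id 0..191; ids the method cannot
    estimate (e.g. empty intersections under cross-classification) are NaN.
    A non-converged fit carries no estimates.
    """

    method: str
    estimates: pd.Series | None
    converged: bool = True
    fit_metadata: dict = field(default_factory=dict)
    #: number of design intersections to reindex to (None keeps the given
    #: index, e.g. for real-data runs with fewer intersections)
    n_intersections: int | None = N_INTERSECTIONS

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.converged:
            self.estimates = None
        if self.estimates is not None:
            if self.n_intersections is None:
                full = pd.Index(sorted(self.estimates.index), name="intersection_id")
            else:
                full = pd.Index(np.arange(self.n_intersections), name="intersection_id")
            est = self.estimates.reindex(full).astype(float)
            bad = est.dropna()
            if ((bad < -1e-9) | (bad > 1 + 1e-9)).any():
                raise ValueError("prevalence estimates must lie in [0, 1]")
            self.estimates = est.clip(0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        if self.estimates is None:
            return pd.DataFrame(
                columns=["intersection_id", "method", "estimate", "converged"]
            )
        out = self.estimates.rename("estimate").reset_index()
        out["method"] = self.method
        out["converged"] = self.converged
        return out[["intersection_id", "method", "estimate", "converged"]]


def cross_classify(dataset: SimulatedDataset | pd.DataFrame,
                   n_intersections: int | None = N_INTERSECTIONS,
                   ) -> PrevalenceEstimates:
    """Raw within-intersection event proportion, with no adjustment."""
    df = dataset.data if isinstance(dataset, SimulatedDataset) else dataset
    est = df.groupby("intersection_id")["y"].mean()
    n_empty = (n_intersections or est.size) - est.size
    return PrevalenceEstimates(
        method="cross_classification",
        estimates=est,
        fit_metadata={"n_empty_intersections": int(n_empty)},
        n_intersections=n_intersections,
    )


@dataclass
class RobustFit:
    """A modified-Poisson fit: coefficients, sandwich covariance, status."""

    spec: str
    input_type: InputType | None
    params: pd.Series | None
    robust_cov: pd.DataFrame | None
    converged: bool
    n_iter: int
    deviance: float
    dropped_columns: list[str]
    fit_metadata: dict = field(default_factory=dict)
    schema: Schema | None = None  # non-None for real-data (non-simulation) fits

    @property
    def robust_se(self) -> pd.Series | None:
        if self.robust_cov is None:
            return None
        return pd.Series(np.sqrt(np.diag(self.robust_cov.to_numpy())),
                         index=self.robust_cov.index, name="robust_se")


def _poisson_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(w * (term - (y - mu))))


def poisson_irls(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
                 max_iter: int = 25, tol: float = 1e-8):
    """Log-link Poisson IRLS, with the reference GLM's failure semantics.

    Returns dict with params, converged flag, iteration count, deviance and
    the inverse expected information (bread of the sandwich).  ``weights``
    are frequency weights.  As in the reference implementations, the linear
    predictor is uncapped and step-halving is applied only when a step
    produces a non-finite deviance; halving exhaustion (or an invalid very
    first step, which has no previous iterate to retreat toward) marks the
    fit non-converged rather than being silently repaired.  Sparse saturated
    designs exercise exactly these paths.
    """
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    # standard GLM starting value: eta from shrunken response
    eta = np.log(y + 0.1)
    mu = np.exp(eta)
    dev = _poisson_deviance(y, mu, w)
    beta = None
    xtwx = np.eye(p)
    converged = False
    halving_failed = False
    it = 0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for it in range(1, max_iter + 1):
            W = w * mu
            z = eta + (y - mu) / np.where(mu > 0, mu, np.nan)
            bad = ~np.isfinite(z)
            if bad.any():
                # underflowed means carry zero IRLS weight
                z = np.where(bad, 0.0, z)
                W = np.where(bad, 0.0, W)
            WX = X * W[:, None]
            xtwx = X.T @ WX
            xtwz = WX.T @ z
            try:
                beta_new = np.linalg.solve(xtwx, xtwz)
            except np.linalg.LinAlgError:
                beta_new = np.linalg.lstsq(xtwx, xtwz, rcond=None)[0]
            if not np.all(np.isfinite(beta_new)):
                halving_failed = True
                break
            eta_c = X @ beta_new
            mu_c = np.exp(eta_c)
            dev_c = _poisson_deviance(y, mu_c, w)
            if not np.isfinite(dev_c):
                if beta is None:
                    halving_failed = True  # no valid iterate to retreat toward
                    break
                ok = False
                for _ in range(25):
                    beta_new = (beta_new + beta) / 2.0
                    eta_c = X @ beta_new
                    mu_c = np.exp(eta_c)
                    dev_c = _poisson_deviance(y, mu_c, w)
                    if np.isfinite(dev_c):
                        ok = True
                        break
                if not ok:
                    halving_failed = True
                    break
            beta, eta, mu, dev_old, dev = beta_new, eta_c, mu_c, dev, dev_c
            if abs(dev - dev_old) / (abs(dev) + 0.1) < tol:
                converged = True
                break
    converged = (converged and beta is not None and np.all(np.isfinite(beta))
                 and not halving_failed)
    if beta is None:
        beta = np.zeros(p)
    try:
        bread = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        bread = np.linalg.pinv(xtwx)
    return {
        "params": beta, "eta": eta, "mu": mu, "converged": bool(converged),
        "n_iter": it, "deviance": dev, "bread": bread,
        "halving_failed": halving_failed,
    }


def _sandwich(X: np.ndarray, y: np.ndarray, mu: np.ndarray, w: np.ndarray,
              bread: np.ndarray) -> np.ndarray:
    """Robust covariance A^-1 B A^-1 with meat from per-observation scores."""
    resid = y - mu
    Xs = X * (w * resid**2)[:, None]
    meat = X.T @ Xs
    cov = bread @ meat @ bread
    return (cov + cov.T) / 2.0


def _aggregate_categorical(df: pd.DataFrame, feature_cols: list[str]):
    """Collapse all-categorical rows to unique (pattern, y) with counts."""
    cols = [*feature_cols, "y"]
    grouped = df.groupby(cols, sort=True).size().rename("w").reset_index()
    return grouped, grouped["w"].to_numpy(dtype=float)


def fit_modified_poisson(dataset: SimulatedDataset | pd.DataFrame, spec: str,
                         input_type: InputType | None = None,
                         schema: Schema | None = None,
                         max_iter: int = 25, tol: float = 1e-8) -> RobustFit:
    """Fit one of the three modified-Poisson specifications.

    ``spec`` is ``main_effects``, ``correct_spec`` or ``saturated``.
    Rank-deficient designs have aliased columns dropped deterministically in
    column order.  Non-convergence is recorded on the returned fit.  Pass an
    explicit all-categorical ``schema`` to fit a non-simulation flat table.
    """
    if isinstance(dataset, SimulatedDataset):
        df = dataset.data
        input_type = dataset.scenario.input_type
    else:
        df = dataset
        if input_type is None and schema is None:
            raise ValueError("input_type or schema required with a plain DataFrame")
    if spec not in SPEC_NAMES:
        raise ValueError(f"spec must be one of {SPEC_NAMES}")
    if schema is not None:
        input_type = None
        work, w = _aggregate_categorical(df, [c for c, _, _ in schema])
        X, names = build_design(work, spec, schema=schema)
    else:
        input_type = InputType(input_type)
        if input_type is InputType.CATEGORICAL:
            work, w = _aggregate_categorical(df, ["x1", "x2", "x3", "x4", "x5", "x6"])
        else:
            work, w = df, np.ones(len(df))
        X, names = build_design(work, spec, input_type)
    y = work["y"].to_numpy(dtype=float)
    X, names, dropped = drop_aliased_columns(X, names)
    res = poisson_irls(X, y, weights=w, max_iter=max_iter, tol=tol)
    params = cov = None
    if res["converged"]:
        params = pd.Series(res["params"], index=names, name="coef")
        cov = pd.DataFrame(_sandwich(X, y, res["mu"], w, res["bread"]),
                           index=names, columns=names)
    return RobustFit(
        spec=spec,
        input_type=input_type,
        params=params,
        robust_cov=cov,
        converged=res["converged"],
        n_iter=res["n_iter"],
        deviance=res["deviance"],
        dropped_columns=dropped,
        fit_metadata={
            "n_obs": int(len(df)),
            "n_params": len(names),
            "halving_failed": res["halving_failed"],
        },
        schema=schema,
    )


def predict_intersections(fit: RobustFit,
                          dataset: SimulatedDataset) -> PrevalenceEstimates:
    """Per-intersection predicted prevalence from a converged Poisson fit.

    Categorical inputs: predictions at each of the 192 covariate patterns.
    Mixed inputs: per-individual predicted risks averaged within each
    observed intersection.  Log-link predictions can exceed 1; they are
    clipped to [0, 1] and the clip count recorded.
    """
    if not fit.converged or fit.params is None:
        raise NotConvergedError(
            f"cannot predict from non-converged {fit.spec} fit"
        )
    if fit.schema is not None:
        df = dataset.data if isinstance(dataset, SimulatedDataset) else dataset
        X, names = build_design(df, fit.spec, schema=fit.schema)
        keep = [names.index(n) for n in fit.params.index]
        pred = np.exp(np.clip(X[:, keep] @ fit.params.to_numpy(), -30, 30))
        n_clipped = int((pred > 1.0).sum())
        est = (
            pd.Series(np.clip(pred, 0.0, 1.0), index=df["intersection_id"])
            .groupby(level=0)
            .mean()
        )
        meta = dict(fit.fit_metadata, n_clipped_predictions=n_clipped, spec=fit.spec)
        return PrevalenceEstimates(method=fit.spec, estimates=est, converged=True,
                                   fit_metadata=meta, n_intersections=None)
    if fit.input_type is InputType.CATEGORICAL:
        frame = intersection_patterns().reset_index()
        X, names = build_design(frame, fit.spec, fit.input_type)
        keep = [names.index(n) for n in fit.params.index]
        pred = np.exp(np.clip(X[:, keep] @ fit.params.to_numpy(), -30, 30))
        n_clipped = int((pred > 1.0).sum())
        est = pd.Series(np.clip(pred, 0.0, 1.0),
                        index=frame["intersection_id"].to_numpy())
    else:
        X, names = build_design(dataset.data, fit.spec, fit.input_type)
        keep = [names.index(n) for n in fit.params.index]
        pred = np.exp(np.clip(X[:, keep] @ fit.params.to_numpy(), -30, 30))
        n_clipped = int((pred > 1.0).sum())
        est = (
            pd.Series(np.clip(pred, 0.0, 1.0), index=dataset.data["intersection_id"])
            .groupby(level=0)
            .mean()
        )
    meta = dict(fit.fit_metadata, n_clipped_predictions=n_clipped, spec=fit.spec)
    return PrevalenceEstimates(method=fit.spec, estimates=est, converged=True,
                               fit_metadata=meta)
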