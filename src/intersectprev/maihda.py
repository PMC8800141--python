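"""Frequentist MAIHDA: logistic regression with a random intersection intercept.

MAIHDA (multilevel analysis of individual heterogeneity and discriminatory
accuracy) models a binary outcome with fixed main effects for each social
position variable (X1..X6) and a normal random intercept u_i ~ N(0, sigma^2)
for each intersection i::

    logit P(Y=1 | x, i) = x' beta + u_i

Estimation is Laplace-approximated maximum likelihood: for a candidate
variance sigma^2, the joint penalised log-likelihood over (beta, u) is
maximised by penalised IRLS (Newton steps with an efficient Schur-complement
solve, the random-effect block being diagonal), and the profiled Laplace
log-likelihood

    l(sigma^2) = log p(y | beta-hat, u-hat) - ||u-hat||^2 / (2 sigma^2)
                 - 1/2 sum_i log(1 + sigma^2 W_i)

(W_i the summed IRLS weights of intersection i) is maximised over
log(sigma^2) in one dimension.  The empirical-Bayes intercepts (BLUPs) are
the posterior modes u-hat at the optimum.  A variance pinned at zero is a
valid boundary solution and reduces to plain logistic regression.

The BLUPs shrink toward zero as an intersection's sample size shrinks:
small intersections borrow strength from the fixed-effect (main-effects)
prediction, trading bias for variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .config import InputType
from .design import Schema, build_design, drop_aliased_columns
from .regression import NotConvergedError, PrevalenceEstimates
from .simulate import SimulatedDataset, intersection_patterns

__all__ = ["MaihdaFit", "fit_maihda", "predict_maihda"]


@dataclass
class MaihdaFit:
    """Fitted MAIHDA model: fixed effects, variance component, BLUPs."""

    fixed_effects: pd.Series
    random_intercept_variance: float
    blups: pd.Series  # indexed by intersection id present in training data
    converged: bool
    input_type: InputType | None
    boundary: bool = False  # variance component pinned at zero
    fit_metadata: dict = field(default_factory=dict)
    schema: Schema | None = None  # non-None for real-data (non-simulation) fits


def _joint_mode(X, y, groups, n_groups, sigma2, beta0, u0,
                max_iter=200, gtol=1e-8):
    """Penalised IRLS for (beta, u) at fixed sigma^2.

    ``groups`` are contiguous codes 0..n_groups-1.  Returns the mode, the
    per-group summed weights, the penalised log-likelihood at the mode, and
    a convergence flag.  The objective is concave, so Newton with
    step-halving converges reliably.
    """
    n, p = X.shape
    beta, u = beta0.copy(), u0.copy()

    def objective(beta, u):
        eta = X @ beta + u[groups]
        # log-lik of Bernoulli with logit link, numerically stable
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return ll - float(u @ u) / (2.0 * sigma2), eta

    obj, eta = objective(beta, u)
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y - mu
        g_beta = X.T @ r
        g_u = np.bincount(groups, weights=r, minlength=n_groups) - u / sigma2
        gnorm = max(np.abs(g_beta).max(), np.abs(g_u).max())
        if gnorm < gtol * (1.0 + abs(obj)):
            converged = True
            break
        W_g = np.bincount(groups, weights=w, minlength=n_groups)
        D = W_g + 1.0 / sigma2
        WX = X * w[:, None]
        A = X.T @ WX                      # p x p
        B = np.zeros((p, n_groups))       # X' W Z, Z = group indicators
        for j in range(p):
            B[j] = np.bincount(groups, weights=WX[:, j], minlength=n_groups)
        # Newton step via Schur complement on the diagonal u-block
        S = A - (B / D) @ B.T
        rhs_b = g_beta - (B / D) @ g_u
        try:
            d_beta = np.linalg.solve(S, rhs_b)
        except np.linalg.LinAlgError:
            d_beta = np.linalg.lstsq(S, rhs_b, rcond=None)[0]
        d_u = (g_u - B.T @ d_beta) / D
        # step-halving: the objective must not decrease
        step = 1.0
        for _ in range(40):
            beta_c = beta + step * d_beta
            u_c = u + step * d_u
            obj_c, eta_c = objective(beta_c, u_c)
            if np.isfinite(obj_c) and obj_c >= obj - 1e-12 * (1 + abs(obj)):
                break
            step *= 0.5
        else:
            break
        beta, u, obj, eta = beta_c, u_c, obj_c, eta_c
    mu = expit(eta)
    W_g = np.bincount(groups, weights=mu * (1 - mu), minlength=n_groups)
    return beta, u, W_g, obj, converged


def _plain_logistic(X, y, max_iter=100, tol=1e-10):
    """Null-variance fit: ordinary logistic regression log-likelihood."""
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)[0]
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(ll - ll_old) < tol * (abs(ll) + 1):
            break
        ll_old = ll
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return beta, ll


def fit_maihda(dataset: SimulatedDataset | pd.DataFrame,
               input_type: InputType | None = None,
               schema: Schema | None = None,
               log_var_bounds: tuple[float, float] = (-12.0, 5.0),
               xatol: float = 1e-6) -> MaihdaFit:
    """Fit the random-intercept logistic MAIHDA model.

    Requires at least two non-empty intersections.  The variance component
    is profiled on the log scale; an optimum at the lower bound is reported
    as the boundary solution sigma^2 = 0 (plain logistic regression).
    """
    if isinstance(dataset, SimulatedDataset):
        df = dataset.data
        input_type = dataset.scenario.input_type
    else:
        df = dataset
        if input_type is None and schema is None:
            raise ValueError("input_type or schema required with a plain DataFrame")
    if schema is None:
        input_type = InputType(input_type)
    else:
        input_type = None
    ids = df["intersection_id"].to_numpy()
    unique_ids, groups = np.unique(ids, return_inverse=True)
    if unique_ids.size < 2:
        raise ValueError("MAIHDA needs at least two non-empty intersections")
    X, names = build_design(df, "main_effects", input_type, schema=schema)
    X, names, dropped = drop_aliased_columns(X, names)
    y = df["y"].to_numpy(dtype=float)
    n_groups = unique_ids.size

    beta_init, ll0 = _plain_logistic(X, y)
    state = {"beta": beta_init, "u": np.zeros(n_groups)}
    inner_ok = {"all": True}

    def negloglap(log_s2: float) -> float:
        s2 = float(np.exp(log_s2))
        beta, u, W_g, obj, conv = _joint_mode(
            X, y, groups, n_groups, s2, state["beta"], state["u"])
        inner_ok["all"] = inner_ok["all"] and conv
        state["beta"], state["u"] = beta, u
        lap = obj - 0.5 * float(np.sum(np.log1p(s2 * W_g)))
        return -lap

    res = minimize_scalar(negloglap, bounds=log_var_bounds, method="bounded",
                          options={"xatol": xatol})
    log_s2 = float(res.x)
    lap_ll = -float(res.fun)
    boundary = (log_s2 < log_var_bounds[0] + 0.5) or (lap_ll <= ll0 + 1e-7)
    if boundary:
        sigma2 = 0.0
        beta = beta_init
        u = np.zeros(n_groups)
        lap_ll = ll0
    else:
        sigma2 = float(np.exp(log_s2))
        beta, u, _, _, conv = _joint_mode(
            X, y, groups, n_groups, sigma2, state["beta"], state["u"])
        inner_ok["all"] = inner_ok["all"] and conv
    converged = bool(res.success) and inner_ok["all"]
    return MaihdaFit(
        fixed_effects=pd.Series(beta, index=names, name="coef"),
        random_intercept_variance=sigma2,
        blups=pd.Series(u, index=pd.Index(unique_ids, name="intersection_id")),
        converged=converged,
        input_type=input_type,
        boundary=boundary,
        schema=schema,
        fit_metadata={
            "laplace_loglik": lap_ll,
            "loglik_null_variance": ll0,
            "dropped_columns": dropped,
            "n_groups": int(n_groups),
        },
    )


def predict_maihda(fit: MaihdaFit, dataset: SimulatedDataset) -> PrevalenceEstimates:
    """Per-intersection prevalence: inverse-logit of fixed part + BLUP.

    Intersections unseen in training get BLUP 0.  For mixed inputs the
    member-level predictions are averaged within each intersection.
    """
    if not fit.converged:
        raise NotConvergedError("cannot predict from a non-converged MAIHDA fit")
    if fit.schema is not None:
        df = dataset.data if isinstance(dataset, SimulatedDataset) else dataset
        X, names = build_design(df, "main_effects", schema=fit.schema)
        keep = [names.index(n) for n in fit.fixed_effects.index]
        eta = X[:, keep] @ fit.fixed_effects.to_numpy()
        ids = df["intersection_id"]
        blup = fit.blups.reindex(ids).fillna(0.0).to_numpy()
        est = pd.Series(expit(eta + blup), index=ids).groupby(level=0).mean()
        return PrevalenceEstimates(
            method="maihda", estimates=est, converged=True,
            fit_metadata={
                "random_intercept_variance": fit.random_intercept_variance,
                "boundary": fit.boundary,
            },
            n_intersections=None,
        )
    if fit.input_type is InputType.CATEGORICAL:
        frame = intersection_patterns().reset_index()
        X, names = build_design(frame, "main_effects", fit.input_type)
        keep = [names.index(n) for n in fit.fixed_effects.index]
        eta = X[:, keep] @ fit.fixed_effects.to_numpy()
        blup = fit.blups.reindex(frame["intersection_id"]).fillna(0.0).to_numpy()
        est = pd.Series(expit(eta + blup), index=frame["intersection_id"].to_numpy())
    else:
        X, names = build_design(dataset.data, "main_effects", fit.input_type)
        keep = [names.index(n) for n in fit.fixed_effects.index]
        eta = X[:, keep] @ fit.fixed_effects.to_numpy()
        ids = dataset.data["intersection_id"]
        blup = fit.blups.reindex(ids).fillna(0.0).to_numpy()
        est = pd.Series(expit(eta + blup), index=ids).groupby(level=0).mean()
    return PrevalenceEstimates(
        method="maihda", estimates=est, converged=True,
        fit_metadata={
            "random_intercept_variance": fit.random_intercept_variance,
            "boundary": fit.boundary,
        },
    )
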