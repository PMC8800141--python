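"""Experiment orchestration: scenario grids and the real-data demonstration.

:func:`run_grid` executes a scenario grid — for each scenario iteration it
draws an admissible coefficient set, generates the dataset, fits every
requested method, and collects per-intersection estimates, MAD accuracy
rows, convergence flags and tree variable-usage rows, plus a JSON manifest
of seeds and counters.  Results are deterministic given the configuration
(including under parallel execution, because every iteration derives its
own child seed).

:func:`run_real_data` applies the applicable methods to a flat table of
social-position categories and blood-pressure readings: the outcome is
high blood pressure (mean systolic >= 130 mmHg and/or mean diastolic
>= 80 mmHg, each averaged over up to three readings), intersections are the
cross-classification of the four social variables, and the analysis is
unweighted complete-case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import RunConfig, ScenarioConfig
from .evaluate import compute_mad
from .maihda import fit_maihda, predict_maihda
from .regression import (
    PrevalenceEstimates,
    cross_classify,
    fit_modified_poisson,
    predict_intersections,
)
from .simulate import SimulatedDataset, simulate_dataset
from .trees import (
    fit_cart,
    fit_chaid,
    fit_ctree,
    fit_random_forest,
    predict_tree_intersections,
)

__all__ = ["METHOD_NAMES", "RealDataSpec", "run_grid", "run_real_data"]

METHOD_NAMES = (
    "cross_classification", "main_effects", "correct_spec", "saturated",
    "maihda", "cart", "ctree", "chaid", "random_forest",
)

def _fit_one_method(method: str, dataset: SimulatedDataset, seed: int,
                    rf_n_trees: int, rf_n_permutations: int):
    """Returns (PrevalenceEstimates, variables_used or None, extra meta)."""
    if method == "cross_classification":
        return cross_classify(dataset), None, {}
    if method in ("main_effects", "correct_spec", "saturated"):
        fit = fit_modified_poisson(dataset, method)
        if not fit.converged:
            est = PrevalenceEstimates(method=method, estimates=None, converged=False)
            return est, None, {"n_iter": fit.n_iter}
        return predict_intersections(fit, dataset), None, {"n_iter": fit.n_iter}
    if method == "maihda":
        fit = fit_maihda(dataset)
        if not fit.converged:
            est = PrevalenceEstimates(method="maihda", estimates=None, converged=False)
            return est, None, {}
        return predict_maihda(fit, dataset), None, {
            "variance": fit.random_intercept_variance}
    if method == "cart":
        model = fit_cart(dataset, random_state=seed)
        return predict_tree_intersections(model, dataset), model.variables_used, {}
    if method == "ctree":
        model = fit_ctree(dataset)
        return predict_tree_intersections(model, dataset), model.variables_used, {}
    if method == "chaid":
        model = fit_chaid(dataset)
        return predict_tree_intersections(model, dataset), model.variables_used, {}
    if method == "random_forest":
        model, vim = fit_random_forest(
            dataset, n_trees=rf_n_trees, n_permutations=rf_n_permutations,
            seed=seed)
        return predict_tree_intersections(model, dataset), model.variables_used, {
            "mtry": model.tuning["mtry"],
            "impurity_vim": vim.impurity_vim.to_dict(),
            "permutation_p": vim.permutation_vim["p_value"].to_dict(),
        }
    raise ValueError(f"unknown method {method!r}")


def _run_iteration(scenario: ScenarioConfig, s_idx: int, iteration: int,
                   methods: list[str], rf_n_trees: int, rf_n_permutations: int):
    dataset = simulate_dataset(scenario, iteration)
    truth = dataset.intersections["true_prevalence"]
    counts = dataset.intersections["n_members"]
    p = dataset.overall_prevalence
    seed = int(np.random.default_rng(
        scenario.iteration_seed(iteration)).integers(2**31))
    est_rows, mad_rows, var_rows, conv_rows, failures = [], [], [], [], []
    for method in methods:
        try:
            est, variables, meta = _fit_one_method(
                method, dataset, seed, rf_n_trees, rf_n_permutations)
        except Exception as exc:  # a failed method must not sink the grid
            failures.append({
                "scenario": scenario.label(), "iteration": iteration,
                "method": method, "error": f"{type(exc).__name__}: {exc}",
            })
            continue
        frame = est.to_frame()
        frame.insert(0, "iteration", iteration)
        frame.insert(0, "scenario", scenario.label())
        est_rows.append(frame)
        conv_rows.append({
            "scenario": scenario.label(), "n_individuals": scenario.n_individuals,
            "iteration": iteration, "method": method, "converged": est.converged,
        })
        if est.converged and p > 0:
            mad = compute_mad(est, truth, p, counts=counts)
            mad_rows.append({
                "scenario": scenario.label(),
                "n_individuals": scenario.n_individuals,
                "iteration": iteration, "method": method, "mad": mad.mad,
                "n_intersections_used": mad.n_intersections_used,
            })
        if variables is not None:
            for v in ("x1", "x2", "x3", "x4", "x5", "x6"):
                var_rows.append({
                    "scenario": scenario.label(), "iteration": iteration,
                    "method": method, "variable": v, "used": v in variables,
                })
    return {
        "estimates": est_rows, "mad": mad_rows, "variables": var_rows,
        "convergence": conv_rows, "failures": failures,
        "n_redraws": dataset.n_coefficient_redraws,
        "overall_prevalence": p,
    }


def run_grid(config: RunConfig) -> dict:
    """Run the full scenario x iteration x method grid.

    Returns a dict of DataFrames (``estimates``, ``mad``, ``variables``,
    ``convergence``) plus the ``manifest``; writes them as CSV/JSON when
    ``config.output_dir`` is set.
    """
    tasks = [
        (sc, si, it)
        for si, sc in enumerate(config.scenarios)
        for it in range(sc.n_iterations)
    ]
    results = Parallel(n_jobs=config.n_jobs)(
        delayed(_run_iteration)(sc, si, it, config.methods,
                                config.rf_n_trees, config.rf_n_permutations)
        for sc, si, it in tasks
    )
    est = [f for r in results for f in r["estimates"]]
    out = {
        "estimates": pd.concat(est, ignore_index=True) if est else pd.DataFrame(),
        "mad": pd.DataFrame([row for r in results for row in r["mad"]]),
        "variables": pd.DataFrame([row for r in results for row in r["variables"]]),
        "convergence": pd.DataFrame([row for r in results for row in r["convergence"]]),
    }
    from . import __version__

    manifest = {
        "package_version": __version__,
        "methods": list(config.methods),
        "scenarios": [
            {
                "label": sc.label(),
                "input_type": sc.input_type.value,
                "prevalence_tier": sc.prevalence_tier.value,
                "n_individuals": sc.n_individuals,
                "n_iterations": sc.n_iterations,
                "master_seed": sc.master_seed,
                "interaction_boost": sc.interaction_boost,
            }
            for sc in config.scenarios
        ],
        "rf_n_trees": config.rf_n_trees,
        "rf_n_permutations": config.rf_n_permutations,
        "coefficient_redraws": [r["n_redraws"] for r in results],
        "overall_prevalences": [r["overall_prevalence"] for r in results],
        "failures": [row for r in results for row in r["failures"]],
    }
    out["manifest"] = manifest
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("estimates", "mad", "variables", "convergence"):
            out[name].to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# ---------------------------------------------------------------------------
# Real-data demonstration path
# ---------------------------------------------------------------------------

@dataclass
class RealDataSpec:
    """Column mapping and outcome rule for a blood-pressure flat table."""

    category_columns: tuple[str, ...] = (
        "sex_gender", "race_ethnicity", "age_group", "poverty")
    systolic_columns: tuple[str, ...] = ("sbp1", "sbp2", "sbp3")
    diastolic_columns: tuple[str, ...] = ("dbp1", "dbp2", "dbp3")
    systolic_threshold: float = 130.0
    diastolic_threshold: float = 80.0


def blood_pressure_outcome(df: pd.DataFrame, spec: RealDataSpec) -> pd.Series:
    """High-blood-pressure indicator from averaged available readings."""
    sbp = df[list(spec.systolic_columns)].mean(axis=1, skipna=True)
    dbp = df[list(spec.diastolic_columns)].mean(axis=1, skipna=True)
    return ((sbp >= spec.systolic_threshold)
            | (dbp >= spec.diastolic_threshold)).astype(int)


DEFAULT_REAL_METHODS = (
    "cross_classification", "main_effects", "saturated", "maihda",
    "cart", "ctree", "chaid", "random_forest",
)


def run_real_data(table: pd.DataFrame, spec: RealDataSpec | None = None,
                  methods: tuple[str, ...] = DEFAULT_REAL_METHODS,
                  rf_n_trees: int = 500, rf_n_permutations: int = 100,
                  seed: int = 0) -> dict:
    """Estimate per-intersection outcome prevalence on a real flat table.

    Complete-case: rows missing any category or every reading of either
    kind are dropped and counted.  Returns a dict with the long estimates
    table, the variable-selection report, the intersection lookup table and
    bookkeeping metadata.
    """
    spec = spec or RealDataSpec()
    cats = list(spec.category_columns)
    has_sbp = table[list(spec.systolic_columns)].notna().any(axis=1)
    has_dbp = table[list(spec.diastolic_columns)].notna().any(axis=1)
    complete = table[cats].notna().all(axis=1) & has_sbp & has_dbp
    df = table[complete].reset_index(drop=True).copy()
    n_dropped = int((~complete).sum())
    df["y"] = blood_pressure_outcome(df, spec)

    # integer-code each category column (sorted levels) and cross-classify
    level_maps = {c: {lv: k for k, lv in enumerate(sorted(df[c].unique()))}
                  for c in cats}
    sizes = [len(level_maps[c]) for c in cats]
    codes = np.column_stack([df[c].map(level_maps[c]).to_numpy() for c in cats])
    weights = np.cumprod([1] + sizes[::-1][:-1])[::-1]
    df["intersection_id"] = codes @ weights
    n_intersections = int(np.prod(sizes))

    lookup = pd.DataFrame(
        [
            {**dict(zip(cats, combo)),
             "intersection_id": int(np.array([level_maps[c][v] for c, v in
                                              zip(cats, combo)]) @ weights)}
            for combo in pd.MultiIndex.from_product(
                [sorted(level_maps[c]) for c in cats], names=cats)
        ]
    ).set_index("intersection_id").sort_index()

    coded = df.copy()
    for c in cats:
        coded[c] = df[c].map(level_maps[c])
    coded_schema = [(c, "categorical", sorted(level_maps[c].values()))
                    for c in cats]

    rng = np.random.default_rng(seed)
    estimates, var_rows, failures = [], [], []
    for method in methods:
        try:
            if method == "cross_classification":
                est = cross_classify(df, n_intersections=None)
                variables = None
                meta = {}
            elif method in ("main_effects", "saturated"):
                fit = fit_modified_poisson(coded, method, schema=coded_schema)
                est = (predict_intersections(fit, coded) if fit.converged else
                       PrevalenceEstimates(method=method, estimates=None,
                                           converged=False))
                variables, meta = None, {"converged": fit.converged}
            elif method == "maihda":
                fit = fit_maihda(coded, schema=coded_schema)
                est = predict_maihda(fit, coded)
                variables = None
                meta = {"variance": fit.random_intercept_variance}
            elif method == "cart":
                model = fit_cart(coded, features=cats,
                                 random_state=int(rng.integers(2**31)))
                est = predict_tree_intersections(model, _wrap(coded))
                variables, meta = model.variables_used, dict(model.tuning)
            elif method == "ctree":
                model = fit_ctree(coded, features=cats, continuous=set())
                est = predict_tree_intersections(model, _wrap(coded))
                variables, meta = model.variables_used, dict(model.tuning)
            elif method == "chaid":
                model = fit_chaid(coded, features=cats)
                est = predict_tree_intersections(model, _wrap(coded))
                variables, meta = model.variables_used, dict(model.tuning)
            elif method == "random_forest":
                model, vim = fit_random_forest(
                    coded, n_trees=rf_n_trees, features=cats,
                    n_permutations=rf_n_permutations,
                    seed=int(rng.integers(2**31)))
                est = predict_tree_intersections(model, _wrap(coded))
                variables = model.variables_used
                meta = {"mtry": model.tuning["mtry"]}
                for v in cats:
                    var_rows.append({
                        "method": method, "variable": v,
                        "impurity_vim": float(vim.impurity_vim[v]),
                        "permutation_p": float(vim.permutation_vim.loc[v, "p_value"]),
                        "used": bool(v in variables),
                    })
            else:
                raise ValueError(f"method {method!r} not applicable to real data")
        except Exception as exc:
            failures.append({"method": method,
                             "error": f"{type(exc).__name__}: {exc}"})
            continue
        if variables is not None and method != "random_forest":
            for v in cats:
                var_rows.append({"method": method, "variable": v,
                                 "impurity_vim": np.nan, "permutation_p": np.nan,
                                 "used": bool(v in variables)})
        if est.estimates is not None:
            frame = est.to_frame()
            estimates.append(frame)
    long = (pd.concat(estimates, ignore_index=True)
            if estimates else pd.DataFrame())
    return {
        "estimates": long,
        "variable_selection": pd.DataFrame(var_rows),
        "intersections": lookup,
        "n_dropped_rows": n_dropped,
        "n_intersections": n_intersections,
        "overall_prevalence": float(df["y"].mean()),
        "failures": failures,
    }


class _wrap:
    """Duck-typed stand-in exposing ``.data`` for the tree predictors."""

    def __init__(self, df: pd.DataFrame):
        self.data = df
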