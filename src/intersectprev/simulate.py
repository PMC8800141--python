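"""Synthetic data generation.

Two data-generating processes for a binary outcome over 192 social
intersections:

* **categorical** — X1 uniform over 4 categories, X2/X3/X5 Bernoulli, X4
  Bernoulli mediated by X3 (P(X4=1|X3=0)=0.4, P(X4=1|X3=1)=0.7), X6 uniform
  over 3 categories with no effect on the outcome.  Risk model on the
  log scale::

      log P(Y=1) = intercept + b11*[X1=1] + b12*[X1=2] + b13*[X1=3]
                   + b2*X2 + b3*X3 + b4*X4 + b5*X5
                   + b6*[X1=2 & X2=1] + b7*[X1=3 & X2=1] + b8*X3*X4*X5

* **mixed** — X1 and X6 standard normal (binned into sample quartiles /
  tertiles to form intersections), X2..X5 as above::

      log P(Y=1) = intercept + b1*X1 + b2*X2 + b3*X3 + b4*X4 + b5*X5
                   + b6*X1*X2*[X1>1 & X2=1] + b7*X3*X4*X5

Effect sizes are drawn per iteration from a normal centred at relative risk
1 (SD 0.30), truncated to a tier-specific pair of windows that excludes
near-null effects, and a whole coefficient draw is rejected whenever it
could produce an individual outcome probability above 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    INTERSECTION_LEVELS,
    N_INTERSECTIONS,
    RR_MEAN,
    RR_SD,
    InputType,
    ScenarioConfig,
)

__all__ = [
    "CoefficientDraw",
    "SimulatedDataset",
    "InadmissibleDrawError",
    "ProbabilityOverflowError",
    "draw_coefficients",
    "generate_dataset",
    "simulate_dataset",
    "true_intersection_prevalence",
    "intersection_patterns",
    "generate_nhanes_like_fixture",
]

COVARIATE_COLUMNS = ["x1", "x2", "x3", "x4", "x5", "x6"]

#: Weights used to encode an (x1..x6) category combination as a single
#: intersection id in [0, 191]: id = 48*x1 + 24*x2 + 12*x3 + 6*x4 + 3*x5 + x6.
_ID_WEIGHTS = np.array([48, 24, 12, 6, 3, 1])


class ProbabilityOverflowError(ValueError):
    """A coefficient draw implies an outcome probability above 1."""


class InadmissibleDrawError(RuntimeError):
    """No admissible coefficient draw found within the redraw budget."""


@dataclass
class CoefficientDraw:
    """One set of log-relative-risk coefficients for the generating model.

    ``beta_x1`` holds three values (the X1=1/2/3 category effects) for the
    categorical model and a single slope for the mixed model.  ``beta_x6`` is
    identically 0: X6 is the null variable.  ``beta_int_12b`` exists only in
    the categorical model (the X1=3 & X2=1 interaction).
    """

    intercept: float
    beta_x1: np.ndarray | float
    beta_x2: float
    beta_x3: float
    beta_x4: float
    beta_x5: float
    beta_int_12: float
    beta_int_345: float
    beta_int_12b: float | None = None
    input_type: InputType = InputType.CATEGORICAL
    beta_x6: float = field(default=0.0, init=False)  # null variable, fixed

    def __post_init__(self) -> None:
        self.input_type = InputType(self.input_type)
        if self.input_type is InputType.CATEGORICAL:
            self.beta_x1 = np.asarray(self.beta_x1, dtype=float)
            if self.beta_x1.shape != (3,):
                raise ValueError("categorical model needs three X1 effects")
            if self.beta_int_12b is None:
                raise ValueError("categorical model needs beta_int_12b")
        else:
            self.beta_x1 = float(self.beta_x1)
            if self.beta_int_12b is not None:
                raise ValueError("mixed model has no beta_int_12b term")

    def relative_risks(self) -> dict[str, float]:
        """All sampled effects on the RR scale (exp of each log coefficient)."""
        out: dict[str, float] = {}
        if self.input_type is InputType.CATEGORICAL:
            for k, b in enumerate(np.atleast_1d(self.beta_x1), start=1):
                out[f"x1.{k}"] = float(np.exp(b))
        else:
            out["x1"] = float(np.exp(self.beta_x1))
        out["x2"] = float(np.exp(self.beta_x2))
        out["x3"] = float(np.exp(self.beta_x3))
        out["x4"] = float(np.exp(self.beta_x4))
        out["x5"] = float(np.exp(self.beta_x5))
        out["int_12"] = float(np.exp(self.beta_int_12))
        if self.beta_int_12b is not None:
            out["int_12b"] = float(np.exp(self.beta_int_12b))
        out["int_345"] = float(np.exp(self.beta_int_345))
        return out

    def to_dict(self) -> dict:
        d = {
            "intercept": self.intercept,
            "beta_x1": np.asarray(self.beta_x1).tolist()
            if self.input_type is InputType.CATEGORICAL
            else self.beta_x1,
            "beta_x2": self.beta_x2,
            "beta_x3": self.beta_x3,
            "beta_x4": self.beta_x4,
            "beta_x5": self.beta_x5,
            "beta_x6": self.beta_x6,
            "beta_int_12": self.beta_int_12,
            "beta_int_12b": self.beta_int_12b,
            "beta_int_345": self.beta_int_345,
            "input_type": self.input_type.value,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientDraw":
        d = dict(d)
        d.pop("beta_x6", None)
        return cls(**d)

    @classmethod
    def null(cls, intercept: float, input_type: InputType = InputType.CATEGORICAL) -> "CoefficientDraw":
        """Testing hook: every relative risk forced to 1 (all betas 0)."""
        input_type = InputType(input_type)
        if input_type is InputType.CATEGORICAL:
            return cls(intercept, np.zeros(3), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                       input_type=input_type)
        return cls(intercept, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, None,
                   input_type=input_type)


def _sample_rr(rng: np.random.Generator, windows, size: int,
               upper_only: bool = False) -> np.ndarray:
    """Sample relative risks from N(1, 0.3) truncated to the window union."""
    (lo1, hi1), (lo2, hi2) = windows
    out = np.empty(size)
    filled = 0
    while filled < size:
        cand = rng.normal(RR_MEAN, RR_SD, size=8 * (size - filled) + 32)
        if upper_only:
            keep = (cand >= lo2) & (cand <= hi2)
        else:
            keep = ((cand >= lo1) & (cand <= hi1)) | ((cand >= lo2) & (cand <= hi2))
        ok = cand[keep]
        take = min(ok.size, size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def draw_coefficients(scenario: ScenarioConfig,
                      rng: np.random.Generator | int) -> CoefficientDraw:
    """Draw one admissible-candidate coefficient set for a scenario.

    Admissibility (no individual probability above 1) is checked when the
    draw is combined with data in :func:`generate_dataset`;
    :func:`simulate_dataset` wraps the redraw loop.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    windows = scenario.rr_windows
    boost = scenario.interaction_boost
    if scenario.input_type is InputType.CATEGORICAL:
        main = np.log(_sample_rr(rng, windows, 7))
        ints = np.log(_sample_rr(rng, windows, 3, upper_only=boost))
        return CoefficientDraw(
            intercept=scenario.intercept,
            beta_x1=main[:3],
            beta_x2=main[3], beta_x3=main[4], beta_x4=main[5], beta_x5=main[6],
            beta_int_12=ints[0], beta_int_12b=ints[1], beta_int_345=ints[2],
            input_type=scenario.input_type,
        )
    main = np.log(_sample_rr(rng, windows, 5))
    ints = np.log(_sample_rr(rng, windows, 2, upper_only=boost))
    return CoefficientDraw(
        intercept=scenario.intercept,
        beta_x1=main[0],
        beta_x2=main[1], beta_x3=main[2], beta_x4=main[3], beta_x5=main[4],
        beta_int_12=ints[0], beta_int_345=ints[1], beta_int_12b=None,
        input_type=scenario.input_type,
    )


def _categorical_log_risk(coeffs: CoefficientDraw, x1, x2, x3, x4, x5):
    """Vectorised log-risk for the categorical generating formula."""
    b1 = np.asarray(coeffs.beta_x1)
    x1 = np.asarray(x1)
    lp = np.full(x1.shape, coeffs.intercept, dtype=float)
    lp += np.where(x1 >= 1, b1[np.clip(x1, 1, 3) - 1], 0.0)
    lp += coeffs.beta_x2 * x2 + coeffs.beta_x3 * x3
    lp += coeffs.beta_x4 * x4 + coeffs.beta_x5 * x5
    lp += coeffs.beta_int_12 * ((x1 == 2) & (x2 == 1))
    lp += coeffs.beta_int_12b * ((x1 == 3) & (x2 == 1))
    lp += coeffs.beta_int_345 * (x3 * x4 * x5)
    return lp


def _mixed_log_risk(coeffs: CoefficientDraw, x1, x2, x3, x4, x5):
    lp = np.full(np.shape(x1), coeffs.intercept, dtype=float)
    lp += coeffs.beta_x1 * x1
    lp += coeffs.beta_x2 * x2 + coeffs.beta_x3 * x3
    lp += coeffs.beta_x4 * x4 + coeffs.beta_x5 * x5
    lp += coeffs.beta_int_12 * x1 * x2 * ((x1 > 1) & (x2 == 1))
    lp += coeffs.beta_int_345 * (x3 * x4 * x5)
    return lp


def _risk_pattern_grid(coeffs: CoefficientDraw) -> np.ndarray:
    """Log risk at each of the 64 (x1,x2,x3,x4,x5) categorical patterns."""
    x1, x2, x3, x4, x5 = np.meshgrid(
        np.arange(4), np.arange(2), np.arange(2), np.arange(2), np.arange(2),
        indexing="ij",
    )
    return _categorical_log_risk(coeffs, x1.ravel(), x2.ravel(), x3.ravel(),
                                 x4.ravel(), x5.ravel())


def max_pattern_probability(coeffs: CoefficientDraw) -> float:
    """Largest outcome probability over all categorical covariate patterns."""
    if coeffs.input_type is not InputType.CATEGORICAL:
        raise ValueError("pattern enumeration applies to the categorical model")
    return float(np.exp(_risk_pattern_grid(coeffs).max()))


def _draw_covariates(scenario: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = scenario.n_individuals
    if scenario.input_type is InputType.CATEGORICAL:
        x1 = rng.integers(0, 4, size=n)
        x6 = rng.integers(0, 3, size=n)
    else:
        x1 = rng.standard_normal(n)
        x6 = rng.standard_normal(n)
    x2 = (rng.random(n) < 0.2).astype(np.int64)
    x3 = (rng.random(n) < 0.5).astype(np.int64)
    # X4 is mediated by X3
    p4 = np.where(x3 == 1, 0.7, 0.4)
    x4 = (rng.random(n) < p4).astype(np.int64)
    x5 = (rng.random(n) < 0.25).astype(np.int64)
    return pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, "x4": x4, "x5": x5, "x6": x6})


def _quantile_bin(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin into sample quantile groups 0..n_bins-1 (computed per sample)."""
    binned = pd.qcut(values, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(binned, dtype=np.int64)


def assign_intersection_ids(df: pd.DataFrame, input_type: InputType) -> np.ndarray:
    """Intersection id in [0, 191] from the (binned) covariate categories."""
    if InputType(input_type) is InputType.CATEGORICAL:
        cats = df[COVARIATE_COLUMNS].to_numpy(dtype=np.int64)
    else:
        cats = np.column_stack([
            _quantile_bin(df["x1"].to_numpy(), 4),
            df[["x2", "x3", "x4", "x5"]].to_numpy(dtype=np.int64),
            _quantile_bin(df["x6"].to_numpy(), 3),
        ])
    return cats @ _ID_WEIGHTS


def intersection_patterns() -> pd.DataFrame:
    """All 192 intersection category patterns, indexed by intersection id."""
    grids = np.meshgrid(*[np.arange(k) for k in INTERSECTION_LEVELS], indexing="ij")
    cats = np.column_stack([g.ravel() for g in grids])
    ids = cats @ _ID_WEIGHTS
    out = pd.DataFrame(cats, columns=COVARIATE_COLUMNS)
    out.index = pd.Index(ids, name="intersection_id")
    return out.sort_index()


@dataclass
class SimulatedDataset:
    """Individual-level simulated data plus the intersection truth table.

    Attributes
    ----------
    data
        One row per individual: x1..x6, y, true_prob, intersection_id.
    intersections
        One row per intersection id present in the design (all 192):
        member count and true prevalence (NaN for empty intersections of
        the mixed model, whose truth is a member average).
    """

    data: pd.DataFrame
    scenario: ScenarioConfig
    coefficients: CoefficientDraw
    n_coefficient_redraws: int = 0

    def __post_init__(self) -> None:
        self.intersections = self._build_intersection_table()

    def _build_intersection_table(self) -> pd.DataFrame:
        ids = pd.Index(np.arange(N_INTERSECTIONS), name="intersection_id")
        counts = (
            self.data.groupby("intersection_id")["y"].size().reindex(ids, fill_value=0)
        )
        if self.scenario.input_type is InputType.CATEGORICAL:
            pat = intersection_patterns()
            truth = np.exp(
                _categorical_log_risk(
                    self.coefficients,
                    pat["x1"].to_numpy(), pat["x2"].to_numpy(), pat["x3"].to_numpy(),
                    pat["x4"].to_numpy(), pat["x5"].to_numpy(),
                )
            )
            truth = pd.Series(truth, index=ids, name="true_prevalence")
        else:
            truth = (
                self.data.groupby("intersection_id")["true_prob"]
                .mean()
                .reindex(ids)
                .rename("true_prevalence")
            )
        return pd.DataFrame({"n_members": counts, "true_prevalence": truth})

    @property
    def n_empty_intersections(self) -> int:
        return int((self.intersections["n_members"] == 0).sum())

    @property
    def overall_prevalence(self) -> float:
        return float(self.data["y"].mean())

    def to_csv(self, path: str | Path) -> None:
        """Write individuals to CSV with a JSON sidecar of scenario+draw."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = {
            "scenario": {
                "input_type": self.scenario.input_type.value,
                "prevalence_tier": self.scenario.prevalence_tier.value,
                "n_individuals": self.scenario.n_individuals,
                "n_iterations": self.scenario.n_iterations,
                "master_seed": self.scenario.master_seed,
                "interaction_boost": self.scenario.interaction_boost,
            },
            "coefficients": self.coefficients.to_dict(),
            "n_coefficient_redraws": self.n_coefficient_redraws,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimulatedDataset":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        scenario = ScenarioConfig(**sidecar["scenario"])
        coeffs = CoefficientDraw.from_dict(sidecar["coefficients"])
        return cls(data=data, scenario=scenario, coefficients=coeffs,
                   n_coefficient_redraws=sidecar.get("n_coefficient_redraws", 0))


def generate_dataset(scenario: ScenarioConfig, coeffs: CoefficientDraw,
                     rng: np.random.Generator | int) -> SimulatedDataset:
    """Generate one dataset from a given coefficient draw.

    Raises
    ------
    ProbabilityOverflowError
        If the draw implies an outcome probability above 1 — for the
        categorical model this is checked analytically over all covariate
        patterns; for the mixed model over the realised sample (a universal
        guarantee is impossible with unbounded continuous X1).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if coeffs.input_type is not scenario.input_type:
        raise ValueError("coefficient draw input_type does not match scenario")
    df = _draw_covariates(scenario, rng)
    return _finish_dataset(scenario, coeffs, df, rng)


def _finish_dataset(scenario, coeffs, df, rng, n_redraws: int = 0) -> SimulatedDataset:
    if scenario.input_type is InputType.CATEGORICAL:
        if max_pattern_probability(coeffs) > 1.0:
            raise ProbabilityOverflowError(
                f"draw implies pattern probability > 1 in scenario {scenario.label()}"
            )
        lp = _categorical_log_risk(
            coeffs, df["x1"].to_numpy(), df["x2"].to_numpy(), df["x3"].to_numpy(),
            df["x4"].to_numpy(), df["x5"].to_numpy(),
        )
    else:
        lp = _mixed_log_risk(
            coeffs, df["x1"].to_numpy(), df["x2"].to_numpy(), df["x3"].to_numpy(),
            df["x4"].to_numpy(), df["x5"].to_numpy(),
        )
    prob = np.exp(lp)
    if prob.max() > 1.0:
        raise ProbabilityOverflowError(
            f"draw implies individual probability > 1 in scenario {scenario.label()}"
        )
    out = df.copy()
    out["true_prob"] = prob
    out["y"] = (rng.random(len(df)) < prob).astype(np.int64)
    out["intersection_id"] = assign_intersection_ids(df, scenario.input_type)
    return SimulatedDataset(data=out, scenario=scenario, coefficients=coeffs,
                            n_coefficient_redraws=n_redraws)


def simulate_dataset(scenario: ScenarioConfig, iteration: int = 0,
                     max_redraws: int = 1000) -> SimulatedDataset:
    """Draw admissible coefficients and generate the dataset for one iteration.

    The covariate sample is drawn once; coefficient draws are rejected and
    redrawn (up to ``max_redraws`` times) until no individual probability
    exceeds 1.
    """
    rng = scenario.iteration_rng(iteration)
    df = _draw_covariates(scenario, rng)
    for redraw in range(max_redraws + 1):
        coeffs = draw_coefficients(scenario, rng)
        try:
            return _finish_dataset(scenario, coeffs, df, rng, n_redraws=redraw)
        except ProbabilityOverflowError:
            continue
    raise InadmissibleDrawError(
        f"no admissible coefficient draw in {max_redraws} redraws for "
        f"scenario {scenario.label()}"
    )


def true_intersection_prevalence(dataset: SimulatedDataset) -> pd.Series:
    """True prevalence P_i per intersection id.

    Categorical model: the generating-formula value at the intersection's
    covariate pattern (defined for all 192 ids).  Mixed model: the mean
    true probability of the intersection's members; empty intersections
    are NaN.
    """
    return dataset.intersections["true_prevalence"].copy()


# ---------------------------------------------------------------------------
# Blood-pressure-style fixture table (synthetic stand-in for survey data)
# ---------------------------------------------------------------------------

_SEX = ["female", "male"]
_RACE = ["white", "black", "hispanic", "asian", "other"]
_AGE = ["18-39", "40-59", "60+"]
_POVERTY = ["below", "above"]

# Latent mean systolic/diastolic shifts (mmHg).  Age dominates, echoing the
# usual epidemiology of hypertension; constants chosen so the >=130/>=80
# averaged-reading rule yields a marginal prevalence near 41%.
_AGE_SBP = {"18-39": 0.0, "40-59": 9.0, "60+": 22.0}
_AGE_DBP = {"18-39": 0.0, "40-59": 5.0, "60+": 3.0}
_SEX_SBP = {"female": 0.0, "male": 5.0}
_RACE_SBP = {"white": 0.0, "black": 6.0, "hispanic": 2.0, "asian": 1.0, "other": 2.0}
_POV_SBP = {"below": 2.0, "above": 0.0}
_BASE_SBP = 107.0
_BASE_DBP = 64.0


def generate_nhanes_like_fixture(n: int, seed: int = 0,
                                 one_per_cell: bool = False) -> pd.DataFrame:
    """Synthetic flat table shaped like a blood-pressure survey extract.

    Columns: sex_gender (2 levels), race_ethnicity (5), age_group (3),
    poverty (2) — 60 intersections — plus up to three systolic and three
    diastolic readings per row.  The marginal prevalence of high blood
    pressure (mean systolic >= 130 or mean diastolic >= 80) is tuned near
    41%.  With ``one_per_cell`` the first 60 rows enumerate each cell once.
    """
    if n < 60:
        raise ValueError("need n >= 60 to populate 60 intersections")
    rng = np.random.default_rng(seed)
    cells = pd.MultiIndex.from_product(
        [_SEX, _RACE, _AGE, _POVERTY],
        names=["sex_gender", "race_ethnicity", "age_group", "poverty"],
    ).to_frame(index=False)
    if one_per_cell:
        reps = cells.sample(n=n - 60, replace=True, random_state=rng.integers(2**31))
        df = pd.concat([cells, reps], ignore_index=True)
    else:
        df = cells.sample(n=n, replace=True, random_state=rng.integers(2**31),
                          ignore_index=True)
        # guarantee every cell appears when the sample is large enough
        missing = cells.merge(df.drop_duplicates(), how="left", indicator=True)
        missing = missing[missing["_merge"] == "left_only"].drop(columns="_merge")
        if len(missing) and n >= 60:
            df.iloc[: len(missing)] = missing.to_numpy()
    sbp_mu = (
        _BASE_SBP
        + df["age_group"].map(_AGE_SBP)
        + df["sex_gender"].map(_SEX_SBP)
        + df["race_ethnicity"].map(_RACE_SBP)
        + df["poverty"].map(_POV_SBP)
        + rng.normal(0.0, 14.0, size=len(df))
    ).to_numpy()
    dbp_mu = (
        _BASE_DBP
        + df["age_group"].map(_AGE_DBP)
        + 0.25 * (sbp_mu - _BASE_SBP)
        + rng.normal(0.0, 8.0, size=len(df))
    ).to_numpy()
    for k in (1, 2, 3):
        df[f"sbp{k}"] = np.round(sbp_mu + rng.normal(0.0, 4.0, size=len(df)), 1)
        df[f"dbp{k}"] = np.round(dbp_mu + rng.normal(0.0, 3.0, size=len(df)), 1)
    # a third reading is sometimes missing, as in real survey exams
    drop3 = rng.random(len(df)) < 0.1
    df.loc[drop3, ["sbp3", "dbp3"]] = np.nan
    return df
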