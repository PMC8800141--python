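"""Synthetic-data generator: coefficient sampling, generation, truth tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from intersectprev import (
    CoefficientDraw,
    ScenarioConfig,
    draw_coefficients,
    generate_dataset,
    simulate_dataset,
    true_intersection_prevalence,
)
from intersectprev.config import InputType, PrevalenceTier, RR_WINDOWS
from intersectprev.simulate import (
    ProbabilityOverflowError,
    generate_nhanes_like_fixture,
    intersection_patterns,
    max_pattern_probability,
)

RARE_WINDOWS = RR_WINDOWS[PrevalenceTier.RARE]


def in_windows(rr, windows):
    (lo1, hi1), (lo2, hi2) = windows
    return (lo1 <= rr <= hi1) or (lo2 <= rr <= hi2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1),
       st.sampled_from(["rare", "common"]),
       st.sampled_from(["categorical", "mixed"]))
def test_coefficient_draw_respects_truncation_windows(seed, tier, inputs):
    """Every sampled relative risk lies in the tier's window union; X6 is null."""
    sc = ScenarioConfig(inputs, tier, 100, master_seed=0)
    draw = draw_coefficients(sc, seed)
    for name, rr in draw.relative_risks().items():
        assert in_windows(rr, sc.rr_windows), (name, rr)
    assert draw.beta_x6 == 0.0
    assert draw.intercept == sc.intercept


def test_interaction_boost_uses_harmful_window_only():
    sc = ScenarioConfig("categorical", "common", 100, master_seed=0,
                        interaction_boost=True)
    for seed in range(25):
        rr = draw_coefficients(sc, seed).relative_risks()
        for key in ("int_12", "int_12b", "int_345"):
            assert rr[key] >= 1.11


def test_null_draw_gives_baseline_probability():
    """All relative risks forced to 1: every individual risk is exp(-3)."""
    sc = ScenarioConfig("categorical", "rare", 500, master_seed=3)
    ds = generate_dataset(sc, CoefficientDraw.null(-3.0), 42)
    assert np.allclose(ds.data["true_prob"], np.exp(-3.0))
    truth = true_intersection_prevalence(ds)
    assert np.allclose(truth, np.exp(-3.0))
    assert len(truth) == 192


def test_categorical_formula_hand_evaluated():
    """One covariate pattern matches the generating formula computed by hand."""
    coeffs = CoefficientDraw(
        intercept=-3.0,
        beta_x1=np.log([1.5, 0.5, 1.3]),
        beta_x2=np.log(0.7), beta_x3=np.log(1.4), beta_x4=np.log(0.6),
        beta_x5=np.log(1.25), beta_int_12=np.log(1.35),
        beta_int_12b=np.log(0.75), beta_int_345=np.log(1.3),
    )
    # pattern x1=2, x2=1, x3=1, x4=1, x5=0: intercept + b1.2 + b2 + b3 + b4
    # + the (X1=2 & X2=1) interaction; the X3*X4*X5 term is off (x5=0)
    expected = np.exp(-3.0) * 0.5 * 0.7 * 1.4 * 0.6 * 1.35
    sc = ScenarioConfig("categorical", "rare", 64, master_seed=9)
    ds = generate_dataset(sc, coeffs, 7)
    pat = intersection_patterns()
    ids = pat[(pat.x1 == 2) & (pat.x2 == 1) & (pat.x3 == 1)
              & (pat.x4 == 1) & (pat.x5 == 0)].index
    truth = true_intersection_prevalence(ds)
    assert np.allclose(truth[ids], expected)
    # x6 does not move the truth: all three x6 levels share the value
    assert len(ids) == 3


def test_design_has_exactly_192_intersections():
    pat = intersection_patterns()
    assert len(pat) == 192
    assert pat.index.is_unique
    assert (pat.index == np.arange(192)).all()


def test_probability_overflow_rejected():
    """A draw implying risk above 1 is refused for the categorical model."""
    coeffs = CoefficientDraw(
        intercept=-1.5,
        beta_x1=np.log([1.8, 1.8, 1.8]),
        beta_x2=np.log(1.8), beta_x3=np.log(1.8), beta_x4=np.log(1.8),
        beta_x5=np.log(1.8), beta_int_12=np.log(1.8),
        beta_int_12b=np.log(1.8), beta_int_345=np.log(1.8),
    )
    assert max_pattern_probability(coeffs) > 1
    sc = ScenarioConfig("categorical", "common", 200, master_seed=0)
    with pytest.raises(ProbabilityOverflowError):
        generate_dataset(sc, coeffs, 0)


def test_generated_probabilities_admissible_and_reproducible():
    sc = ScenarioConfig("mixed", "common", 3000, master_seed=21)
    a = simulate_dataset(sc, 4)
    b = simulate_dataset(sc, 4)
    pd.testing.assert_frame_equal(a.data, b.data)
    assert a.data["true_prob"].between(0, 1).all()
    c = simulate_dataset(sc, 5)
    assert not a.data["y"].equals(c.data["y"])


def test_covariate_marginals_match_design(common_categorical_mid):
    """X2..X5 Bernoulli rates and the X3->X4 mediation at their design values."""
    df = common_categorical_mid.data
    assert df["x2"].mean() == pytest.approx(0.2, abs=0.02)
    assert df["x3"].mean() == pytest.approx(0.5, abs=0.02)
    assert df["x5"].mean() == pytest.approx(0.25, abs=0.02)
    p4_given_x3 = df.groupby("x3")["x4"].mean()
    assert p4_given_x3[0] == pytest.approx(0.4, abs=0.03)
    assert p4_given_x3[1] == pytest.approx(0.7, abs=0.03)


def test_mixed_truth_is_member_average_and_bins_balanced(rare_mixed_mid):
    ds = rare_mixed_mid
    got = true_intersection_prevalence(ds)
    manual = ds.data.groupby("intersection_id")["true_prob"].mean()
    pd.testing.assert_series_equal(got.dropna(), manual, check_names=False)
    # quartile/tertile binning gives roughly N/192 members per intersection
    counts = ds.intersections["n_members"]
    assert counts.sum() == len(ds.data)
    expected = len(ds.data) / 192
    assert counts.mean() == pytest.approx(expected)
    assert counts.max() < 6 * expected


def test_mixed_truth_matches_monte_carlo_oracle(rare_mixed_mid):
    """Fresh Bernoulli draws at members' risks reproduce the stored truth."""
    ds = rare_mixed_mid
    rng = np.random.default_rng(0)
    some_id = int(ds.intersections["n_members"].idxmax())
    members = ds.data[ds.data["intersection_id"] == some_id]
    draws = rng.random((4000, len(members))) < members["true_prob"].to_numpy()
    mc = draws.mean()
    se = float(members["true_prob"].std() / np.sqrt(4000 * len(members)) + 1e-9)
    truth = ds.intersections.loc[some_id, "true_prevalence"]
    assert mc == pytest.approx(truth, abs=max(5 * se, 0.003))


def test_x6_is_independent_of_outcome(common_categorical_mid):
    """Chi-square of X6 vs Y does not reject at a large sample size."""
    df = common_categorical_mid.data
    table = pd.crosstab(df["x6"], df["y"]).to_numpy()
    _, p, _, _ = stats.chi2_contingency(table)
    assert p > 0.001


def test_csv_round_trip(tmp_path, rare_categorical_small):
    path = tmp_path / "ds.csv"
    rare_categorical_small.to_csv(path)
    from intersectprev.simulate import SimulatedDataset

    back = SimulatedDataset.from_csv(path)
    pd.testing.assert_frame_equal(
        back.data, rare_categorical_small.data, check_dtype=False)
    pd.testing.assert_frame_equal(
        back.intersections, rare_categorical_small.intersections)
    assert back.scenario == rare_categorical_small.scenario


@pytest.mark.parametrize("n,one_per_cell", [(9576, False), (60, True)])
def test_fixture_table_covers_all_60_cells(n, one_per_cell):
    df = generate_nhanes_like_fixture(n, seed=1, one_per_cell=one_per_cell)
    cells = df.groupby(["sex_gender", "race_ethnicity", "age_group",
                        "poverty"]).size()
    assert len(cells) == 60
    assert len(df) == n
    if one_per_cell:
        assert (cells == 1).all()


def test_fixture_prevalence_near_41_percent():
    from intersectprev.runner import RealDataSpec, blood_pressure_outcome

    df = generate_nhanes_like_fixture(9576, seed=0)
    prev = blood_pressure_outcome(df, RealDataSpec()).mean()
    assert prev == pytest.approx(0.41, abs=0.03)
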