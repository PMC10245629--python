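"""Propensity estimation, greedy caliper matching, and balance diagnostics.

Independent oracles: a hand-coded Newton (IRLS) logistic solver, and a
brute-force greedy matcher that re-derives the caliper and processing
order from their definitions.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pmxcea
from pmxcea.exceptions import ConfigurationError, SeparationError
from pmxcea.matching import (
    absolute_standardized_difference,
    balance_report,
    fit_propensity,
    match_1_to_k,
)

from conftest import patients_frame


# ---------------------------------------------------------------- logistic fit

def newton_logistic(X, y, iterations=60):
    """Direct IRLS/Newton maximum-likelihood logistic fit (oracle)."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(iterations):
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        W = p * (1 - p)
        beta = beta + np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - p))
    return beta


def test_fit_matches_newton_oracle():
    """8-patient, 2-covariate fit equals independently run Newton iterations."""
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(8)],
            "x1": [0.2, 1.5, -0.3, 2.2, 0.9, -1.1, 1.8, 0.4],
            "x2": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
            "group": ["pmx", "control", "control", "pmx", "control", "pmx", "pmx", "control"],
        }
    )
    model = fit_propensity(df, covariate_list=("x1", "x2"))
    oracle = newton_logistic(
        df[["x1", "x2"]].to_numpy(), (df["group"] == "pmx").to_numpy(float)
    )
    assert model.intercept == pytest.approx(oracle[0], abs=1e-6)
    assert model.coefficients["x1"] == pytest.approx(oracle[1], abs=1e-6)
    assert model.coefficients["x2"] == pytest.approx(oracle[2], abs=1e-6)
    scores = model.predict(df)
    assert ((scores > 0) & (scores < 1)).all()


def test_degenerate_all_zero_covariates():
    """With uninformative covariates the fit reduces to the marginal odds."""
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(8)],
            "x1": np.zeros(8),
            "group": ["pmx", "pmx", "control", "control", "control", "control", "control", "control"],
        }
    )
    model = fit_propensity(df, covariate_list=("x1",))
    assert model.intercept == pytest.approx(np.log(2 / 6), abs=1e-4)
    assert model.coefficients["x1"] == pytest.approx(0.0, abs=1e-6)


def test_perfect_separation_raises():
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(8)],
            "x1": [1.0, 2.0, 3.0, 4.0, -1.0, -2.0, -3.0, -4.0],
            "group": ["pmx"] * 4 + ["control"] * 4,
        }
    )
    with pytest.raises(SeparationError):
        fit_propensity(df, covariate_list=("x1",))


# ---------------------------------------------------------------- matching

def make_ps(treated, controls):
    ps = pd.Series({**treated, **controls})
    return ps, list(treated), list(controls)


def test_nearest_three_within_wide_caliper():
    ps, t, c = make_ps({"t1": 0.5}, {"c1": 0.49, "c2": 0.51, "c3": 0.52, "c4": 0.9})
    matched = match_1_to_k(ps, t, c, k=3, caliper_sd_multiplier=10.0, seed=0)
    assert set(matched.match_map["t1"]) == {"c1", "c2", "c3"}


def test_treated_dropped_when_caliper_starves_it():
    ps, t, c = make_ps({"t1": 0.5}, {"c1": 0.49, "c2": 0.51, "c3": 0.52, "c4": 0.9})
    # caliper narrow enough to leave only two in-range controls
    sd = ps.std(ddof=1)
    matched = match_1_to_k(ps, t, c, k=3, caliper_sd_multiplier=0.015 / sd, seed=0)
    assert matched.match_map == {}


def test_k_below_one_rejected():
    ps, t, c = make_ps({"t1": 0.5}, {"c1": 0.49})
    with pytest.raises(ConfigurationError):
        match_1_to_k(ps, t, c, k=0)


def test_no_treated_gives_empty_result():
    ps = pd.Series({"c1": 0.4, "c2": 0.6})
    matched = match_1_to_k(ps, [], ["c1", "c2"], k=3, seed=0)
    assert matched.match_map == {}


def greedy_oracle(ps, treated, controls, k, multiplier, seed):
    """Brute-force greedy matcher re-deriving caliper and order independently."""
    pool = ps.loc[sorted(treated) + sorted(controls)]
    caliper = multiplier * pool.std(ddof=1)
    order = np.random.default_rng(seed).permutation(len(sorted(treated)))
    sorted_treated = sorted(treated)
    available = set(controls)
    result = {}
    for idx in order:
        t = sorted_treated[idx]
        cand = sorted(
            (c for c in available if abs(ps[c] - ps[t]) <= caliper),
            key=lambda c: (abs(ps[c] - ps[t]), c),
        )
        if len(cand) >= k:
            result[t] = cand[:k]
            available -= set(cand[:k])
    return result, caliper


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_greedy_equals_brute_force_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    treated = {f"t{i:03d}": rng.beta(3, 5) for i in range(30)}
    controls = {f"c{i:03d}": rng.beta(2, 6) for i in range(150)}
    ps, t, c = make_ps(treated, controls)
    matched = match_1_to_k(ps, t, c, k=3, caliper_sd_multiplier=0.2, seed=seed)
    oracle, caliper = greedy_oracle(ps, t, c, 3, 0.2, seed)
    assert matched.caliper_width == pytest.approx(caliper)
    assert matched.match_map == oracle


@settings(max_examples=25)
@given(
    seed=st.integers(0, 10_000),
    n_treated=st.integers(1, 15),
    n_control=st.integers(5, 60),
    multiplier=st.floats(0.05, 1.0),
)
def test_matching_invariants_on_random_instances(seed, n_treated, n_control, multiplier):
    """Complete sets, no control reuse, caliper respected — on every run.

    MatchedCohort re-checks these at construction; here they are asserted
    independently of that guard.
    """
    rng = np.random.default_rng(seed)
    ps = pd.Series(
        rng.uniform(0.05, 0.95, n_treated + n_control),
        index=[f"t{i}" for i in range(n_treated)] + [f"c{i}" for i in range(n_control)],
    )
    t, c = list(ps.index[:n_treated]), list(ps.index[n_treated:])
    matched = match_1_to_k(ps, t, c, k=3, caliper_sd_multiplier=multiplier, seed=seed)
    used = [cid for ids in matched.match_map.values() for cid in ids]
    assert len(used) == len(set(used))
    for tid, ids in matched.match_map.items():
        assert len(ids) == 3
        for cid in ids:
            assert abs(ps[tid] - ps[cid]) <= matched.caliper_width + 1e-12


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_wider_caliper_does_not_lose_matches(seed):
    """With a dense control reservoir, widening the caliper only rescues
    treated patients (a statistical regularity of greedy matching, not a
    theorem — adversarial sparse instances can violate it)."""
    rng = np.random.default_rng(200 + seed)
    ps = pd.Series(
        np.concatenate([rng.beta(3, 4, 25), rng.beta(3, 5, 250)]),
        index=[f"t{i}" for i in range(25)] + [f"c{i}" for i in range(250)],
    )
    t, c = list(ps.index[:25]), list(ps.index[25:])
    counts = [
        len(match_1_to_k(ps, t, c, k=3, caliper_sd_multiplier=m, seed=seed).match_map)
        for m in (0.05, 0.1, 0.2, 0.5, 1.0)
    ]
    assert counts == sorted(counts)


# ---------------------------------------------------------------- balance

def test_asd_identical_samples_zero():
    assert absolute_standardized_difference([1, 2, 3], [1, 2, 3]) == 0.0
    assert absolute_standardized_difference([1, 1, 0, 0], [0, 1, 0, 1], "binary") == 0.0


def test_asd_hand_value():
    # 100 * |1 - 2| / sqrt((4/3 + 4/3) / 2) = 86.60
    value = absolute_standardized_difference([0, 0, 2, 2], [1, 1, 3, 3])
    assert value == pytest.approx(86.60, abs=0.01)


def test_asd_zero_variance_nonzero_difference_is_infinite():
    with pytest.warns(UserWarning):
        assert absolute_standardized_difference([1, 1], [2, 2]) == np.inf


def test_asd_nonnegative_property():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b = rng.normal(size=20), rng.normal(size=25)
        assert absolute_standardized_difference(a, b) >= 0


def test_randomized_data_balanced_before_matching(life_table):
    """With treatment assigned by a fair coin, even pre-matching ASDs are small."""
    rng = np.random.default_rng(42)
    n = 12_000
    cohort = pmxcea.generate_cohort(pmxcea.default_config_from_table1(n_patients=n, seed=3))
    cohort = cohort.copy()
    coin = rng.random(n) < 0.2
    cohort["pmx_day"] = np.where(coin, 1.0, np.nan)
    cohort["group"] = np.where(coin, "pmx", "control")
    ps = pd.Series(0.25 + rng.normal(0, 0.01, n), index=cohort["patient_id"])
    treated = list(cohort.loc[coin, "patient_id"])
    controls = list(cohort.loc[~coin, "patient_id"])
    matched = match_1_to_k(ps, treated, controls, k=3, caliper_sd_multiplier=5.0, seed=0)
    report = balance_report(cohort, matched)
    assert (report.table["asd_before"] < 10).all()
    assert report.all_balanced


def test_zero_threshold_cannot_be_balanced(labeled_cohort, fitted):
    report = balance_report(
        labeled_cohort[0], fitted.matched, threshold=0.0
    )
    assert not report.all_balanced
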