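"""Cost aggregation, QALY chain, ICER, sensitivity/subgroup analyses, WTP."""

import numpy as np
import pandas as pd
import pytest

from pmxcea.economics import (
    COST_CATEGORIES,
    AdjustmentFactors,
    cea_analysis,
    convert_jpy_to_eur,
    cost_breakdown,
    icer,
    patient_qaly,
    qaly_delta,
    sensitivity_analysis,
    subgroup_analysis,
    wtp_decision,
)
from pmxcea.exceptions import (
    ConfigurationError,
    DataError,
    StratumError,
    UndefinedICERError,
)
from pmxcea.lifetable import LifeTable, make_fixture_life_table

from conftest import patients_frame


class TestConversion:
    def test_wtp_constant(self):
        assert round(convert_jpy_to_eur(5_000_000)) == 38462

    @pytest.mark.parametrize("jpy, eur", [(0, 0.0), (130, 1.0), (1300, 10.0)])
    def test_simple_conversions(self, jpy, eur):
        assert convert_jpy_to_eur(jpy) == pytest.approx(eur)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            convert_jpy_to_eur(100, rate=0)


def constant_table(le: float) -> LifeTable:
    return LifeTable(knots={"total": (np.array([0.0, 120.0]), np.array([le, le]))})


class TestQALYChain:
    def test_decedent_contributes_zero(self):
        assert patient_qaly(70, True, constant_table(10.0)) == (0.0, 0.0, 0.0)

    def test_survivor_chain(self):
        le, lyg, qaly = patient_qaly(70, False, constant_table(10.0))
        assert (le, lyg, qaly) == pytest.approx((10.0, 5.1, 3.519))

    def test_identity_factors(self):
        le, _, qaly = patient_qaly(70, False, constant_table(10.0), AdjustmentFactors(1.0, 1.0))
        assert qaly == le

    def test_multiplicative_chain_property(self):
        table = make_fixture_life_table()
        for age in (25, 50, 75, 100):
            for r, u in ((0.51, 0.69), (0.3, 0.6), (0.7, 0.8)):
                le, lyg, qaly = patient_qaly(age, False, table, AdjustmentFactors(r, u))
                assert qaly == pytest.approx(le * r * u)
                assert lyg == pytest.approx(le * r)


class TestICER:
    def test_published_base_case(self):
        value = icer(6935, qaly_delta(1.70, AdjustmentFactors(0.51, 0.69)))
        assert value == pytest.approx(11592.5, abs=0.1)

    def test_zero_cost_difference(self):
        assert icer(0.0, 0.5) == 0.0
        assert icer(0.0, 0.0) == 0.0

    def test_alternative_factors(self):
        value = icer(6935, qaly_delta(1.70, AdjustmentFactors(0.3, 0.6)))
        assert value == pytest.approx(6935 / 0.306, abs=0.1)

    def test_zero_qaly_delta_undefined(self):
        with pytest.raises(UndefinedICERError):
            icer(100.0, 0.0)


class TestCostBreakdown:
    def test_single_patient_per_arm_difference(self):
        df = patients_frame(
            [
                {"patient_id": "T", "pmx_day": 1.0, "cost_jpy_treatment": 130.0},
                {"patient_id": "C"},
            ]
        )
        costs = cost_breakdown(df, ["T"], ["C"])
        assert costs.table.loc["treatment", "difference"] == pytest.approx(1.0)
        assert costs.total_difference_eur == pytest.approx(1.0)

    def test_mean_of_totals_equals_sum_of_category_means(self, big_cohort):
        treated = list(big_cohort["patient_id"][:40])
        controls = list(big_cohort["patient_id"][40:160])
        costs = cost_breakdown(big_cohort, treated, controls)
        for arm in ("treated", "control"):
            cat_sum = costs.table.loc[list(COST_CATEGORIES), f"mean_{arm}"].sum()
            assert costs.table.loc["total", f"mean_{arm}"] == pytest.approx(cat_sum)

    def test_missing_category_rejected(self):
        df = patients_frame([{"patient_id": "T"}, {"patient_id": "C"}])
        with pytest.raises(DataError):
            cost_breakdown(df.drop(columns=["cost_jpy_meals"]), ["T"], ["C"])

    def test_device_cost_dominates_between_arm_difference(self, fitted):
        """On the default synthetic cohort the 'treatment' category carries
        the largest arm difference, as the device cost sits there."""
        diffs = fitted.costs.table.drop(index="total")["difference"]
        assert diffs.idxmax() == "treatment"
        assert diffs["treatment"] == pytest.approx(4461, rel=0.15)


class TestCEA:
    def test_equal_benefit_is_undefined(self):
        df = patients_frame(
            [
                {"patient_id": "T", "age": 70, "pmx_day": 1.0, "cost_jpy_treatment": 130.0},
                {"patient_id": "C", "age": 70},
            ]
        )
        with pytest.raises(UndefinedICERError):
            cea_analysis(df, ["T"], ["C"], constant_table(10.0))

    def test_forced_mean_le_reproduces_published_qaly(self):
        """Arm mean LE 12.93 maps to LYG 6.59 and QALY 4.55 under (0.51, 0.69)."""
        df = patients_frame(
            [
                {"patient_id": "T", "pmx_day": 1.0, "cost_jpy_treatment": 130.0},
                {"patient_id": "C", "death_day": 5, "los_days": 5},
            ]
        )
        result = cea_analysis(df, ["T"], ["C"], constant_table(12.93))
        assert result.mean_lyg_treated == pytest.approx(6.59, abs=0.005)
        assert result.mean_qaly_treated == pytest.approx(4.55, abs=0.005)

    def test_empty_arm_rejected(self):
        df = patients_frame([{"patient_id": "T", "pmx_day": 1.0}])
        with pytest.raises(StratumError):
            cea_analysis(df, ["T"], [], constant_table(10.0))

    def test_mean_qaly_is_scaled_mean_le(self, fitted):
        b = fitted.base_case
        r, u = b.factors.reduction_rate, b.factors.utility_weight
        assert b.mean_qaly_treated == pytest.approx(r * u * b.mean_le_treated)
        assert b.mean_qaly_control == pytest.approx(r * u * b.mean_le_control)

    def test_synthetic_default_icer_positive_finite(self, fitted):
        assert np.isfinite(fitted.icer)
        assert fitted.icer > 0


class TestSensitivity:
    def test_deltas_constant_across_grid(self, fitted):
        frames = fitted.sensitivity
        assert len(frames) == 3
        for r in frames[1:]:
            assert r.delta_cost == pytest.approx(frames[0].delta_cost)
            assert r.delta_le == pytest.approx(frames[0].delta_le)

    def test_identity_factors_reduce_to_cost_per_life_year(self, big_cohort, life_table):
        treated = list(big_cohort["patient_id"][:50])
        controls = list(big_cohort["patient_id"][50:200])
        results = sensitivity_analysis(
            big_cohort, treated, controls, life_table,
            factor_grid=(AdjustmentFactors(1.0, 1.0),),
        )
        r = results[0]
        assert r.icer_eur_per_qaly == pytest.approx(r.delta_cost / r.delta_le)

    def test_icer_monotone_decreasing_in_ru(self):
        grid = [AdjustmentFactors(r, u) for r, u in ((0.3, 0.6), (0.51, 0.69), (0.7, 0.8), (1, 1))]
        values = [icer(6935, qaly_delta(1.70, f)) for f in grid]
        assert values == sorted(values, reverse=True)

    def test_empty_grid_rejected(self, big_cohort, life_table):
        with pytest.raises(ConfigurationError):
            sensitivity_analysis(
                big_cohort, ["P000000"], ["P000001"], life_table, factor_grid=()
            )


class TestSubgroups:
    def test_strata_partition_matched_cohort(self, fitted):
        sizes = [(r.n_treated, r.n_control) for r in fitted.subgroups]
        assert len(fitted.subgroups) == 4
        assert sum(t for t, _ in sizes) == len(fitted.matched.treated_ids)
        assert sum(c for _, c in sizes) == len(fitted.matched.control_ids)

    def test_pooled_cost_delta_is_weighted_combination(self, fitted):
        """Pooled arm means equal stratum means weighted by stratum sizes."""
        b = fitted.base_case
        for arm, total_n in (("treated", b.n_treated), ("control", b.n_control)):
            pooled = sum(
                getattr(r, f"mean_cost_{arm}") * getattr(r, f"n_{arm}")
                for r in fitted.subgroups
            ) / total_n
            assert pooled == pytest.approx(getattr(b, f"mean_cost_{arm}"), rel=1e-9)

    def test_empty_stratum_skipped_with_warning(self, life_table):
        df = patients_frame(
            [
                {"patient_id": "T", "pmx_day": 1.0, "sofa_baseline": 8,
                 "abdominal_infection": True, "cost_jpy_treatment": 130.0},
                {"patient_id": "C", "sofa_baseline": 8, "abdominal_infection": True, "age": 60},
            ]
        )
        with pytest.warns(UserWarning):
            results = subgroup_analysis(df, ["T"], ["C"], life_table)
        assert [r.stratum for r in results] == ["sofa_7-9_abdominal"]


class TestWTPDecision:
    def test_published_icer_is_acceptable(self):
        assert wtp_decision(11592) == "acceptable"

    def test_boundary(self):
        assert wtp_decision(38462) == "acceptable"
        assert wtp_decision(38463) == "not_acceptable"

    def test_dominance(self):
        assert wtp_decision(-1.0, delta_cost=-1.0, delta_qaly=1.0) == "dominant"
        assert wtp_decision(-1.0, delta_cost=1.0, delta_qaly=-1.0) == "dominated"
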