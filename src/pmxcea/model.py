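"""Model/Results interface tying the whole pipeline together.

``CostEffectivenessModel`` is built from a patient-level cohort table and
a life table; ``fit()`` runs eligibility selection, propensity estimation,
1:k caliper matching, outcome comparison, cost aggregation and the
QALY/ICER chain, and returns a ``CostEffectivenessResults`` carrying every
intermediate artifact plus a text ``summary()``.

Usage::

    from pmxcea import CostEffectivenessModel, default_config_from_table1
    from pmxcea.synthetic import generate_cohort
    from pmxcea.lifetable import make_fixture_life_table

    cohort = generate_cohort(default_config_from_table1(n_patients=20000, seed=1))
    model = CostEffectivenessModel(cohort, make_fixture_life_table())
    results = model.fit(seed=1)
    print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import economics, matching, outcomes, selection
from .economics import (
    DEFAULT_FACTOR_GRID,
    DEFAULT_JPY_PER_EUR,
    DEFAULT_WTP_EUR_PER_QALY,
    AdjustmentFactors,
    CEAResult,
    CostBreakdown,
)
from .exceptions import ConfigurationError
from .lifetable import LifeTable, load_life_table

__all__ = ["CostEffectivenessModel", "CostEffectivenessResults"]


class CostEffectivenessModel:
    """Matched cost-effectiveness analysis of a binary in-hospital treatment.

    Parameters
    ----------
    data : pandas.DataFrame
        Patient-level cohort table (see :mod:`pmxcea.synthetic` for the
        column contract).
    life_table : LifeTable
        Residual life expectancy by age for valuing survival.
    k : int
        Controls matched per treated patient (default 3).
    caliper_sd_multiplier : float
        Caliper as a multiple of the propensity-score SD (default 0.2).
    scale : str
        ``probability`` (default) or ``logit`` caliper scale.
    factors : AdjustmentFactors
        Base-case reduction rate and utility weight.
    factor_grid : sequence of AdjustmentFactors
        Settings for the sensitivity analysis (base case first).
    sex_mode : str
        ``total`` (default) or ``by_sex`` life-table lookup.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        life_table: LifeTable,
        covariates=matching.PS_COVARIATES,
        k: int = 3,
        caliper_sd_multiplier: float = 0.2,
        scale: str = "probability",
        factors: AdjustmentFactors = AdjustmentFactors(),
        factor_grid=DEFAULT_FACTOR_GRID,
        jpy_per_eur: float = DEFAULT_JPY_PER_EUR,
        wtp_eur_per_qaly: float = DEFAULT_WTP_EUR_PER_QALY,
        sex_mode: str = "total",
        sofa_min: int = 7,
        sofa_max: int = 12,
        max_los: int = 125,
    ) -> None:
        if sex_mode not in ("total", "by_sex"):
            raise ConfigurationError(f"unknown sex_mode {sex_mode!r}")
        self.data = data
        self.life_table = life_table
        self.covariates = tuple(covariates)
        self.k = k
        self.caliper_sd_multiplier = caliper_sd_multiplier
        self.scale = scale
        self.factors = factors
        self.factor_grid = tuple(factor_grid)
        self.jpy_per_eur = jpy_per_eur
        self.wtp_eur_per_qaly = wtp_eur_per_qaly
        self.sex_mode = sex_mode
        self.sofa_min = sofa_min
        self.sofa_max = sofa_max
        self.max_los = max_los

    @classmethod
    def from_csv(cls, cohort_path, life_table_path, **kwargs) -> "CostEffectivenessModel":
        from .synthetic import read_cohort_csv

        return cls(read_cohort_csv(cohort_path), load_life_table(life_table_path), **kwargs)

    def fit(self, seed: int = 0) -> "CostEffectivenessResults":
        """Run the full pipeline; ``seed`` fixes the matching order."""
        eligible, report = selection.select_cohort(
            self.data, self.sofa_min, self.sofa_max, self.max_los
        )
        labeled = selection.assign_groups(eligible)
        ps_model = matching.fit_propensity(labeled, self.covariates)
        ps = ps_model.predict(labeled)
        treated = labeled.loc[labeled["group"] == "pmx", "patient_id"]
        controls = labeled.loc[labeled["group"] == "control", "patient_id"]
        matched = matching.match_1_to_k(
            ps, treated, controls,
            k=self.k, caliper_sd_multiplier=self.caliper_sd_multiplier,
            scale=self.scale, seed=seed,
        )
        balance = matching.balance_report(labeled, matched, self.covariates)
        outcome_tbl = outcomes.outcome_table(labeled, matched.treated_ids, matched.control_ids)
        costs = economics.cost_breakdown(
            labeled, matched.treated_ids, matched.control_ids, rate=self.jpy_per_eur
        )
        sensitivity = economics.sensitivity_analysis(
            labeled, matched.treated_ids, matched.control_ids, self.life_table,
            (self.factors,) + tuple(f for f in self.factor_grid if f != self.factors),
            rate=self.jpy_per_eur, sex_mode=self.sex_mode,
        )
        base = sensitivity[0]
        subgroups = economics.subgroup_analysis(
            labeled, matched.treated_ids, matched.control_ids, self.life_table,
            self.factors, rate=self.jpy_per_eur, sex_mode=self.sex_mode,
        )
        decision = economics.wtp_decision(
            base.icer_eur_per_qaly, self.wtp_eur_per_qaly,
            delta_cost=base.delta_cost, delta_qaly=base.delta_qaly,
        )
        return CostEffectivenessResults(
            model=self,
            seed=seed,
            selection_report=report,
            propensity_model=ps_model,
            matched=matched,
            balance=balance,
            outcomes=outcome_tbl,
            costs=costs,
            base_case=base,
            sensitivity=list(sensitivity),
            subgroups=list(subgroups),
            wtp_decision=decision,
        )


@dataclass
class CostEffectivenessResults:
    """Everything the fitted pipeline produced."""

    model: CostEffectivenessModel
    seed: int
    selection_report: selection.SelectionReport
    propensity_model: matching.PropensityModel
    matched: matching.MatchedCohort
    balance: matching.BalanceReport
    outcomes: outcomes.OutcomeTable
    costs: CostBreakdown
    base_case: CEAResult
    sensitivity: list = field(default_factory=list)
    subgroups: list = field(default_factory=list)
    wtp_decision: str = ""

    @property
    def icer(self) -> float:
        return self.base_case.icer_eur_per_qaly

    def sensitivity_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.sensitivity])

    def subgroup_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.subgroups])

    def summary(self) -> str:
        b = self.base_case
        rep = self.selection_report
        lines = [
            "Matched cost-effectiveness analysis",
            "=" * 60,
            f"input admissions:        {rep.n_input}",
            f"eligible after filters:  {rep.n_final} "
            f"(treated {rep.n_pmx_group}, control {rep.n_control_group})",
            f"matched 1:{self.matched.k}:             "
            f"{len(self.matched.treated_ids)} treated, {len(self.matched.control_ids)} controls "
            f"(caliper {self.matched.caliper_width:.4f} on the {self.model.scale} scale)",
            f"covariate balance:       max ASD after matching "
            f"{self.balance.table['asd_after'].max():.1f}% "
            f"({'all' if self.balance.all_balanced else 'NOT all'} below "
            f"{self.balance.threshold:.0f}%)",
            "-" * 60,
            f"mean cost (EUR):         treated {b.mean_cost_treated:,.0f}  "
            f"control {b.mean_cost_control:,.0f}  difference {b.delta_cost:,.0f}",
            f"mean life expectancy:    treated {b.mean_le_treated:.2f} y  "
            f"control {b.mean_le_control:.2f} y  difference {b.delta_le:.2f} y",
            f"mean QALY (r={b.factors.reduction_rate}, u={b.factors.utility_weight}): "
            f"treated {b.mean_qaly_treated:.2f} y  control {b.mean_qaly_control:.2f} y  "
            f"difference {b.delta_qaly:.2f} y",
            f"ICER:                    {b.icer_eur_per_qaly:,.0f} EUR/QALY-year",
            f"WTP threshold:           {self.model.wtp_eur_per_qaly:,.0f} EUR/QALY "
            f"-> {self.wtp_decision}",
            "-" * 60,
            "sensitivity (r, u -> ICER EUR/year): "
            + "; ".join(
                f"({r.factors.reduction_rate}, {r.factors.utility_weight}) -> "
                f"{r.icer_eur_per_qaly:,.0f}"
                for r in self.sensitivity
            ),
            "subgroups: "
            + "; ".join(
                f"{r.stratum} -> {r.icer_eur_per_qaly:,.0f}" for r in self.subgroups
            ),
        ]
        return "\n".join(lines)
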