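"""Cost aggregation and cost-effectiveness (QALY / ICER) computations.

The economic model values the survival benefit of treatment through a
three-step per-patient chain:

* ``LE``  — residual life expectancy after discharge, looked up in a life
  table at the patient's age; patients who died in hospital have no life
  after discharge and contribute ``LE = 0``;
* ``LYG = LE * r`` — life-years gained, where the reduction rate ``r``
  (default 0.51) discounts survivors' residual life for the excess
  mortality observed after sepsis;
* ``QALY = LYG * u`` — quality-adjusted life-years, where the utility
  weight ``u`` (default 0.69) discounts for reduced post-sepsis quality of
  life.

The incremental cost-effectiveness ratio is then

    ICER = (mean cost, treated - mean cost, control)
           / (mean QALY, treated - mean QALY, control)

with costs converted from JPY at a fixed rate (default 130 JPY per Euro)
and no discounting of future life years or costs. An ICER below the
willingness-to-pay threshold (default 38,462 Euro/QALY, i.e. 5 million
JPY/QALY) is deemed acceptable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, StratumError, UndefinedICERError
from .lifetable import LifeTable

__all__ = [
    "COST_CATEGORIES",
    "AdjustmentFactors",
    "CEAResult",
    "CostBreakdown",
    "convert_jpy_to_eur",
    "cost_breakdown",
    "patient_qaly",
    "qaly_delta",
    "icer",
    "cea_analysis",
    "sensitivity_analysis",
    "subgroup_analysis",
    "wtp_decision",
    "DEFAULT_FACTOR_GRID",
    "DEFAULT_JPY_PER_EUR",
    "DEFAULT_WTP_EUR_PER_QALY",
]

#: The 11 itemized claims cost categories, in reporting order.
COST_CATEGORIES = (
    "hospital_visit_management",
    "prescription",
    "injection",
    "treatment",
    "surgery_anesthesia",
    "laboratory_test",
    "diagnostic_imaging",
    "rehabilitation",
    "general_hospitalization",
    "er_icu_hospitalization",
    "meals",
)

DEFAULT_JPY_PER_EUR = 130.0
#: 5 million JPY per QALY at 130 JPY/EUR, rounded to the integer Euro value
#: conventionally quoted for Japan.
DEFAULT_WTP_EUR_PER_QALY = 38462.0


@dataclass(frozen=True)
class AdjustmentFactors:
    """Reduction rate r (life-expectancy discount) and utility weight u."""

    reduction_rate: float = 0.51
    utility_weight: float = 0.69

    def __post_init__(self) -> None:
        if not (0 < self.reduction_rate <= 1):
            raise ConfigurationError(f"reduction_rate must be in (0,1], got {self.reduction_rate}")
        if not (0 < self.utility_weight <= 1):
            raise ConfigurationError(f"utility_weight must be in (0,1], got {self.utility_weight}")


#: Base case plus the two published sensitivity settings.
DEFAULT_FACTOR_GRID = (
    AdjustmentFactors(0.51, 0.69),
    AdjustmentFactors(0.3, 0.6),
    AdjustmentFactors(0.7, 0.8),
)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category and total costs by arm, in EUR."""

    table: pd.DataFrame  # index: category + "total"; columns: mean/sd per arm, difference
    n_treated: int
    n_control: int

    @property
    def total_difference_eur(self) -> float:
        return float(self.table.loc["total", "difference"])


@dataclass(frozen=True)
class CEAResult:
    """Cost-effectiveness summary for one stratum and one factor setting."""

    stratum: str
    factors: AdjustmentFactors
    n_treated: int
    n_control: int
    mean_cost_treated: float
    mean_cost_control: float
    mean_le_treated: float
    mean_le_control: float
    icer_eur_per_qaly: float
    dominance: str  # "", "dominant" (cheaper & better) or "dominated"

    @property
    def delta_cost(self) -> float:
        return self.mean_cost_treated - self.mean_cost_control

    @property
    def delta_le(self) -> float:
        return self.mean_le_treated - self.mean_le_control

    @property
    def mean_lyg_treated(self) -> float:
        return self.mean_le_treated * self.factors.reduction_rate

    @property
    def mean_lyg_control(self) -> float:
        return self.mean_le_control * self.factors.reduction_rate

    @property
    def mean_qaly_treated(self) -> float:
        return self.mean_lyg_treated * self.factors.utility_weight

    @property
    def mean_qaly_control(self) -> float:
        return self.mean_lyg_control * self.factors.utility_weight

    @property
    def delta_qaly(self) -> float:
        return self.mean_qaly_treated - self.mean_qaly_control

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "reduction_rate": self.factors.reduction_rate,
            "utility_weight": self.factors.utility_weight,
            "n_treated": self.n_treated,
            "n_control": self.n_control,
            "mean_cost_treated_eur": self.mean_cost_treated,
            "mean_cost_control_eur": self.mean_cost_control,
            "delta_cost_eur": self.delta_cost,
            "mean_le_treated_y": self.mean_le_treated,
            "mean_le_control_y": self.mean_le_control,
            "delta_le_y": self.delta_le,
            "delta_lyg_y": self.delta_le * self.factors.reduction_rate,
            "delta_qaly_y": self.delta_qaly,
            "icer_eur_per_qaly": self.icer_eur_per_qaly,
            "dominance": self.dominance,
        }


def convert_jpy_to_eur(amount_jpy: float, rate: float = DEFAULT_JPY_PER_EUR) -> float:
    """Convert a JPY amount to EUR at ``rate`` JPY per Euro."""
    if rate <= 0:
        raise ConfigurationError(f"conversion rate must be positive, got {rate}")
    return amount_jpy / rate


def _cost_columns(df: pd.DataFrame) -> list[str]:
    cols = [f"cost_jpy_{c}" for c in COST_CATEGORIES]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"missing cost columns: {missing}")
    return cols


def cost_breakdown(
    df: pd.DataFrame,
    treated_ids,
    control_ids,
    rate: float = DEFAULT_JPY_PER_EUR,
) -> CostBreakdown:
    """Per-arm mean and sample SD of each cost category and of the total.

    Amounts are converted JPY -> EUR before averaging; ``difference`` is the
    treated-arm mean minus the control-arm mean. The per-patient total is
    the sum of the 11 categories, so mean(total) == sum of category means.
    """
    cols = _cost_columns(df)
    sub = df.set_index("patient_id") if "patient_id" in df.columns else df
    rows = {}
    arms = {"treated": list(treated_ids), "control": list(control_ids)}
    for arm, ids in arms.items():
        eur = sub.loc[ids, cols].to_numpy(dtype=float) / rate
        total = eur.sum(axis=1)
        rows[arm] = {
            "mean": np.append(eur.mean(axis=0), total.mean()),
            "sd": np.append(eur.std(axis=0, ddof=1), total.std(ddof=1)),
        }
    index = list(COST_CATEGORIES) + ["total"]
    table = pd.DataFrame(
        {
            "mean_treated": rows["treated"]["mean"],
            "sd_treated": rows["treated"]["sd"],
            "mean_control": rows["control"]["mean"],
            "sd_control": rows["control"]["sd"],
        },
        index=index,
    )
    table["difference"] = table["mean_treated"] - table["mean_control"]
    return CostBreakdown(
        table=table, n_treated=len(arms["treated"]), n_control=len(arms["control"])
    )


def patient_qaly(
    age: float,
    died_in_hospital: bool,
    table: LifeTable,
    factors: AdjustmentFactors = AdjustmentFactors(),
    sex: str = "total",
) -> tuple[float, float, float]:
    """Per-patient (life expectancy, LYG, QALY) in years.

    In-hospital decedents contribute (0, 0, 0); survivors contribute the
    life-table residual expectancy at their age, multiplied down the
    LE -> LYG -> QALY chain.
    """
    if died_in_hospital:
        return (0.0, 0.0, 0.0)
    le = table.life_expectancy_at(age, sex)
    lyg = le * factors.reduction_rate
    return (le, lyg, lyg * factors.utility_weight)


def qaly_delta(delta_le: float, factors: AdjustmentFactors) -> float:
    """QALY difference implied by a life-expectancy difference.

    Valid because the LE -> LYG -> QALY chain is linear: the arm-mean QALY
    is r*u times the arm-mean LE, so differences scale the same way.
    """
    return delta_le * factors.reduction_rate * factors.utility_weight


def icer(delta_cost_eur: float, delta_qaly_years: float) -> float:
    """Incremental cost-effectiveness ratio in EUR per QALY-year.

    Sign is preserved: a negative ratio arises when one delta is negative
    (dominance situations); classification is left to :func:`wtp_decision`.
    """
    if delta_qaly_years == 0:
        if delta_cost_eur == 0:
            return 0.0
        raise UndefinedICERError("zero QALY difference with nonzero cost difference")
    return delta_cost_eur / delta_qaly_years


def _mean_le(df: pd.DataFrame, ids, table: LifeTable, sex_mode: str) -> float:
    sub = df.set_index("patient_id").loc[list(ids)]
    les = np.empty(len(sub))
    for i, (_, row) in enumerate(sub.iterrows()):
        died = pd.notna(row["death_day"])
        if died:
            les[i] = 0.0
        else:
            sex = row["sex"] if sex_mode == "by_sex" else "total"
            les[i] = table.life_expectancy_at(float(row["age"]), sex)
    return float(les.mean())


def cea_analysis(
    df: pd.DataFrame,
    treated_ids,
    control_ids,
    table: LifeTable,
    factors: AdjustmentFactors = AdjustmentFactors(),
    stratum: str = "all",
    rate: float = DEFAULT_JPY_PER_EUR,
    sex_mode: str = "total",
) -> CEAResult:
    """Full cost-effectiveness analysis for one stratum of a matched cohort."""
    treated_ids, control_ids = list(treated_ids), list(control_ids)
    if not treated_ids or not control_ids:
        raise StratumError(f"stratum {stratum!r} has an empty arm")
    costs = cost_breakdown(df, treated_ids, control_ids, rate=rate)
    mean_le_t = _mean_le(df, treated_ids, table, sex_mode)
    mean_le_c = _mean_le(df, control_ids, table, sex_mode)
    d_cost = costs.total_difference_eur
    d_qaly = qaly_delta(mean_le_t - mean_le_c, factors)
    ratio = icer(d_cost, d_qaly)
    dominance = ""
    if d_cost < 0 and d_qaly > 0:
        dominance = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        dominance = "dominated"
    return CEAResult(
        stratum=stratum,
        factors=factors,
        n_treated=len(treated_ids),
        n_control=len(control_ids),
        mean_cost_treated=float(costs.table.loc["total", "mean_treated"]),
        mean_cost_control=float(costs.table.loc["total", "mean_control"]),
        mean_le_treated=mean_le_t,
        mean_le_control=mean_le_c,
        icer_eur_per_qaly=ratio,
        dominance=dominance,
    )


def sensitivity_analysis(
    df: pd.DataFrame,
    treated_ids,
    control_ids,
    table: LifeTable,
    factor_grid=DEFAULT_FACTOR_GRID,
    rate: float = DEFAULT_JPY_PER_EUR,
    sex_mode: str = "total",
) -> list[CEAResult]:
    """Re-run the CEA over a grid of (reduction rate, utility weight) settings.

    Costs and life-expectancy deltas are identical across the grid — only
    the LYG/QALY scaling, and hence the ICER, changes.
    """
    if not factor_grid:
        raise ConfigurationError("factor grid must be nonempty")
    base = cea_analysis(df, treated_ids, control_ids, table, factor_grid[0], rate=rate, sex_mode=sex_mode)
    out = [base]
    for factors in factor_grid[1:]:
        d_qaly = qaly_delta(base.delta_le, factors)
        out.append(
            replace(
                base,
                factors=factors,
                icer_eur_per_qaly=icer(base.delta_cost, d_qaly),
            )
        )
    return out


SOFA_STRATA = ((7, 9), (10, 12))


def subgroup_analysis(
    df: pd.DataFrame,
    treated_ids,
    control_ids,
    table: LifeTable,
    factors: AdjustmentFactors = AdjustmentFactors(),
    rate: float = DEFAULT_JPY_PER_EUR,
    sex_mode: str = "total",
) -> list[CEAResult]:
    """CEA within the matched cohort, stratified by baseline severity and site.

    Four strata: SOFA 7-9 vs 10-12, crossed with abdominal vs other
    infection site. Strata are defined by the patient's own covariates, so
    matched sets may straddle strata; the analysis compares the treated and
    control members that fall inside each stratum. An empty stratum arm is
    skipped with a warning rather than raising.
    """
    sub = df.set_index("patient_id")
    results = []
    for lo, hi in SOFA_STRATA:
        for abdominal in (True, False):
            label = f"sofa_{lo}-{hi}_{'abdominal' if abdominal else 'other'}"
            mask = (
                sub["sofa_baseline"].between(lo, hi)
                & (sub["abdominal_infection"] == abdominal)
            )
            ids = set(sub.index[mask])
            t = [i for i in treated_ids if i in ids]
            c = [i for i in control_ids if i in ids]
            if not t or not c:
                warnings.warn(f"stratum {label} has an empty arm; skipped")
                continue
            results.append(
                cea_analysis(df, t, c, table, factors, stratum=label, rate=rate, sex_mode=sex_mode)
            )
    return results


def wtp_decision(
    icer_value: float,
    wtp_eur_per_qaly: float = DEFAULT_WTP_EUR_PER_QALY,
    delta_cost: float | None = None,
    delta_qaly: float | None = None,
) -> str:
    """Classify an ICER against a willingness-to-pay threshold.

    Returns one of ``acceptable`` (0 <= ICER <= WTP), ``not_acceptable``,
    ``dominant`` (cheaper and more effective) or ``dominated`` (costlier and
    less effective). The dominance categories require the signed deltas.
    """
    if delta_cost is not None and delta_qaly is not None:
        if delta_cost < 0 and delta_qaly > 0:
            return "dominant"
        if delta_cost > 0 and delta_qaly < 0:
            return "dominated"
    return "acceptable" if 0 <= icer_value <= wtp_eur_per_qaly else "not_acceptable"
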