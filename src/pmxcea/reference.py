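"""Published summary inputs for the matched PMX cost-effectiveness study.

The original analysis ran on the access-restricted Japanese DPC inpatient
claims database, so its patient-level results cannot be regenerated here.
What can be regenerated exactly is the cost-effectiveness arithmetic: every
published ICER is a deterministic function of the published between-arm cost
difference, life-expectancy difference and the adjustment factors. This
module stores those published summary inputs (and the ICERs printed next to
them) so the pipeline's economic chain can be checked against them.

All monetary values are EUR (converted at 130 JPY/EUR in the source
analysis); life-expectancy differences are years.
"""

from __future__ import annotations

import pandas as pd

from .economics import AdjustmentFactors, icer, qaly_delta

__all__ = [
    "BASE_CASE",
    "SENSITIVITY_CASES",
    "SUBGROUP_CASES",
    "ARM_LIFE_EXPECTANCY",
    "WTP_JPY_PER_QALY",
    "JPY_PER_EUR",
    "verify_reference_arithmetic",
]

JPY_PER_EUR = 130.0
WTP_JPY_PER_QALY = 5_000_000.0

#: label -> (delta_cost EUR, delta_LE years, r, u, published ICER EUR/year)
BASE_CASE = ("base_case", 6935.0, 1.70, 0.51, 0.69, 11_592)

SENSITIVITY_CASES = (
    ("sensitivity_r0.3_u0.6", 6935.0, 1.70, 0.30, 0.60, 22_663),
    ("sensitivity_r0.7_u0.8", 6935.0, 1.70, 0.70, 0.80, 7_285),
)

SUBGROUP_CASES = (
    ("sofa_7-9_abdominal", 5952.0, 3.40, 0.51, 0.69, 4_974),
    ("sofa_7-9_other", 7001.0, 1.50, 0.51, 0.69, 13_263),
    ("sofa_10-12_abdominal", 3840.0, 2.66, 0.51, 0.69, 4_102),
    ("sofa_10-12_other", 6911.0, 1.58, 0.51, 0.69, 12_429),
)

#: treated / control arm mean residual life expectancy (years) in the
#: published matched cohort; used to check the LE -> LYG -> QALY scaling.
ARM_LIFE_EXPECTANCY = {"treated": 12.93, "control": 11.23}


def all_cases() -> tuple:
    return (BASE_CASE,) + SENSITIVITY_CASES + SUBGROUP_CASES


def verify_reference_arithmetic(tolerance_eur: float = 1.0) -> pd.DataFrame:
    """Recompute every published ICER from its published inputs.

    For each case the published cost difference is divided by the QALY
    difference implied by the published life-expectancy difference and the
    case's adjustment factors. A row passes when the recomputed ratio is
    within ``tolerance_eur`` of the published integer (the published inputs
    are themselves rounded, so exact agreement is not expected).
    """
    rows = []
    for label, d_cost, d_le, r, u, published in all_cases():
        factors = AdjustmentFactors(r, u)
        recomputed = icer(d_cost, qaly_delta(d_le, factors))
        rows.append(
            {
                "case": label,
                "delta_cost_eur": d_cost,
                "delta_le_y": d_le,
                "reduction_rate": r,
                "utility_weight": u,
                "recomputed_icer": recomputed,
                "published_icer": published,
                "abs_error": abs(recomputed - published),
                "passed": abs(recomputed - published) <= tolerance_eur,
            }
        )
    return pd.DataFrame(rows)
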