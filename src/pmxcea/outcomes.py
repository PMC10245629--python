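"""Clinical outcomes on the matched cohort.

Outcomes compared between arms: 28-day mortality, in-hospital mortality,
length of hospital stay, and ventilator-, vasopressor- and CRRT-free days
at day 28. Free days count days alive and free of the given organ support
through day 28; a patient who died before day 28 scores zero on all three
(death trumps liberation), and days after a live discharge count as free.

Mortality contrasts use the Pearson chi-square test (no continuity
correction); stay lengths and free days use the Wilcoxon rank-sum test,
with an exact permutation p-value for small samples and a tie-corrected
normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

__all__ = [
    "SUPPORT_TYPES",
    "OutcomeTable",
    "mortality_28d",
    "hospital_mortality",
    "free_days_at_28",
    "chi_square_pearson",
    "wilcoxon_rank_sum",
    "outcome_table",
]

SUPPORT_TYPES = ("ventilator", "vasopressor", "crrt")

_SUPPORT_COLUMNS = {
    "ventilator": "ventilator_days",
    "vasopressor": "vasopressor_days",
    "crrt": "crrt_days",
}


def mortality_28d(death_day) -> bool:
    """Death on or before day 28 from sepsis diagnosis."""
    return death_day is not None and not pd.isna(death_day) and death_day <= 28


def hospital_mortality(death_day) -> bool:
    """Any in-hospital death."""
    return death_day is not None and not pd.isna(death_day)


def free_days_at_28(
    support_days,
    death_day=None,
    death_on_day_28_zeroes: bool = False,
) -> int:
    """Days in [1, 28] alive and free of one organ support.

    A death strictly before day 28 scores 0. A death exactly on day 28 is
    counted as a 28-day death by :func:`mortality_28d` yet still accrues
    free days here under the default convention ("died before day 28"
    read literally); set ``death_on_day_28_zeroes`` to zero it as well.
    """
    died = death_day is not None and not pd.isna(death_day)
    if died and (death_day < 28 or (death_on_day_28_zeroes and death_day <= 28)):
        return 0
    support = set(support_days) if support_days else set()
    return sum(1 for d in range(1, 29) if d not in support)


def chi_square_pearson(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], 1 df.

    No continuity correction; returns (statistic, upper-tail p). A zero
    row or column margin leaves independence undefined and raises.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise DataError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("chi-square undefined with a zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration, midranks for ties.

    Enumerates every assignment of the pooled midranks to the x positions
    and measures how extreme the observed rank sum is relative to its mean
    under the null. Feasible only for small samples.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9  # tolerate float noise in midrank sums
    count = sum(
        1
        for subset in combinations(range(n), nx)
        if abs(ranks[list(subset)].sum() - mu) >= dev
    )
    return count / comb(n, nx)


def wilcoxon_rank_sum(
    x,
    y,
    exact_threshold: int = 20,
    enumeration_limit: int = 400_000,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic for x, p). Samples with at most ``exact_threshold``
    observations per arm get an exact p — via the exact permutation
    distribution when there are no ties, or full enumeration over midrank
    assignments when there are ties and the number of assignments is below
    ``enumeration_limit``. Larger samples use the normal approximation with
    the tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both samples must be nonempty")
    small = len(x) <= exact_threshold and len(y) <= exact_threshold
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if small and comb(len(x) + len(y), len(x)) <= enumeration_limit:
        u = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
        return float(u), _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class OutcomeTable:
    """Between-arm comparison of the matched-cohort clinical outcomes."""

    table: pd.DataFrame
    n_treated: int
    n_control: int


def outcome_table(
    df: pd.DataFrame,
    treated_ids,
    control_ids,
    death_on_day_28_zeroes: bool = False,
) -> OutcomeTable:
    """Assemble the clinical-outcome comparison for a matched cohort.

    One row per outcome: mortality rows carry counts, percentages and the
    Pearson chi-square p; stay and free-day rows carry median (IQR, linear
    interpolation between order statistics) and the rank-sum p.
    """
    sub = df.set_index("patient_id") if "patient_id" in df.columns else df
    arms = {"treated": sub.loc[list(treated_ids)], "control": sub.loc[list(control_ids)]}
    n = {arm: len(frame) for arm, frame in arms.items()}
    rows = []

    for label, fn in (("28-day mortality", mortality_28d), ("hospital mortality", hospital_mortality)):
        deaths = {arm: int(frame["death_day"].map(fn).sum()) for arm, frame in arms.items()}
        try:
            _, p = chi_square_pearson(
                deaths["treated"], n["treated"] - deaths["treated"],
                deaths["control"], n["control"] - deaths["control"],
            )
        except DataError:  # degenerate table (e.g. no deaths at all)
            p = float("nan")
        rows.append({
            "outcome": label,
            "treated": f"{deaths['treated']} ({100 * deaths['treated'] / n['treated']:.1f})",
            "control": f"{deaths['control']} ({100 * deaths['control'] / n['control']:.1f})",
            "treated_value": deaths["treated"] / n["treated"],
            "control_value": deaths["control"] / n["control"],
            "p_value": p,
        })

    def continuous_row(label: str, series_by_arm: dict) -> dict:
        _, p = wilcoxon_rank_sum(series_by_arm["treated"], series_by_arm["control"])
        cells = {}
        for arm, vals in series_by_arm.items():
            med, q1, q3 = _median_iqr(np.asarray(vals, dtype=float))
            cells[arm] = f"{med:g} ({q1:g}-{q3:g})"
            cells[f"{arm}_value"] = med
        return {"outcome": label, **{k: cells[k] for k in ("treated", "control", "treated_value", "control_value")}, "p_value": p}

    rows.append(continuous_row(
        "length of stay (days)",
        {arm: frame["los_days"].to_numpy(float) for arm, frame in arms.items()},
    ))
    for support in SUPPORT_TYPES:
        col = _SUPPORT_COLUMNS[support]
        rows.append(continuous_row(
            f"{support}-free days",
            {
                arm: np.array([
                    free_days_at_28(days, dd, death_on_day_28_zeroes)
                    for days, dd in zip(frame[col], frame["death_day"])
                ])
                for arm, frame in arms.items()
            },
        ))
    return OutcomeTable(
        table=pd.DataFrame(rows).set_index("outcome"),
        n_treated=n["treated"],
        n_control=n["control"],
    )
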