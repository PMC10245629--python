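"""Eligibility filters and treatment-group assignment.

The study population is adult sepsis admissions with moderate organ
dysfunction (baseline SOFA 7-12, the range in which hemoperfusion showed
benefit in earlier work). Exclusions remove admissions where the treatment
comparison is not meaningful: very early deaths (within 3 days of
diagnosis), extreme stays (> 125 days), unresolved transfers within 28
days, and patients first treated with PMX later than day 2 (who belong to
neither arm under an intention-to-treat-on-day-1/2 definition).

All filters are pure row predicates, so the surviving set is independent of
filter order; only the per-filter attrition counts depend on it. The
reported order follows the study's patient-flow diagram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SelectionReport", "select_cohort", "assign_groups"]


@dataclass
class SelectionReport:
    """Attrition counts along the eligibility filter chain."""

    n_input: int
    n_after_each_filter: dict[str, int] = field(default_factory=dict)
    n_pmx_group: int | None = None
    n_control_group: int | None = None

    @property
    def n_final(self) -> int:
        if self.n_after_each_filter:
            return list(self.n_after_each_filter.values())[-1]
        return self.n_input

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_after_each_filter": self.n_after_each_filter,
                "n_pmx_group": self.n_pmx_group,
                "n_control_group": self.n_control_group,
            },
            **kwargs,
        )


def select_cohort(
    df: pd.DataFrame,
    sofa_min: int = 7,
    sofa_max: int = 12,
    max_los: int = 125,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Apply the eligibility filters, returning the kept rows and a report.

    Filters, in reported order: adult (age >= 20); baseline SOFA present
    and within [sofa_min, sofa_max]; no death within 3 days of diagnosis;
    length of stay <= max_los; no transfer without recovery by day 28; no
    first PMX treatment after day 2.
    """
    report = SelectionReport(n_input=len(df))
    filters = [
        ("adult", df["age"] >= 20),
        ("sofa_in_range", df["sofa_baseline"].notna()
         & df["sofa_baseline"].between(sofa_min, sofa_max)),
        ("no_early_death", ~(df["death_day"].notna() & (df["death_day"] <= 3))),
        ("los_within_limit", df["los_days"] <= max_los),
        ("no_unrecovered_transfer", ~(df["transfer_without_recovery_day"].notna()
                                      & (df["transfer_without_recovery_day"] <= 28))),
        ("pmx_on_day_1_or_2", ~(df["pmx_day"].notna() & ~df["pmx_day"].isin([1, 2]))),
    ]
    keep = pd.Series(True, index=df.index)
    for name, predicate in filters:
        keep &= predicate.fillna(True) if predicate.isna().any() else predicate
        report.n_after_each_filter[name] = int(keep.sum())
    eligible = df.loc[keep].copy()
    n_pmx = int(eligible["pmx_day"].notna().sum())
    report.n_pmx_group = n_pmx
    report.n_control_group = len(eligible) - n_pmx
    return eligible, report


def assign_groups(eligible: pd.DataFrame) -> pd.DataFrame:
    """Label eligible rows as ``pmx`` (treated on day 1 or 2) or ``control``.

    Assumes :func:`select_cohort` already removed late-treated patients;
    any residual pmx_day outside {1, 2, missing} indicates an upstream bug.
    """
    pmx_day = eligible["pmx_day"]
    bad = pmx_day.notna() & ~pmx_day.isin([1, 2])
    if bad.any():
        raise AssertionError(
            f"unfiltered late PMX days remain: {sorted(pmx_day[bad].unique())}"
        )
    out = eligible.copy()
    out["group"] = pmx_day.notna().map({True: "pmx", False: "control"})
    return out
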