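"""Abridged life tables and residual life-expectancy lookup.

A life table maps exact age (and optionally sex) to the expected number of
remaining years of life at that age. The cost-effectiveness stage uses it to
value survival: each hospital survivor contributes the residual life
expectancy at their age, while in-hospital decedents contribute zero (that
rule lives in :mod:`pmxcea.economics`, not here).

Abridged tables (5-year age bands) are interpolated linearly to single years
of age; ages beyond the oldest tabulated age use the oldest age's value
(floor extrapolation), which can never go negative because tabulated values
are validated non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import LifeTableFormatError, LifeTableLookupError

__all__ = [
    "LifeTable",
    "load_life_table",
    "life_expectancy_at",
    "make_fixture_life_table",
]

_VALID_SEXES = {"male", "female", "total"}
_REQUIRED_COLUMNS = ("age", "sex", "life_expectancy")


@dataclass(frozen=True)
class LifeTable:
    """Residual life expectancy by age and sex stratum.

    Parameters
    ----------
    knots : dict
        Maps sex stratum ("male", "female", "total") to a pair of numpy
        arrays ``(ages, life_expectancies)`` with strictly increasing ages.
    """

    knots: dict = field(repr=False)

    def __post_init__(self) -> None:
        for sex, (ages, les) in self.knots.items():
            if sex not in _VALID_SEXES:
                raise LifeTableFormatError(f"unknown sex stratum {sex!r}")
            if len(ages) == 0:
                raise LifeTableFormatError(f"empty stratum {sex!r}")
            if np.any(np.diff(ages) <= 0):
                raise LifeTableFormatError(
                    f"ages not strictly increasing in stratum {sex!r}"
                )
            if np.any(np.asarray(les) < 0):
                raise LifeTableFormatError(
                    f"negative life expectancy in stratum {sex!r}"
                )

    @property
    def max_age(self) -> int:
        return int(max(ages[-1] for ages, _ in self.knots.values()))

    def strata(self) -> tuple[str, ...]:
        return tuple(self.knots)

    def life_expectancy_at(self, age: float, sex: str = "total") -> float:
        """Residual life expectancy in years at ``age`` for stratum ``sex``.

        Linear interpolation between tabulated ages; ages above the oldest
        tabulated age return the oldest age's value, ages below the youngest
        return the youngest's. A "total" query against a table stratified
        only by sex returns the unweighted male/female mean.
        """
        if age < 0:
            raise LifeTableLookupError(f"age must be non-negative, got {age}")
        if sex in self.knots:
            ages, les = self.knots[sex]
            return float(np.interp(age, ages, les))
        if sex == "total" and "male" in self.knots and "female" in self.knots:
            return 0.5 * (
                self.life_expectancy_at(age, "male")
                + self.life_expectancy_at(age, "female")
            )
        raise LifeTableLookupError(
            f"sex stratum {sex!r} not in table (has {sorted(self.knots)})"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age": int(a), "sex": sex, "life_expectancy": float(e)}
            for sex, (ages, les) in sorted(self.knots.items())
            for a, e in zip(ages, les)
        ]
        return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_life_table(path) -> LifeTable:
    """Read and validate a life table from delimited text.

    The file must be a UTF-8 CSV with header ``age,sex,life_expectancy``;
    ``sex`` is one of male/female/total. Duplicate (age, sex) pairs, missing
    columns and negative expectancies raise :class:`LifeTableFormatError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LifeTableFormatError(f"missing columns: {missing}")
    bad_sex = set(df["sex"].unique()) - _VALID_SEXES
    if bad_sex:
        raise LifeTableFormatError(f"unknown sex values: {sorted(bad_sex)}")
    if df.duplicated(subset=["age", "sex"]).any():
        dup = df[df.duplicated(subset=["age", "sex"], keep=False)]
        raise LifeTableFormatError(
            f"duplicate (age, sex) rows: {dup[['age', 'sex']].values.tolist()}"
        )
    if df["life_expectancy"].isna().any() or (df["life_expectancy"] < 0).any():
        raise LifeTableFormatError("life_expectancy must be present and >= 0")

    knots = {}
    for sex, grp in df.groupby("sex"):
        grp = grp.sort_values("age")
        knots[str(sex)] = (
            grp["age"].to_numpy(dtype=float),
            grp["life_expectancy"].to_numpy(dtype=float),
        )
    return LifeTable(knots=knots)


def life_expectancy_at(table: LifeTable, age: float, sex: str = "total") -> float:
    """Functional alias for :meth:`LifeTable.life_expectancy_at`."""
    return table.life_expectancy_at(age, sex)


def make_fixture_life_table(seed: int | None = None) -> LifeTable:
    """Deterministic synthetic life table for tests and demos.

    Shaped after a modern high-income-country period table: about 63
    remaining years at age 20, declining smoothly to roughly 1.5 years at
    age 110, with a female advantage of ~3 years at adult ages. This is a
    synthetic stand-in, not any official national table; it exists so the
    pipeline is runnable without external data. ``seed`` is accepted for
    interface symmetry and ignored — the fixture is a fixed curve.
    """
    ages = np.arange(20, 111, 5, dtype=float)
    frac = (ages - 20.0) / 92.0
    total = 63.0 * (1.0 - frac**1.15)
    total = np.maximum(total, 1.0)
    spread = 3.0 * (1.0 - frac)  # sex gap narrows at extreme ages
    female = total + 0.5 * spread
    male = np.maximum(total - 0.5 * spread, 0.5)
    return LifeTable(
        knots={
            "total": (ages.copy(), total),
            "male": (ages.copy(), male),
            "female": (ages.copy(), female),
        }
    )
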