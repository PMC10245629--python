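"""Propensity-score estimation, 1:k greedy caliper matching, and balance.

The propensity score — the probability of receiving PMX given baseline
covariates — is estimated by maximum-likelihood logistic regression on the
17 confounders recorded at baseline (demographics, admission context,
comorbidity, organ supports, adjunct drugs, transfusions, and the maximum
daily noradrenaline dose). Treated patients are then matched without
replacement to their k nearest controls on the score, subject to a caliper
of 0.2 standard deviations of the score; a treated patient who cannot fill
all k slots inside the caliper is dropped entirely (complete sets only).
Balance is assessed by the absolute standardized difference (ASD), with
values below 10% conventionally regarded as well balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConfigurationError, SeparationError

__all__ = [
    "PS_COVARIATES",
    "PropensityModel",
    "MatchedCohort",
    "BalanceReport",
    "fit_propensity",
    "match_1_to_k",
    "absolute_standardized_difference",
    "balance_report",
]

#: The 17 baseline confounders entering the propensity model, in order.
PS_COVARIATES = (
    "age",
    "male",
    "emergency_admission",
    "university_hospital",
    "er_icu_admission",
    "cci",
    "crrt",
    "hd",
    "mechanical_ventilation",
    "surgery",
    "gamma_globulin",
    "at3",
    "rtm",
    "steroid",
    "rbc_transfusion",
    "platelet_transfusion",
    "max_noradrenaline",
)

#: Covariates treated as binary (prevalence-based ASD); the rest are continuous.
BINARY_COVARIATES = frozenset(PS_COVARIATES) - {"age", "cci", "max_noradrenaline"}


def design_matrix(df: pd.DataFrame, covariate_list=PS_COVARIATES) -> pd.DataFrame:
    """Numeric design matrix; the ``sex`` category becomes a ``male`` indicator."""
    X = pd.DataFrame(index=df.index)
    for cov in covariate_list:
        if cov == "male":
            X[cov] = (df["sex"] == "male").astype(float)
        else:
            X[cov] = df[cov].astype(float)
    return X


@dataclass(frozen=True)
class PropensityModel:
    """Fitted logistic treatment model with per-covariate log-odds."""

    coefficients: dict[str, float]
    intercept: float
    covariate_list: tuple[str, ...]

    def predict(self, df: pd.DataFrame) -> pd.Series:
        """Propensity scores in (0,1), indexed by patient_id."""
        X = design_matrix(df, self.covariate_list)
        eta = self.intercept + X.to_numpy() @ np.array(
            [self.coefficients[c] for c in self.covariate_list]
        )
        ps = 1.0 / (1.0 + np.exp(-eta))
        index = df["patient_id"] if "patient_id" in df.columns else df.index
        return pd.Series(ps, index=index, name="ps")


def fit_propensity(
    df: pd.DataFrame,
    covariate_list=PS_COVARIATES,
    treatment_col: str = "group",
) -> PropensityModel:
    """ML logistic fit of the treatment indicator on the baseline covariates.

    The problem is convex, so the fit is deterministic given the data.
    Perfect separation (diverging coefficients) raises
    :class:`SeparationError`; the caller may drop or regularize covariates.
    """
    y = (df[treatment_col] == "pmx").astype(float) if df[treatment_col].dtype == object \
        else df[treatment_col].astype(float)
    if y.nunique() < 2:
        raise SeparationError("need at least one treated and one control patient")
    X = sm.add_constant(design_matrix(df, covariate_list), has_constant="add")
    with warnings.catch_warnings():
        warnings.filterwarnings("error", message=".*[Ss]eparation.*")
        try:
            model = sm.Logit(y.to_numpy(), X)
            try:
                res = model.fit(disp=0, maxiter=200)
            except np.linalg.LinAlgError:
                # singular Hessian (e.g. constant covariate columns): fall
                # back to a gradient method, which leaves those slopes at 0
                res = model.fit(disp=0, maxiter=500, method="bfgs")
        except Exception as exc:  # statsmodels raises/warns PerfectSeparation*
            if "eparation" in type(exc).__name__ or "eparation" in str(exc):
                raise SeparationError(
                    "perfect separation in propensity fit; consider dropping "
                    "or regularizing the offending covariate"
                ) from exc
            raise
    params = pd.Series(res.params, index=X.columns)
    if not np.all(np.isfinite(params)):
        raise SeparationError("non-finite propensity coefficients")
    return PropensityModel(
        coefficients={c: float(params[c]) for c in covariate_list},
        intercept=float(params["const"]),
        covariate_list=tuple(covariate_list),
    )


@dataclass(frozen=True)
class MatchedCohort:
    """Result of 1:k matching without replacement.

    ``match_map`` maps each matched treated id to its k controls ordered by
    proximity; invariants (complete sets, no control reuse, caliper
    respected) are checked at construction.
    """

    match_map: dict = field(repr=False)
    caliper_width: float
    k: int
    ps: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        seen: set = set()
        for t, controls in self.match_map.items():
            if len(controls) != self.k:
                raise AssertionError(f"treated {t!r} has {len(controls)} != k controls")
            for c in controls:
                if c in seen:
                    raise AssertionError(f"control {c!r} reused")
                seen.add(c)
                if abs(self.ps[t] - self.ps[c]) > self.caliper_width + 1e-12:
                    raise AssertionError(
                        f"pair ({t!r}, {c!r}) violates caliper "
                        f"{abs(self.ps[t] - self.ps[c]):.6f} > {self.caliper_width:.6f}"
                    )

    @property
    def treated_ids(self) -> list:
        return list(self.match_map)

    @property
    def control_ids(self) -> list:
        return [c for controls in self.match_map.values() for c in controls]

    @property
    def all_ids(self) -> list:
        return self.treated_ids + self.control_ids

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "treated_id": t,
                "control_id": c,
                "rank": r + 1,
                "ps_treated": float(self.ps[t]),
                "ps_control": float(self.ps[c]),
            }
            for t, controls in self.match_map.items()
            for r, c in enumerate(controls)
        ]
        return pd.DataFrame(
            rows, columns=["treated_id", "control_id", "rank", "ps_treated", "ps_control"]
        )


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def match_1_to_k(
    ps: pd.Series,
    treated_ids,
    control_ids,
    k: int = 3,
    caliper_sd_multiplier: float = 0.2,
    scale: str = "probability",
    seed: int = 0,
) -> MatchedCohort:
    """Greedy nearest-neighbor 1:k matching with a caliper, no replacement.

    The caliper is ``caliper_sd_multiplier`` times the sample SD of the
    score over the full pre-match sample (treated plus control), on the
    chosen scale (``probability`` as specified, or ``logit`` as commonly
    practiced). Treated patients are processed in a seeded random order;
    each takes its k nearest not-yet-used controls within the caliper,
    breaking distance ties by smaller id. A treated patient with fewer than
    k available in-caliper controls is dropped and reserves nothing.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if scale not in ("probability", "logit"):
        raise ConfigurationError(f"unknown scale {scale!r}")
    treated_ids = sorted(treated_ids)
    control_ids = sorted(control_ids)

    values = ps.astype(float)
    if scale == "logit":
        values = pd.Series(_logit(values.to_numpy()), index=values.index)
    pool = values.loc[treated_ids + control_ids]
    caliper = caliper_sd_multiplier * float(pool.std(ddof=1)) if len(pool) > 1 else 0.0

    if not treated_ids:
        return MatchedCohort(match_map={}, caliper_width=caliper, k=k, ps=values)

    order = np.random.default_rng(seed).permutation(len(treated_ids))

    # controls sorted by (score, id) so in-caliper windows are contiguous
    ctrl = sorted(control_ids, key=lambda i: (values[i], i))
    ctrl_scores = np.array([values[i] for i in ctrl])
    used = np.zeros(len(ctrl), dtype=bool)

    match_map: dict = {}
    for idx in order:
        t = treated_ids[idx]
        s = values[t]
        lo = np.searchsorted(ctrl_scores, s - caliper, side="left")
        hi = np.searchsorted(ctrl_scores, s + caliper, side="right")
        cand = [j for j in range(lo, hi) if not used[j]]
        # guard against float round-off at the window edge
        cand = [j for j in cand if abs(ctrl_scores[j] - s) <= caliper]
        if len(cand) < k:
            continue
        cand.sort(key=lambda j: (abs(ctrl_scores[j] - s), ctrl[j]))
        chosen = cand[:k]
        for j in chosen:
            used[j] = True
        match_map[t] = [ctrl[j] for j in chosen]

    return MatchedCohort(match_map=match_map, caliper_width=caliper, k=k, ps=values)


def absolute_standardized_difference(values_a, values_b, kind: str = "continuous") -> float:
    """ASD in percent between two samples of one covariate.

    Continuous: 100*|mean_a - mean_b| / sqrt((var_a + var_b)/2), sample
    variances. Binary: the analogous expression with p(1-p) variances.
    Both zero numerator and denominator -> 0; a zero denominator with a
    nonzero numerator returns +inf with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("ASD requires nonempty groups")
    if kind == "binary":
        pa, pb = a.mean(), b.mean()
        num = abs(pa - pb)
        denom = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
    elif kind == "continuous":
        num = abs(a.mean() - b.mean())
        denom = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    else:
        raise ConfigurationError(f"unknown kind {kind!r}")
    if denom == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero pooled variance with nonzero mean difference; ASD is infinite")
        return float("inf")
    return 100.0 * num / denom


@dataclass(frozen=True)
class BalanceReport:
    """Per-covariate ASD before and after matching."""

    table: pd.DataFrame  # index: covariate; columns: asd_before, asd_after
    threshold: float

    @property
    def all_balanced(self) -> bool:
        return bool((self.table["asd_after"] < self.threshold).all())


def balance_report(
    df: pd.DataFrame,
    matched: MatchedCohort,
    covariate_list=PS_COVARIATES,
    threshold: float = 10.0,
    treatment_col: str = "group",
) -> BalanceReport:
    """ASD for every covariate, before (all treated vs all controls) and
    after matching (matched treated vs matched controls)."""
    sub = df.set_index("patient_id") if "patient_id" in df.columns else df
    X = design_matrix(sub, covariate_list)
    is_treated = sub[treatment_col] == "pmx"
    rows = {}
    for cov in covariate_list:
        kind = "binary" if cov in BINARY_COVARIATES else "continuous"
        rows[cov] = {
            "asd_before": absolute_standardized_difference(
                X.loc[is_treated, cov], X.loc[~is_treated, cov], kind
            ),
            "asd_after": absolute_standardized_difference(
                X.loc[matched.treated_ids, cov], X.loc[matched.control_ids, cov], kind
            ),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return BalanceReport(table=table, threshold=threshold)
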