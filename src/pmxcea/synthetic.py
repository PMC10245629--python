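"""Synthetic administrative-claims cohort generator.

Emulates the structure of a nationwide inpatient claims extract of adult
sepsis admissions, so every downstream stage (selection, matching,
outcomes, economics) is testable without access to the real, restricted
database. The generator produces, per admission:

* baseline covariates with marginals calibrated to the published unmatched
  control arm (age 77.2 +/- 12.7, CRRT 10.8%, mechanical ventilation
  21.9%, maximum noradrenaline dose 7.4, ...), with a dependence chain
  severity (SOFA) -> noradrenaline dose, CRRT, ventilation so that
  covariates are correlated and matching is a nontrivial task;
* confounded treatment assignment: the probability of PMX treatment is a
  logistic function of the baseline covariates with positive weights on
  severity markers, so treated patients are systematically sicker
  (confounding by indication) and the crude mortality contrast is biased
  toward harm;
* outcomes: in-hospital death from a logistic model that includes a known
  true treatment effect, death day / length of stay from log-normal draws,
  organ-support day sets, and occasional unresolved transfers — including
  the pathological rows (very early deaths, stays beyond 125 days, late
  PMX starts) that the eligibility filters exist to remove;
* itemized costs: gamma draws per claims category calibrated to the
  published control-arm means and SDs, plus an additive device cost on the
  "treatment" category for treated patients.

All days are 1-based with day 1 = day of sepsis diagnosis (the first SOFA
record). Identical configs (including seed) yield identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .economics import COST_CATEGORIES
from .exceptions import ConfigurationError
from .matching import PS_COVARIATES

__all__ = [
    "GeneratorConfig",
    "default_config_from_table1",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "encode_day_set",
    "decode_day_set",
]

#: Fixed internal seed for intercept calibration; independent of the
#: config seed so that default configs are reproducible constants.
_CALIBRATION_SEED = 20180401
_CALIBRATION_N = 60_000

#: Anchor for the treated fraction: 1492 treated of 19,283 eligible.
TARGET_TREATED_FRACTION = 1492 / 19283

_PREVALENCE_KEYS = (
    "male_prevalence",
    "emergency_admission_prevalence",
    "university_hospital_prevalence",
    "er_icu_admission_prevalence",
    "crrt_prevalence",
    "hd_prevalence",
    "mechanical_ventilation_prevalence",
    "surgery_prevalence",
    "gamma_globulin_prevalence",
    "at3_prevalence",
    "rtm_prevalence",
    "steroid_prevalence",
    "rbc_transfusion_prevalence",
    "platelet_transfusion_prevalence",
    "abdominal_infection_prevalence",
)

#: Flags whose assignment probability rises with baseline severity.
_SOFA_DEPENDENT_FLAGS = ("crrt", "mechanical_ventilation")


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    ``treatment_assignment_coefficients`` and
    ``outcome_parameters['death_coefficients']`` are on the log-odds scale
    and include an ``intercept`` entry; use
    :func:`default_config_from_table1` to obtain calibrated intercepts.
    """

    n_patients: int
    seed: int
    covariate_distribution_parameters: dict = field(default_factory=dict)
    treatment_assignment_coefficients: dict = field(default_factory=dict)
    true_treatment_log_odds_on_death: float = np.log(0.625)
    outcome_parameters: dict = field(default_factory=dict)
    cost_model_parameters: dict = field(default_factory=dict)
    sofa_range: tuple = (2, 17)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        cov = self.covariate_distribution_parameters
        for key in _PREVALENCE_KEYS:
            p = cov.get(key)
            if p is not None and not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{key} must be in [0,1], got {p}")
        lo, hi = self.sofa_range
        if lo >= hi:
            raise ConfigurationError(f"invalid sofa_range {self.sofa_range}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sofa_range"] = list(self.sofa_range)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _default_covariate_params() -> dict:
    return {
        "age_mean": 77.2, "age_sd": 12.7, "age_min": 20, "age_max": 105,
        "male_prevalence": 0.55,
        "emergency_admission_prevalence": 0.967,
        "university_hospital_prevalence": 0.120,
        "er_icu_admission_prevalence": 0.463,
        "cci_mean": 1.9, "cci_sd": 1.7,
        "sofa_mean": 9.5, "sofa_sd": 2.5,
        "max_noradrenaline_mean": 7.4, "max_noradrenaline_sd": 9.9,
        "noradrenaline_sofa_slope": 0.10,  # log-scale shift per SOFA point
        "crrt_prevalence": 0.108,
        "hd_prevalence": 0.041,
        "mechanical_ventilation_prevalence": 0.219,
        "surgery_prevalence": 0.137,
        "gamma_globulin_prevalence": 0.074,
        "at3_prevalence": 0.047,
        "rtm_prevalence": 0.090,
        "steroid_prevalence": 0.259,
        "rbc_transfusion_prevalence": 0.121,
        "platelet_transfusion_prevalence": 0.047,
        "abdominal_infection_prevalence": 0.31,
        # log-odds per SOFA point for the severity-dependent flags
        "sofa_slopes": {"crrt": 0.35, "mechanical_ventilation": 0.30},
    }


def _default_assignment_coefficients() -> dict:
    """Directions mirror the published unmatched treated-arm shifts:
    treated patients are younger, less often male, more often in
    university hospitals and ER/ICU, and carry far more organ support,
    adjunct therapy and vasopressor load."""
    return {
        "age": -0.025,
        "male": -0.30,
        "emergency_admission": -1.10,
        "university_hospital": 0.70,
        "er_icu_admission": 1.10,
        "cci": 0.0,
        "crrt": 2.40,
        "hd": 0.10,
        "mechanical_ventilation": 1.40,
        "surgery": 1.90,
        "gamma_globulin": 1.40,
        "at3": 1.30,
        "rtm": 1.80,
        "steroid": 0.70,
        "rbc_transfusion": 1.10,
        "platelet_transfusion": 0.80,
        "max_noradrenaline": 0.035,
        "intercept": None,  # calibrated
    }


def _default_outcome_params() -> dict:
    return {
        "death_coefficients": {
            "sofa": 0.22,          # per point above the SOFA mean
            "age": 0.020,          # per year above the age mean
            "crrt": 0.40,
            "mechanical_ventilation": 0.50,
            "max_noradrenaline": 0.020,
            "intercept": None,     # calibrated
        },
        "target_baseline_mortality": 0.32,
        "death_day_log_mean": float(np.log(12.0)),
        "death_day_log_sd": 0.85,
        "survivor_los_log_mean": float(np.log(24.0)),
        "survivor_los_log_sd": 0.65,
        "treated_log_los_shift": 0.18,
        "transfer_probability": 0.04,
        "pmx_day_probabilities": {1: 0.62, 2: 0.28, 3: 0.06, 4: 0.04},
        "ventilator_mean_days": 9.0,
        "vasopressor_mean_days": 4.0,
        "crrt_mean_days": 6.0,
        "vasopressor_dose_threshold": 0.5,
    }


def _default_cost_params() -> dict:
    """Control-arm category means and SDs in EUR (claims-scale), and the
    additive treated-arm device cost on the 'treatment' category."""
    means_sds = {
        "hospital_visit_management": (126, 118),
        "prescription": (247, 614),
        "injection": (4827, 6552),
        "treatment": (3053, 4821),
        "surgery_anesthesia": (3724, 8208),
        "laboratory_test": (1004, 1482),
        "diagnostic_imaging": (663, 625),
        "rehabilitation": (57, 819),
        "general_hospitalization": (4013, 3560),
        "er_icu_hospitalization": (5947, 4726),
        "meals": (341, 362),
    }
    return {
        "categories": {
            cat: {"mean_eur": float(m), "sd_eur": float(s)}
            for cat, (m, s) in means_sds.items()
        },
        "treated_device_cost_eur": 4461.0,
        "jpy_per_eur": 130.0,
    }


def _sofa_pmf(sofa_range: tuple, mean: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
    grid = np.arange(sofa_range[0], sofa_range[1] + 1)
    w = norm.pdf((grid - mean) / sd)
    return grid, w / w.sum()


def _solve_flag_intercept(target: float, slope: float, grid: np.ndarray,
                          pmf: np.ndarray, mean: float) -> float:
    """Intercept making the SOFA-marginalized prevalence hit ``target`` exactly."""
    if target in (0.0, 1.0):
        return np.inf if target == 1.0 else -np.inf
    f = lambda a: float(np.sum(pmf * expit(a + slope * (grid - mean)))) - target
    return brentq(f, -30.0, 30.0)


def _draw_covariates(cov: dict, sofa_range: tuple, n: int, rng: np.random.Generator) -> pd.DataFrame:
    grid, pmf = _sofa_pmf(sofa_range, cov["sofa_mean"], cov["sofa_sd"])
    sofa = rng.choice(grid, size=n, p=pmf)

    df = pd.DataFrame({"sofa_baseline": sofa.astype(int)})
    age = rng.normal(cov["age_mean"], cov["age_sd"], size=n)
    df["age"] = np.clip(np.rint(age), cov["age_min"], cov["age_max"]).astype(int)
    df["sex"] = np.where(rng.random(n) < cov["male_prevalence"], "male", "female")
    for flag, key in (
        ("emergency_admission", "emergency_admission_prevalence"),
        ("university_hospital", "university_hospital_prevalence"),
        ("er_icu_admission", "er_icu_admission_prevalence"),
        ("hd", "hd_prevalence"),
        ("surgery", "surgery_prevalence"),
        ("gamma_globulin", "gamma_globulin_prevalence"),
        ("at3", "at3_prevalence"),
        ("rtm", "rtm_prevalence"),
        ("steroid", "steroid_prevalence"),
        ("rbc_transfusion", "rbc_transfusion_prevalence"),
        ("platelet_transfusion", "platelet_transfusion_prevalence"),
        ("abdominal_infection", "abdominal_infection_prevalence"),
    ):
        df[flag] = rng.random(n) < cov[key]

    # severity-dependent flags: intercept solved against the SOFA pmf so
    # the configured marginal prevalence is recovered exactly in expectation
    centered = sofa - cov["sofa_mean"]
    for flag in _SOFA_DEPENDENT_FLAGS:
        slope = cov["sofa_slopes"].get(flag, 0.0)
        a = _solve_flag_intercept(cov[f"{flag}_prevalence"], slope, grid, pmf, cov["sofa_mean"])
        df[flag] = rng.random(n) < expit(a + slope * centered)

    # CCI: negative binomial matching the configured mean and SD
    m, s = cov["cci_mean"], cov["cci_sd"]
    var = max(s**2, m + 1e-9)
    if var > m:
        r = m**2 / (var - m)
        df["cci"] = rng.negative_binomial(r, r / (r + m), size=n)
    else:
        df["cci"] = rng.poisson(m, size=n)

    # noradrenaline: gamma scaled up with severity, renormalized so the
    # configured marginal mean is exact in expectation
    nm, ns = cov["max_noradrenaline_mean"], cov["max_noradrenaline_sd"]
    shape = nm**2 / ns**2
    slope = cov["noradrenaline_sofa_slope"]
    mult = np.exp(slope * centered)
    norm_const = float(np.sum(pmf * np.exp(slope * (grid - cov["sofa_mean"]))))
    base_scale = (nm / shape) / norm_const
    df["max_noradrenaline"] = rng.gamma(shape, base_scale, size=n) * mult
    return df


def _linear_predictor(df: pd.DataFrame, coefficients: dict) -> np.ndarray:
    eta = np.zeros(len(df))
    for name, beta in coefficients.items():
        if name == "intercept" or beta == 0.0:
            continue
        x = (df["sex"] == "male").to_numpy(float) if name == "male" else df[name].to_numpy(float)
        eta += beta * x
    return eta


def _death_predictor(df: pd.DataFrame, cov: dict, coefs: dict) -> np.ndarray:
    eta = np.zeros(len(df))
    for name, beta in coefs.items():
        if name == "intercept" or beta is None or beta == 0.0:
            continue
        if name == "sofa":
            x = df["sofa_baseline"].to_numpy(float) - cov["sofa_mean"]
        elif name == "age":
            x = df["age"].to_numpy(float) - cov["age_mean"]
        else:
            x = df[name].to_numpy(float)
        eta += beta * x
    return eta


def default_config_from_table1(
    n_patients: int = 20_000,
    seed: int = 0,
    target_treated_fraction: float = TARGET_TREATED_FRACTION,
) -> GeneratorConfig:
    """Config calibrated to the published unmatched-cohort margins.

    Covariate targets equal the published control-arm values; assignment
    coefficients reproduce the published treated-arm shifts in direction.
    The assignment and death-model intercepts are solved on a fixed
    internal covariate sample so the treated fraction (~7.7%) and the
    untreated mortality level are hit in expectation.
    """
    cov = _default_covariate_params()
    assign = _default_assignment_coefficients()
    outcome = _default_outcome_params()
    config = GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        covariate_distribution_parameters=cov,
        treatment_assignment_coefficients=assign,
        outcome_parameters=outcome,
        cost_model_parameters=_default_cost_params(),
    )
    rng = np.random.default_rng(_CALIBRATION_SEED)
    sample = _draw_covariates(cov, config.sofa_range, _CALIBRATION_N, rng)

    eta_assign = _linear_predictor(sample, assign)
    assign["intercept"] = brentq(
        lambda a: float(expit(a + eta_assign).mean()) - target_treated_fraction, -30, 10
    )
    death_coefs = outcome["death_coefficients"]
    eta_death = _death_predictor(sample, cov, death_coefs)
    death_coefs["intercept"] = brentq(
        lambda a: float(expit(a + eta_death).mean()) - outcome["target_baseline_mortality"],
        -30, 10,
    )
    return config


def _support_day_sets(flags: np.ndarray, start: np.ndarray, duration: np.ndarray,
                      los: np.ndarray) -> list[frozenset]:
    out = []
    for f, s, d, l in zip(flags, start, duration, los):
        if not f or d <= 0:
            out.append(frozenset())
        else:
            end = min(int(s) + int(d) - 1, int(l))
            out.append(frozenset(range(int(s), end + 1)) if end >= s else frozenset())
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a full synthetic cohort table from ``config``.

    Returns one row per admission with all covariates, treatment timing,
    outcomes, support-day sets (``frozenset`` columns) and the 11 itemized
    cost columns (``cost_jpy_*``). Deterministic given the config.
    """
    cov = {**_default_covariate_params(), **config.covariate_distribution_parameters}
    assign = {**_default_assignment_coefficients(), **config.treatment_assignment_coefficients}
    outcome = {**_default_outcome_params(), **config.outcome_parameters}
    cost = config.cost_model_parameters or _default_cost_params()
    if assign.get("intercept") is None:
        raise ConfigurationError(
            "assignment intercept not set; build configs via default_config_from_table1 "
            "or set treatment_assignment_coefficients['intercept']"
        )
    n = config.n_patients
    rng = np.random.default_rng(config.seed)

    df = _draw_covariates(cov, config.sofa_range, n, rng)
    df.insert(0, "patient_id", [f"P{i:06d}" for i in range(n)])

    # --- confounded treatment assignment -------------------------------
    p_treat = expit(assign["intercept"] + _linear_predictor(df, assign))
    treated = rng.random(n) < p_treat
    day_probs = outcome["pmx_day_probabilities"]
    days = np.array(sorted(day_probs), dtype=float)
    probs = np.array([day_probs[int(d)] for d in days])
    pmx_day = np.full(n, np.nan)
    pmx_day[treated] = rng.choice(days, size=int(treated.sum()), p=probs / probs.sum())
    df["pmx_day"] = pmx_day

    # --- death and length of stay --------------------------------------
    death_coefs = outcome["death_coefficients"]
    if death_coefs.get("intercept") is None:
        raise ConfigurationError("death-model intercept not set")
    eta = (
        death_coefs["intercept"]
        + _death_predictor(df, cov, death_coefs)
        + config.true_treatment_log_odds_on_death * treated
    )
    died = rng.random(n) < expit(eta)

    death_day = np.rint(
        np.exp(rng.normal(outcome["death_day_log_mean"], outcome["death_day_log_sd"], n))
    ).clip(1, 180)
    survivor_los = np.rint(
        np.exp(
            rng.normal(outcome["survivor_los_log_mean"], outcome["survivor_los_log_sd"], n)
            + outcome["treated_log_los_shift"] * treated
        )
    ).clip(2, 365)
    los = np.where(died, death_day, survivor_los).astype(int)
    df["death_day"] = np.where(died, death_day, np.nan)
    df["los_days"] = los

    # unresolved transfers among survivors only
    transfer = (~died) & (rng.random(n) < outcome["transfer_probability"]) & (los >= 6)
    upper = np.minimum(los, 60)
    t_day = 5 + np.floor(rng.random(n) * np.maximum(upper - 5, 1)).astype(int)
    df["transfer_without_recovery_day"] = np.where(transfer, t_day, np.nan)

    # --- organ-support day sets ----------------------------------------
    vent_dur = 1 + rng.poisson(outcome["ventilator_mean_days"], n)
    vaso_dur = 1 + rng.poisson(outcome["vasopressor_mean_days"], n)
    crrt_dur = 1 + rng.poisson(outcome["crrt_mean_days"], n)
    crrt_start = rng.integers(1, 3, n)  # CRRT begins day 1 or 2
    ones = np.ones(n, dtype=int)
    on_vaso = df["max_noradrenaline"].to_numpy() > outcome["vasopressor_dose_threshold"]
    df["ventilator_days"] = _support_day_sets(df["mechanical_ventilation"].to_numpy(), ones, vent_dur, los)
    df["vasopressor_days"] = _support_day_sets(on_vaso, ones, vaso_dur, los)
    df["crrt_days"] = _support_day_sets(df["crrt"].to_numpy(), crrt_start, crrt_dur, los)

    # --- itemized costs -------------------------------------------------
    jpy = cost["jpy_per_eur"]
    for cat in COST_CATEGORIES:
        params = cost["categories"][cat]
        m, s = params["mean_eur"], params["sd_eur"]
        shape = m**2 / s**2
        draws = rng.gamma(shape, s**2 / m, size=n)
        if cat == "treatment":
            draws = draws + cost["treated_device_cost_eur"] * treated
        df[f"cost_jpy_{cat}"] = draws * jpy

    return df


# ----------------------------------------------------------------------
# delimited-text round trip

def encode_day_set(days) -> str:
    """Run-length encode a day set: {1,2,3,7} -> '1-3,7'; empty -> ''."""
    days = sorted(days)
    if not days:
        return ""
    runs, start, prev = [], days[0], days[0]
    for d in days[1:]:
        if d == prev + 1:
            prev = d
        else:
            runs.append((start, prev))
            start = prev = d
    runs.append((start, prev))
    return ",".join(f"{a}-{b}" if b > a else f"{a}" for a, b in runs)


def decode_day_set(text) -> frozenset:
    """Inverse of :func:`encode_day_set`."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return frozenset()
    days: set[int] = set()
    for run in str(text).split(","):
        if "-" in run:
            a, b = run.split("-")
            days.update(range(int(a), int(b) + 1))
        else:
            days.add(int(run))
    return frozenset(days)


_DAY_SET_COLUMNS = ("ventilator_days", "vasopressor_days", "crrt_days")
_NULLABLE_INT_COLUMNS = ("pmx_day", "death_day", "transfer_without_recovery_day")


def write_cohort_csv(df: pd.DataFrame, path, config: GeneratorConfig | None = None) -> None:
    """Write a cohort table as CSV (day sets run-length encoded); when a
    config is given, a ``<path>.config.json`` sidecar records it."""
    out = df.copy()
    for col in _DAY_SET_COLUMNS:
        out[col] = out[col].map(encode_day_set)
    out.to_csv(path, index=False)
    if config is not None:
        with open(f"{path}.config.json", "w") as fh:
            fh.write(config.to_json(indent=2))


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    for col in _DAY_SET_COLUMNS:
        df[col] = df[col].map(decode_day_set)
    for col in _NULLABLE_INT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
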