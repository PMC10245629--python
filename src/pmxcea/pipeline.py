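"""End-to-end pipeline orchestration with file artifacts.

``run_pipeline`` executes the whole analysis from either a cohort CSV on
disk or generator settings, writes every stage artifact as CSV/JSON into an
output directory, and records a run manifest (config echo, seed, per-stage
counts, content hashes) so identical configs yield identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .economics import AdjustmentFactors, DEFAULT_JPY_PER_EUR, DEFAULT_WTP_EUR_PER_QALY
from .exceptions import ConfigurationError
from .lifetable import load_life_table, make_fixture_life_table
from .model import CostEffectivenessModel
from .reference import verify_reference_arithmetic
from .synthetic import default_config_from_table1, generate_cohort, read_cohort_csv

__all__ = ["PipelineConfig", "run_pipeline", "verify_reference_arithmetic"]


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run.

    Exactly one of ``cohort_csv`` (file mode) or ``generator`` (synthetic
    mode, a dict of ``default_config_from_table1`` keyword arguments) must
    be provided. ``life_table_csv`` may be omitted only in synthetic mode,
    in which case the built-in fixture table is used.
    """

    cohort_csv: str | None = None
    generator: dict | None = None
    life_table_csv: str | None = None
    seed: int = 0
    k: int = 3
    caliper_sd_multiplier: float = 0.2
    scale: str = "probability"
    reduction_rate: float = 0.51
    utility_weight: float = 0.69
    factor_grid: list = field(
        default_factory=lambda: [[0.51, 0.69], [0.3, 0.6], [0.7, 0.8]]
    )
    jpy_per_eur: float = DEFAULT_JPY_PER_EUR
    wtp_eur_per_qaly: float = DEFAULT_WTP_EUR_PER_QALY
    sex_mode: str = "total"
    output_dir: str = "pmxcea_output"

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.generator is None):
            raise ConfigurationError(
                "exactly one of cohort_csv / generator settings must be provided"
            )
        if self.cohort_csv is not None and self.life_table_csv is None:
            raise ConfigurationError("file mode requires a life_table_csv")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write artifacts; returns the manifest dict.

    Artifacts: selection_report.json, propensity_model.json,
    match_map.csv, balance.csv, outcomes.csv, costs.csv, cea_base.json,
    sensitivity.csv, subgroups.csv, summary.txt, manifest.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        gen_config = default_config_from_table1(
            seed=config.generator.get("seed", config.seed),
            **{k: v for k, v in config.generator.items() if k != "seed"},
        )
        cohort = generate_cohort(gen_config)
    else:
        cohort = read_cohort_csv(config.cohort_csv)

    life_table = (
        load_life_table(config.life_table_csv)
        if config.life_table_csv is not None
        else make_fixture_life_table()
    )

    model = CostEffectivenessModel(
        cohort,
        life_table,
        k=config.k,
        caliper_sd_multiplier=config.caliper_sd_multiplier,
        scale=config.scale,
        factors=AdjustmentFactors(config.reduction_rate, config.utility_weight),
        factor_grid=tuple(AdjustmentFactors(r, u) for r, u in config.factor_grid),
        jpy_per_eur=config.jpy_per_eur,
        wtp_eur_per_qaly=config.wtp_eur_per_qaly,
        sex_mode=config.sex_mode,
    )
    results = model.fit(seed=config.seed)

    (out / "selection_report.json").write_text(results.selection_report.to_json(indent=2))
    (out / "propensity_model.json").write_text(json.dumps(
        {
            "intercept": results.propensity_model.intercept,
            "coefficients": results.propensity_model.coefficients,
        },
        indent=2, sort_keys=True,
    ))
    results.matched.to_frame().to_csv(out / "match_map.csv", index=False)
    results.balance.table.to_csv(out / "balance.csv", index_label="covariate")
    results.outcomes.table.to_csv(out / "outcomes.csv")
    results.costs.table.to_csv(out / "costs.csv", index_label="category")
    (out / "cea_base.json").write_text(json.dumps(results.base_case.to_dict(), indent=2))
    results.sensitivity_frame().to_csv(out / "sensitivity.csv", index=False)
    results.subgroup_frame().to_csv(out / "subgroups.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")

    artifacts = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_counts": {
            "n_input": results.selection_report.n_input,
            "n_eligible": results.selection_report.n_final,
            "n_treated_eligible": results.selection_report.n_pmx_group,
            "n_control_eligible": results.selection_report.n_control_group,
            "n_treated_matched": len(results.matched.treated_ids),
            "n_control_matched": len(results.matched.control_ids),
            "n_subgroup_strata": len(results.subgroups),
        },
        "base_case": results.base_case.to_dict(),
        "wtp_decision": results.wtp_decision,
        "files": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
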