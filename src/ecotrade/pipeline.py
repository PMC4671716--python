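"""End-to-end orchestration: simulate or ingest, account, score, regress.

The pipeline chains every stage of the analysis: an MRIO system per year
(either generated synthetically or read from CSV), per-country SO2
footprints and value-added shares, trade-network integration scores, panel
assembly with the log-transform registry, descriptive statistics, and the
full roster of regression specifications.  The default roster mirrors the
classic design: pollution regressed on integration (with population and
urbanization controls), the pollution-wealth ratio NEM regressed on
integration, and infant/child mortality regressed on integration, NEM,
production SO2, fertility, health expenditure and urbanization -- each both
as Prais-Winsten/PCSE and as a listwise-deletion OLS robustness model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, GroundTruth, SyntheticConfig
from .mrio import available_years, footprint_series, read_mrio_csv, write_mrio_csv
from .network import integration_series
from .panel import (
    DEFAULT_LOG_VARS,
    ModelSpec,
    PanelDataset,
    PanelResults,
    descriptive_stats,
    fit,
)
from .simulate import generate_mrio_series, generate_panel

MORTALITY_CONTROLS = (
    "integration",
    "nem",
    "prod_so2",
    "fertility",
    "health_expenditure",
    "urbanization",
)

POLLUTION_CONTROLS = ("integration", "population", "urbanization")


def default_model_roster() -> dict[str, ModelSpec]:
    """Named specifications covering every model column of the study design."""
    pw = "prais_winsten_pcse"
    ols = "listwise_ols"
    return {
        "prod_so2_integration_fe": ModelSpec("prod_so2", ("integration",), ("year", "country"), pw),
        "prod_so2_controls": ModelSpec("prod_so2", POLLUTION_CONTROLS, ("year",), pw),
        "cons_so2_integration_fe": ModelSpec("cons_so2", ("integration",), ("year", "country"), pw),
        "cons_so2_controls": ModelSpec("cons_so2", POLLUTION_CONTROLS, ("year",), pw),
        "nem_integration_fe": ModelSpec("nem", ("integration",), ("year", "country"), pw),
        "nem_controls_fe": ModelSpec("nem", POLLUTION_CONTROLS, ("year", "country"), pw),
        "under5_integration_fe": ModelSpec("under5_mortality", ("integration",), ("year", "country"), pw),
        "under5_full_controls": ModelSpec("under5_mortality", MORTALITY_CONTROLS, ("year",), pw),
        "under1_integration_fe": ModelSpec("under1_mortality", ("integration",), ("year", "country"), pw),
        "under1_full_controls": ModelSpec("under1_mortality", MORTALITY_CONTROLS, ("year",), pw),
        "ols_prod_so2": ModelSpec("prod_so2", POLLUTION_CONTROLS, (), ols, "listwise"),
        "ols_cons_so2": ModelSpec("cons_so2", POLLUTION_CONTROLS, (), ols, "listwise"),
        "ols_nem": ModelSpec("nem", POLLUTION_CONTROLS, (), ols, "listwise"),
        "ols_under5": ModelSpec("under5_mortality", MORTALITY_CONTROLS, (), ols, "listwise"),
        "ols_under1": ModelSpec("under1_mortality", MORTALITY_CONTROLS, (), ols, "listwise"),
    }


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode='simulate'`` generates the world from ``synthetic``;
    ``mode='ingest'`` reads the four-CSV MRIO layout from ``mrio_dir`` and
    the attribute panel from ``panel_csv``.
    """

    mode: str = "simulate"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    mrio_dir: str | None = None
    panel_csv: str | None = None
    out_dir: str = "results"
    include_final_demand: bool = True
    models: dict[str, ModelSpec] = field(default_factory=default_model_roster)
    write_mrio: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigError(f"unknown mode '{self.mode}'")
        if self.mode == "ingest":
            if not self.mrio_dir or not Path(self.mrio_dir).is_dir():
                raise ConfigError("ingest mode requires an existing mrio_dir")
            if not self.panel_csv or not Path(self.panel_csv).is_file():
                raise ConfigError("ingest mode requires an existing panel_csv")
        if not self.models:
            raise ConfigError("model roster is empty")

    def as_dict(self) -> dict[str, Any]:
        return {
            "mode": self.mode,
            "synthetic": self.synthetic.as_dict(),
            "mrio_dir": self.mrio_dir,
            "panel_csv": self.panel_csv,
            "out_dir": self.out_dir,
            "include_final_demand": self.include_final_demand,
            "write_mrio": self.write_mrio,
            "models": {
                name: dataclasses.asdict(spec) for name, spec in self.models.items()
            },
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("synthetic"), dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        models = d.get("models")
        if models:
            d["models"] = {
                name: spec if isinstance(spec, ModelSpec) else ModelSpec.from_dict(spec)
                for name, spec in models.items()
            }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def assemble_panel(
    footprints: pd.DataFrame,
    integration: pd.DataFrame,
    attributes: pd.DataFrame,
    log_vars=DEFAULT_LOG_VARS,
) -> PanelDataset:
    """Outer-join the three long tables on (country, year).

    Values that are nonpositive but registered for a log transform are set
    missing (with a counted warning) rather than offset: adding a constant
    before the log would silently change every elasticity.
    """
    merged = footprints[
        ["country", "year", "prod_so2", "cons_so2", "nem"]
    ].merge(
        integration[["country", "year", "integration"]],
        on=["country", "year"],
        how="outer",
    )
    merged = merged.merge(attributes, on=["country", "year"], how="outer")
    n_bad = 0
    for col in merged.columns:
        if col in log_vars:
            bad = merged[col].notna() & (merged[col] <= 0)
            n_bad += int(bad.sum())
            merged.loc[bad, col] = np.nan
    if n_bad:
        warnings.warn(
            f"{n_bad} nonpositive cells of log-registered variables set missing",
            stacklevel=2,
        )
    return PanelDataset(merged, log_vars=log_vars)


@dataclass
class ResultsBundle:
    """Everything one pipeline run produced."""

    footprints: pd.DataFrame
    integration: pd.DataFrame
    panel: PanelDataset
    descriptives: pd.DataFrame
    regressions: dict[str, PanelResults]
    failures: dict[str, str]
    ground_truth: GroundTruth | None
    provenance: dict[str, Any]

    def write(self, out_dir: str | Path) -> Path:
        """Write the bundle as CSV/JSON files; returns the directory.

        All numeric files are formatted deterministically; wall-clock
        timestamps live only in provenance.json.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ff = "%.12g"
        self.footprints.to_csv(out / "footprints.csv", index=False, float_format=ff)
        self.integration.to_csv(out / "integration.csv", index=False, float_format=ff)
        self.panel.to_csv(out / "panel.csv")
        self.descriptives.to_csv(out / "descriptive_stats.csv", float_format=ff)
        reg_dir = out / "regressions"
        reg_dir.mkdir(exist_ok=True)
        for name, res in sorted(self.regressions.items()):
            res.to_frame().rename_axis("term").to_csv(
                reg_dir / f"{name}.csv", float_format=ff
            )
            meta = {
                "estimator": res.estimator,
                "nobs": res.nobs,
                "rho": None if not np.isfinite(res.rho) else res.rho,
                "r_squared": res.rsquared,
                "adj_r_squared": None
                if not np.isfinite(res.rsquared_adj)
                else res.rsquared_adj,
                "wald_chi2": None if not np.isfinite(res.wald_chi2) else res.wald_chi2,
                "wald_df": res.wald_df,
                "dropped_terms": res.dropped_terms,
                "coefficients": res.params.to_dict(),
                "std_errors": res.bse.to_dict(),
                "p_values": res.pvalues.to_dict(),
            }
            (reg_dir / f"{name}.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True)
            )
        status = {
            "completed": sorted(self.regressions),
            "failed": {k: v for k, v in sorted(self.failures.items())},
        }
        (out / "run_summary.json").write_text(json.dumps(status, indent=2))
        if self.ground_truth is not None:
            self.ground_truth.to_json(out / "ground_truth.json")
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )
        return out


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute every stage; roster entries fail independently."""
    t0 = time.time()
    truth: GroundTruth | None = None
    if config.mode == "simulate":
        systems = generate_mrio_series(config.synthetic)
        footprints = footprint_series(systems)
        integration = integration_series(
            systems, include_final_demand=config.include_final_demand
        )
        raw_panel, truth = generate_panel(config.synthetic, footprints, integration)
        attribute_cols = [
            "country",
            "year",
            "population",
            "urbanization",
            "fertility",
            "health_expenditure",
            "under1_mortality",
            "under5_mortality",
        ]
        attributes = raw_panel.frame[attribute_cols]
        if config.write_mrio and config.mrio_dir:
            for system in systems:
                write_mrio_csv(system, config.mrio_dir)
    else:
        years = available_years(config.mrio_dir)
        systems = [read_mrio_csv(config.mrio_dir, y) for y in years]
        footprints = footprint_series(systems)
        integration = integration_series(
            systems, include_final_demand=config.include_final_demand
        )
        attributes = pd.read_csv(config.panel_csv)

    panel = assemble_panel(footprints, integration, attributes)
    descriptives = descriptive_stats(panel)

    regressions: dict[str, PanelResults] = {}
    failures: dict[str, str] = {}
    for name, spec in config.models.items():
        try:
            regressions[name] = fit(panel, spec)
        except Exception as exc:  # roster entries fail independently
            failures[name] = f"{type(exc).__name__}: {exc}"

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.synthetic.seed,
        "mode": config.mode,
        "software_version": __version__,
        "elapsed_seconds": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    return ResultsBundle(
        footprints=footprints,
        integration=integration,
        panel=panel,
        descriptives=descriptives,
        regressions=regressions,
        failures=failures,
        ground_truth=truth,
        provenance=provenance,
    )
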