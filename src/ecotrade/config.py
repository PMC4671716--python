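"""Configuration objects for the synthetic world and pipeline runs.

The synthetic generator emulates, at reduced scale, a multi-regional
input-output (MRIO) trade system with a planted core/periphery structure
plus a country-year attribute panel whose mortality series follows a known
linear-in-logs data-generating process.  Every random draw is controlled by
a single integer seed so that two runs with an identical configuration are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its stated bounds."""


@dataclass(frozen=True)
class PanelBetas:
    """Planted coefficients of the mortality DGP.

    The linear predictor acts on the same scales the estimation side uses:
    natural logs for integration, NEM, production SO2 and fertility; levels
    for health expenditure (% of GDP) and urbanization (% urban).
    """

    intercept: float = 2.0
    integration: float = -0.4
    nem: float = 0.05
    prod_so2: float = 0.02
    fertility: float = 1.2
    health_expenditure: float = -0.034
    urbanization: float = -0.016

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    #: order in which coefficients map onto design columns
    REGRESSORS = (
        "integration",
        "nem",
        "prod_so2",
        "fertility",
        "health_expenditure",
        "urbanization",
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic MRIO + panel world.

    Parameters
    ----------
    n_countries, n_sectors, n_years
        Size of the world.  Defaults mimic the 1990-2010 study window
        (21 years) at desk scale.
    core_fraction
        Share of countries planted in the core size class, in (0, 1).
    trade_scale
        Monetary scale of final demand (arbitrary currency units).
    gravity_exponent
        Exponent on the size product in the gravity-style bilateral flow
        model; 0 removes the planted core/periphery contrast.
    emission_elasticity
        Elasticity of sectoral SO2 intensity with respect to country size:
        positive values make large (core) countries dirtier per unit of
        output, which is what makes NEM vary with integration.
    panel_betas
        Planted coefficients of the log-mortality DGP.
    panel_noise_sd
        Standard deviation of the innovation of the mortality error term.
    ar1_rho
        Within-country first-order autocorrelation of the error, in (-1, 1).
    contemp_corr
        Exchangeable cross-country contemporaneous error correlation,
        in [0, 1).
    missing_rate
        Probability that an attribute-panel cell is masked missing-at-random,
        in [0, 1).
    """

    n_countries: int = 30
    n_sectors: int = 4
    n_years: int = 21
    core_fraction: float = 0.25
    trade_scale: float = 1000.0
    gravity_exponent: float = 1.0
    emission_elasticity: float = 0.3
    panel_betas: PanelBetas = field(default_factory=PanelBetas)
    panel_noise_sd: float = 0.3
    ar1_rho: float = 0.5
    contemp_corr: float = 0.3
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ConfigError("n_countries must be >= 2")
        if self.n_sectors < 1:
            raise ConfigError("n_sectors must be >= 1")
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        if not 0.0 < self.core_fraction < 1.0:
            raise ConfigError("core_fraction must lie in (0, 1)")
        if self.trade_scale <= 0:
            raise ConfigError("trade_scale must be positive")
        if self.gravity_exponent < 0:
            raise ConfigError("gravity_exponent must be >= 0")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho must lie in (-1, 1)")
        if not 0.0 <= self.contemp_corr < 1.0:
            raise ConfigError("contemp_corr must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.panel_noise_sd <= 0:
            raise ConfigError("panel_noise_sd must be positive")

    @property
    def n_core(self) -> int:
        """Number of core-class countries (at least one of each class)."""
        n = int(round(self.core_fraction * self.n_countries))
        return min(max(n, 1), self.n_countries - 1)

    @property
    def countries(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_countries)]

    @property
    def sectors(self) -> list[str]:
        return [f"S{j:02d}" for j in range(self.n_sectors)]

    @property
    def years(self) -> list[int]:
        return list(range(1990, 1990 + self.n_years))

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SyntheticConfig":
        d = dict(d)
        betas = d.get("panel_betas")
        if isinstance(betas, dict):
            d["panel_betas"] = PanelBetas(**betas)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters persisted alongside generated data.

    Consumed only by tests and recovery studies -- never by estimation code.
    """

    country_size_class: dict[str, str]  # country -> "core" | "periphery"
    panel_betas: PanelBetas
    ar1_rho: float
    contemp_corr: float
    under5_intercept_shift: float = 0.3

    def core_countries(self) -> list[str]:
        return [c for c, k in self.country_size_class.items() if k == "core"]

    def periphery_countries(self) -> list[str]:
        return [c for c, k in self.country_size_class.items() if k == "periphery"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "country_size_class": self.country_size_class,
            "panel_betas": self.panel_betas.as_dict(),
            "ar1_rho": self.ar1_rho,
            "contemp_corr": self.contemp_corr,
            "under5_intercept_shift": self.under5_intercept_shift,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            country_size_class=payload["country_size_class"],
            panel_betas=PanelBetas(**payload["panel_betas"]),
            ar1_rho=payload["ar1_rho"],
            contemp_corr=payload["contemp_corr"],
            under5_intercept_shift=payload.get("under5_intercept_shift", 0.3),
        )
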