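"""Synthetic MRIO systems and country-year panels with known ground truth.

The generator plants two structures that downstream estimators must be able
to recover:

* a **core/periphery trade structure** -- countries are split into a large
  "core" size class and a smaller "periphery" class, and bilateral flows
  follow a gravity rule (flow proportional to the product of the two
  endpoint sizes raised to ``gravity_exponent``), so core countries trade
  systematically more with everyone;
* a **linear-in-logs mortality process** -- log infant and child mortality
  are linear combinations of integration, NEM, production SO2, fertility,
  health expenditure and urbanization with known coefficients, plus an
  error that is AR(1) within country and exchangeably correlated across
  countries in the same year.

Construction of one year's accounts starts from the technical-coefficient
matrix ``A`` (column sums strictly below one) and final demand ``Y``, then
sets gross output ``x = (I - A)^{-1} Y 1`` and intermediate flows
``Z = A diag(x)``.  This makes the accounting identity
``x = Z 1 + Y 1`` exact, keeps value added ``x_j (1 - colsum_j A)``
nonnegative, and bounds the spectral radius of ``A`` by its largest column
sum -- so every generated system is productive by construction rather than
by after-the-fact rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GroundTruth, SyntheticConfig
from .mrio import MRIOError, MRIOSystem
from .panel import PanelDataset

_HOME_BIAS = 4.0  # domestic flows exceed gravity-implied foreign flows
_INTERMEDIATE_SHARE = (0.3, 0.6)  # column sums of A drawn in this range
_BASE_INTENSITY = 0.5  # Gg SO2 per unit gross output at size 1


class GenerationError(RuntimeError):
    """Raised when a configuration cannot yield a feasible MRIO system."""


@dataclass(frozen=True)
class _WorldParams:
    """Per-country latent parameters, fixed across years of one world."""

    is_core: np.ndarray  # bool (R,)
    size: np.ndarray  # (R,) base economic size
    growth: np.ndarray  # (R,) annual growth rate
    pop0: np.ndarray  # (R,) base population, millions
    urb0: np.ndarray  # (R,) base urbanization %
    fert0: np.ndarray  # (R,) base fertility
    health0: np.ndarray  # (R,) base health expenditure % GDP


def _world_params(config: SyntheticConfig) -> _WorldParams:
    rng = np.random.default_rng([config.seed, 101])
    R = config.n_countries
    order = rng.permutation(R)
    is_core = np.zeros(R, dtype=bool)
    is_core[order[: config.n_core]] = True
    # core countries are roughly an order of magnitude larger
    mu = np.where(is_core, np.log(8.0), 0.0)
    size = np.exp(rng.normal(mu, 0.3))
    growth = rng.normal(0.02, 0.01, R)
    pop0 = size * np.exp(rng.normal(0.0, 0.3, R)) * 10.0
    urb0 = np.where(
        is_core, rng.uniform(55, 85, R), rng.uniform(20, 60, R)
    )
    fert0 = np.where(
        is_core, rng.uniform(1.5, 2.5, R), rng.uniform(3.0, 6.0, R)
    )
    health0 = np.where(
        is_core, rng.uniform(5.0, 9.0, R), rng.uniform(2.0, 6.0, R)
    )
    return _WorldParams(is_core, size, growth, pop0, urb0, fert0, health0)


def _gravity_weights(size: np.ndarray, exponent: float) -> np.ndarray:
    G = np.power(np.outer(size, size), exponent)
    np.fill_diagonal(G, _HOME_BIAS * np.power(size * size, exponent))
    return G


def generate_mrio(config: SyntheticConfig, year_index: int) -> MRIOSystem:
    """Generate one year's MRIO system with planted core/periphery trade.

    Deterministic in ``(config, year_index)``: repeated calls are
    bit-identical.
    """
    if not 0 <= year_index < config.n_years:
        raise GenerationError(
            f"year_index {year_index} outside [0, {config.n_years})"
        )
    params = _world_params(config)
    rng = np.random.default_rng([config.seed, 202, year_index])
    R, S = config.n_countries, config.n_sectors
    n = R * S
    size_t = params.size * np.power(1.0 + params.growth, year_index)
    G = _gravity_weights(size_t, config.gravity_exponent)
    G_sector = np.kron(G, np.ones((S, S)))

    # technical coefficients: column sums drawn strictly below 1
    alpha = rng.uniform(*_INTERMEDIATE_SHARE, n)
    raw = G_sector * rng.uniform(0.5, 1.5, (n, n))
    col_totals = raw.sum(axis=0)
    if np.any(col_totals <= 0):
        raise GenerationError("degenerate gravity weights: empty input column")
    A = raw / col_totals * alpha

    # final demand: consumer d spends trade_scale * size_d, sourced by gravity
    spend = config.trade_scale * size_t
    src = np.kron(G, np.ones((S, 1))) * rng.uniform(0.5, 1.5, (n, R))
    src_totals = src.sum(axis=0)
    if np.any(src_totals <= 0):
        raise GenerationError("degenerate gravity weights: empty demand column")
    Y = src / src_totals * spend

    x = np.linalg.solve(np.eye(n) - A, Y.sum(axis=1))
    Z = A * x[np.newaxis, :]
    value_added = x - Z.sum(axis=0)

    # SO2 intensity scales with country size class via the planted elasticity
    country_size = np.repeat(size_t, S)
    q = (
        _BASE_INTENSITY
        * np.power(country_size, config.emission_elasticity)
        * np.exp(rng.normal(0.0, 0.2, n))
    )
    so2 = q * x

    try:
        return MRIOSystem(
            countries=config.countries,
            sectors=config.sectors,
            Z=Z,
            Y=Y,
            value_added=value_added,
            so2=so2,
            year=config.years[year_index],
        )
    except MRIOError as exc:
        raise GenerationError(f"infeasible configuration: {exc}") from exc


def generate_mrio_series(config: SyntheticConfig) -> list[MRIOSystem]:
    """One system per year of the configured window."""
    return [generate_mrio(config, t) for t in range(config.n_years)]


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Planted parameters of the configured world."""
    params = _world_params(config)
    classes = {
        c: ("core" if k else "periphery")
        for c, k in zip(config.countries, params.is_core)
    }
    return GroundTruth(
        country_size_class=classes,
        panel_betas=config.panel_betas,
        ar1_rho=config.ar1_rho,
        contemp_corr=config.contemp_corr,
    )


def _covariate_trajectories(config: SyntheticConfig) -> pd.DataFrame:
    """Per-country linear trends plus bounded noise for the attribute panel."""
    params = _world_params(config)
    rng = np.random.default_rng([config.seed, 303])
    R, T = config.n_countries, config.n_years
    t = np.arange(T)
    pop = params.pop0[:, None] * (1.0 + 0.02 * t[None, :]) * np.exp(
        rng.normal(0.0, 0.02, (R, T))
    )
    urb = np.clip(
        params.urb0[:, None] + 0.4 * t[None, :] + rng.normal(0.0, 1.0, (R, T)),
        0.0,
        100.0,
    )
    fert = np.maximum(
        params.fert0[:, None] * (1.0 - 0.01 * t[None, :])
        + rng.normal(0.0, 0.1, (R, T)),
        0.5,
    )
    health = np.clip(
        params.health0[:, None] + 0.03 * t[None, :] + rng.normal(0.0, 0.3, (R, T)),
        0.5,
        15.0,
    )
    rows = []
    for i, c in enumerate(config.countries):
        for j, yr in enumerate(config.years):
            rows.append(
                (c, yr, pop[i, j], urb[i, j], fert[i, j], health[i, j])
            )
    return pd.DataFrame(
        rows,
        columns=[
            "country",
            "year",
            "population",
            "urbanization",
            "fertility",
            "health_expenditure",
        ],
    )


def _panel_errors(config: SyntheticConfig, stream: int) -> np.ndarray:
    """AR(1)-within-country, exchangeably-correlated-across-country errors.

    Shape (T, R).  Innovations for year t share a common factor with weight
    sqrt(contemp_corr), giving every country pair contemporaneous
    correlation ``contemp_corr`` and unit innovation variance before the
    ``panel_noise_sd`` scale.  The AR(1) recursion starts from its
    stationary distribution.
    """
    rng = np.random.default_rng([config.seed, 404, stream])
    R, T = config.n_countries, config.n_years
    rho, c, sd = config.ar1_rho, config.contemp_corr, config.panel_noise_sd
    common = rng.normal(0.0, 1.0, (T, 1))
    idio = rng.normal(0.0, 1.0, (T, R))
    eps = sd * (np.sqrt(c) * common + np.sqrt(1.0 - c) * idio)
    u = np.empty((T, R))
    u[0] = eps[0] / np.sqrt(1.0 - rho**2)
    for t in range(1, T):
        u[t] = rho * u[t - 1] + eps[t]
    return u


def generate_panel(
    config: SyntheticConfig,
    footprints: pd.DataFrame,
    integration: pd.DataFrame,
) -> tuple[PanelDataset, GroundTruth]:
    """Build the country-year panel with planted mortality coefficients.

    Parameters
    ----------
    footprints
        Long table from :func:`ecotrade.mrio.footprint_series` computed on
        the same generated MRIO series (columns country, year, prod_so2,
        cons_so2, nem, ...).
    integration
        Long table from :func:`ecotrade.network.integration_series`
        (columns country, year, integration).

    Returns the panel plus the :class:`GroundTruth` actually used.  The
    ground truth is persisted alongside the data and is never consumed by
    estimation code.
    """
    covars = _covariate_trajectories(config)
    merged = covars.merge(
        footprints[["country", "year", "prod_so2", "cons_so2", "nem"]],
        on=["country", "year"],
        how="left",
        validate="one_to_one",
    ).merge(
        integration[["country", "year", "integration"]],
        on=["country", "year"],
        how="left",
        validate="one_to_one",
    )
    if merged[["prod_so2", "nem", "integration"]].isna().any().any():
        raise GenerationError(
            "footprint/integration tables do not cover the configured "
            "country-year grid"
        )
    merged = merged.sort_values(["country", "year"]).reset_index(drop=True)

    b = config.panel_betas
    with np.errstate(divide="ignore"):
        eta = (
            b.intercept
            + b.integration * np.log(merged["integration"].to_numpy())
            + b.nem * np.log(merged["nem"].to_numpy())
            + b.prod_so2 * np.log(merged["prod_so2"].to_numpy())
            + b.fertility * np.log(merged["fertility"].to_numpy())
            + b.health_expenditure * merged["health_expenditure"].to_numpy()
            + b.urbanization * merged["urbanization"].to_numpy()
        )
    if not np.all(np.isfinite(eta)):
        raise GenerationError("nonpositive value hit a log in the mortality DGP")

    truth = ground_truth(config)
    # errors are generated on a (T, R) grid; rows are sorted country-major
    u1 = _panel_errors(config, stream=1).T.reshape(-1)
    u5 = _panel_errors(config, stream=2).T.reshape(-1)
    merged["under1_mortality"] = np.exp(eta + u1)
    merged["under5_mortality"] = np.exp(
        eta + truth.under5_intercept_shift + u5
    )

    # missing-at-random mask on the attribute/mortality variables only;
    # the MRIO-derived series stay complete (their unbalancedness in real
    # data comes from country coverage, not cell-level gaps)
    if config.missing_rate > 0:
        rng = np.random.default_rng([config.seed, 505])
        maskable = [
            "population",
            "urbanization",
            "fertility",
            "health_expenditure",
            "under1_mortality",
            "under5_mortality",
        ]
        for col in maskable:
            mask = rng.random(len(merged)) < config.missing_rate
            merged.loc[mask, col] = np.nan

    return PanelDataset(merged), truth
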