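"""Environmentally-extended input-output accounting.

A multi-regional input-output (MRIO) system records, for one year, the
monetary flows between every sector of every country (the inter-industry
matrix ``Z``), the final demand each consuming country places on every
producing sector (``Y``), the value added generated in each sector, and a
physical SO2 satellite account aligned to the sector axis.

From such a system this module computes:

* gross output ``x`` and the technical-coefficient matrix ``A = Z diag(x)^-1``,
* the Leontief inverse ``L = (I - A)^-1``, whose entry ``L_ij`` is the total
  (direct plus indirect) output of sector *i* required per unit of final
  demand for sector *j*,
* production-based SO2 (emissions released inside a country's borders) and
  consumption-based SO2 (emissions anywhere along the global supply chains
  triggered by a country's final demand),
* each country's share of global production-based SO2 (%SO2) and of global
  value added (%VA), and the normalized efficiency measure
  ``NEM = %SO2 / %VA`` -- values above 1 flag countries whose share of world
  pollution exceeds their share of world income.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class MRIOError(ValueError):
    """Raised for inconsistent or non-productive MRIO systems."""


@dataclass
class MRIOSystem:
    """One year's inter-country, inter-sector economic system.

    Axis order is countries-major, sectors-minor and identical on every
    axis: row/column ``c * S + s`` is sector ``s`` of country ``c``.
    """

    countries: list[str]
    sectors: list[str]
    Z: np.ndarray  # (RS, RS) intermediate flows, monetary
    Y: np.ndarray  # (RS, R) final demand, monetary
    value_added: np.ndarray  # (RS,) monetary
    so2: np.ndarray  # (RS,) physical units (Gg)
    year: int = 0

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.value_added = np.asarray(self.value_added, dtype=float)
        self.so2 = np.asarray(self.so2, dtype=float)
        self.validate()

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def labels(self) -> list[str]:
        return [f"{c}.{s}" for c in self.countries for s in self.sectors]

    def validate(self, tol: float = 1e-9) -> None:
        R, S = self.n_countries, self.n_sectors
        n = R * S
        if self.Z.shape != (n, n):
            raise MRIOError(f"Z must be {(n, n)}, got {self.Z.shape}")
        if self.Y.shape != (n, R):
            raise MRIOError(f"Y must be {(n, R)}, got {self.Y.shape}")
        if self.value_added.shape != (n,):
            raise MRIOError(f"value_added must be ({n},), got {self.value_added.shape}")
        if self.so2.shape != (n,):
            raise MRIOError(f"so2 must be ({n},), got {self.so2.shape}")
        if (self.Z < 0).any() or (self.Y < 0).any():
            raise MRIOError("Z and Y must be elementwise nonnegative")
        if (self.so2 < 0).any():
            raise MRIOError("so2 satellite must be elementwise nonnegative")
        x = gross_output(self, _validate=False)
        intermediate = self.Z.sum(axis=0)
        scale = max(float(np.abs(x).max()), 1.0)
        if (x - intermediate < -tol * scale).any():
            raise MRIOError("implied value added is negative (x < column sums of Z)")


def gross_output(system: MRIOSystem, _validate: bool = True) -> np.ndarray:
    """Gross output ``x_i = sum_j Z_ij + sum_c Y_ic`` per sector row."""
    return system.Z.sum(axis=1) + system.Y.sum(axis=1)


@dataclass
class TechnicalCoefficients:
    """Input requirements per unit of gross output, ``A_ij = Z_ij / x_j``."""

    A: np.ndarray
    spectral_radius: float


def technical_coefficients(system: MRIOSystem) -> TechnicalCoefficients:
    """Compute ``A = Z diag(x)^-1`` with zero-output columns zeroed.

    Raises
    ------
    MRIOError
        If the spectral radius of ``A`` is >= 1 (a non-productive economy
        whose Leontief series would diverge); the offending modulus is named.
    """
    x = gross_output(system)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(x[np.newaxis, :] > 0, system.Z / x[np.newaxis, :], 0.0)
    rho = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    if rho >= 1.0:
        raise MRIOError(
            f"non-productive economy: spectral radius of A is {rho:.6f} >= 1"
        )
    return TechnicalCoefficients(A=A, spectral_radius=rho)


def leontief_inverse(coeffs: TechnicalCoefficients) -> np.ndarray:
    """Dense solve of ``(I - A) L = I``; validated to 1e-10.

    The Neumann series ``sum_k A^k`` converges to the same matrix for
    spectral radius < 1 and is kept as a test oracle only.
    """
    A = coeffs.A
    n = A.shape[0]
    eye = np.eye(n)
    try:
        L = np.linalg.solve(eye - A, eye)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise MRIOError("singular (I - A); Leontief inverse undefined") from exc
    resid = float(np.max(np.abs(L @ (eye - A) - eye)))
    if resid > 1e-8:
        raise MRIOError(f"Leontief inverse failed residual check ({resid:.2e})")
    return L


def _per_country_sum(values: np.ndarray, R: int, S: int) -> np.ndarray:
    return values.reshape(R, S).sum(axis=1)


def production_based_so2(system: MRIOSystem) -> pd.Series:
    """Territorial emissions: the satellite summed over each country's sectors."""
    totals = _per_country_sum(system.so2, system.n_countries, system.n_sectors)
    return pd.Series(totals, index=system.countries, name="prod_so2")


def consumption_based_so2(system: MRIOSystem) -> pd.Series:
    """Footprint emissions allocated to the consuming country.

    Direct pollution intensities ``q_i = so2_i / x_i`` are applied to the
    total outputs ``L Y[:, c]`` triggered by country *c*'s final demand:
    ``cons_c = q' L Y[:, c]``.  Summed over countries this conserves the
    global production total whenever final demand spans all final use.
    """
    x = gross_output(system)
    zero_out = x <= 0
    if np.any(zero_out & (system.so2 > 0)):
        bad = [system.labels[i] for i in np.where(zero_out & (system.so2 > 0))[0]]
        raise MRIOError(
            f"emission intensity undefined: sectors with SO2 but zero output: {bad}"
        )
    q = np.where(zero_out, 0.0, system.so2 / np.where(zero_out, 1.0, x))
    L = leontief_inverse(technical_coefficients(system))
    cons = q @ (L @ system.Y)
    return pd.Series(cons, index=system.countries, name="cons_so2")


def value_added_by_country(system: MRIOSystem) -> pd.Series:
    totals = _per_country_sum(
        system.value_added, system.n_countries, system.n_sectors
    )
    return pd.Series(totals, index=system.countries, name="value_added")


def nem(share_so2: pd.Series, share_va: pd.Series) -> pd.Series:
    """Normalized efficiency measure ``NEM_c = %SO2_c / %VA_c``.

    Countries with zero value-added share but positive emissions get a
    missing NEM (the ratio is undefined) with a warning.
    """
    share_so2, share_va = share_so2.align(share_va)
    out = pd.Series(np.nan, index=share_so2.index, name="nem")
    ok = share_va > 0
    out[ok] = share_so2[ok] / share_va[ok]
    undefined = (~ok) & (share_so2 > 0)
    if undefined.any():
        warnings.warn(
            f"NEM undefined for {list(share_so2.index[undefined])}: "
            "zero value-added share with positive SO2 share",
            stacklevel=2,
        )
    out[(~ok) & (share_so2 == 0)] = np.nan
    return out


def footprint_accounts(system: MRIOSystem) -> pd.DataFrame:
    """Full per-country account table for one year.

    Columns: prod_so2, cons_so2, value_added, share_so2 (%), share_va (%),
    nem.  Shares are computed over the countries present in the system, so
    each share column sums to 100 and the value-added-weighted mean of NEM
    is exactly 1 (``sum_c NEM_c * %VA_c = 100``).
    """
    prod = production_based_so2(system)
    cons = consumption_based_so2(system)
    va = value_added_by_country(system)
    share_so2 = 100.0 * prod / prod.sum() if prod.sum() > 0 else prod * np.nan
    share_va = 100.0 * va / va.sum() if va.sum() > 0 else va * np.nan
    table = pd.DataFrame(
        {
            "prod_so2": prod,
            "cons_so2": cons,
            "value_added": va,
            "share_so2": share_so2,
            "share_va": share_va,
            "nem": nem(share_so2, share_va),
        }
    )
    table.index.name = "country"
    table.insert(0, "year", system.year)
    return table


def footprint_series(systems: Sequence[MRIOSystem]) -> pd.DataFrame:
    """Stack per-year footprint accounts into one long table."""
    return pd.concat([footprint_accounts(s) for s in systems]).reset_index()


# ---------------------------------------------------------------------------
# CSV layout: four files per year with COUNTRY.SECTOR labels
# ---------------------------------------------------------------------------

def write_mrio_csv(system: MRIOSystem, out_dir: str | Path) -> None:
    """Write Z, Y, value_added and so2_satellite CSVs for one year."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = system.labels
    tag = system.year
    pd.DataFrame(system.Z, index=labels, columns=labels).to_csv(
        out / f"Z_{tag}.csv", float_format="%.12g"
    )
    pd.DataFrame(system.Y, index=labels, columns=system.countries).to_csv(
        out / f"Y_{tag}.csv", float_format="%.12g"
    )
    pd.DataFrame({"value_added": system.value_added}, index=labels).to_csv(
        out / f"value_added_{tag}.csv", float_format="%.12g"
    )
    pd.DataFrame({"so2": system.so2}, index=labels).to_csv(
        out / f"so2_satellite_{tag}.csv", float_format="%.12g"
    )


def read_mrio_csv(mrio_dir: str | Path, year: int) -> MRIOSystem:
    """Read one year's system from the four-CSV layout."""
    d = Path(mrio_dir)
    Z = pd.read_csv(d / f"Z_{year}.csv", index_col=0)
    Y = pd.read_csv(d / f"Y_{year}.csv", index_col=0)
    va = pd.read_csv(d / f"value_added_{year}.csv", index_col=0)
    so2 = pd.read_csv(d / f"so2_satellite_{year}.csv", index_col=0)
    labels = list(Z.index)
    countries: list[str] = []
    sectors: list[str] = []
    for lab in labels:
        c, s = lab.rsplit(".", 1)
        if c not in countries:
            countries.append(c)
        if s not in sectors:
            sectors.append(s)
    expected = [f"{c}.{s}" for c in countries for s in sectors]
    if labels != expected:
        raise MRIOError("MRIO CSV labels are not countries-major, sectors-minor")
    return MRIOSystem(
        countries=countries,
        sectors=sectors,
        Z=Z.to_numpy(),
        Y=Y.loc[labels, countries].to_numpy(),
        value_added=va.loc[labels, "value_added"].to_numpy(),
        so2=so2.loc[labels, "so2"].to_numpy(),
        year=year,
    )


def available_years(mrio_dir: str | Path) -> list[int]:
    """Years present in an MRIO CSV directory, sorted."""
    years = sorted(
        int(p.stem.split("_")[1]) for p in Path(mrio_dir).glob("Z_*.csv")
    )
    if not years:
        raise MRIOError(f"no MRIO year files found in {mrio_dir}")
    return years
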