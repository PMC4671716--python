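"""Time-series cross-sectional estimation with panel-corrected standard errors.

The estimator implemented here is the Prais-Winsten feasible-GLS procedure
for a common first-order autocorrelation, combined with panel-corrected
standard errors (PCSE) that allow the disturbances to be heteroskedastic
across panels and contemporaneously correlated between panels:

1. pooled OLS on the (possibly log-transformed) design;
2. a common AR(1) coefficient ``rho`` pooled over every within-country pair
   of consecutive years:  ``rho = sum e_t e_{t-1} / sum e_{t-1}^2``;
3. the Prais-Winsten transform -- the first observation of each
   within-country run of consecutive years is scaled by ``sqrt(1-rho^2)``
   and each later one quasi-differenced (``v_t - rho v_{t-1}``), applied to
   the response, the regressors, the constant and any fixed-effect dummies
   alike;
4. OLS on the transformed data;
5. the PCSE sandwich: the cross-country contemporaneous covariance
   ``Sigma_ij`` is estimated entrywise from transformed residuals (under
   *pairwise* handling over the years both panels are observed, maximizing
   the usable observations of an unbalanced panel; under *listwise* over
   the jointly balanced years only) and plugged into
   ``(X'X)^-1 X' Omega X (X'X)^-1`` with ``Omega`` block-diagonal by year.

A listwise-deletion OLS variant with classical standard errors and adjusted
R-squared serves as the robustness check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: variables that enter models in natural-log form (levels: urbanization,
#: health expenditure as % of GDP)
DEFAULT_LOG_VARS = frozenset(
    {
        "cons_so2",
        "prod_so2",
        "integration",
        "nem",
        "population",
        "under1_mortality",
        "under5_mortality",
        "fertility",
    }
)

PANEL_VARIABLES = (
    "cons_so2",
    "prod_so2",
    "integration",
    "nem",
    "population",
    "urbanization",
    "under1_mortality",
    "under5_mortality",
    "fertility",
    "health_expenditure",
)


class PanelError(ValueError):
    pass


class PanelDataset:
    """Long country-year table of regression variables.

    ``(country, year)`` keys are unique; within each country the year index
    is made contiguous on construction (gaps become rows of missing values,
    so Prais-Winsten run bookkeeping can see them).  A log-transform
    registry records which variables enter models in natural logs.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        log_vars: Iterable[str] = DEFAULT_LOG_VARS,
    ):
        if not {"country", "year"}.issubset(frame.columns):
            raise PanelError("panel frame needs 'country' and 'year' columns")
        if frame.duplicated(["country", "year"]).any():
            raise PanelError("duplicate (country, year) keys in panel")
        self.log_vars = frozenset(log_vars)
        self.frame = self._complete_years(frame)

    @staticmethod
    def _complete_years(frame: pd.DataFrame) -> pd.DataFrame:
        pieces = []
        for country, grp in frame.groupby("country", sort=True):
            years = grp["year"].astype(int)
            full = pd.DataFrame(
                {"country": country, "year": range(years.min(), years.max() + 1)}
            )
            pieces.append(
                full.merge(grp, on=["country", "year"], how="left")
            )
        out = pd.concat(pieces, ignore_index=True)
        return out.sort_values(["country", "year"]).reset_index(drop=True)

    @property
    def variables(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("country", "year")]

    def transformed(self, var: str) -> pd.Series:
        """The variable on its model scale (log where registered)."""
        col = self.frame[var]
        if var in self.log_vars:
            bad = col.notna() & (col <= 0)
            if bad.any():
                row = self.frame.loc[bad.idxmax()]
                raise PanelError(
                    f"variable '{var}' is log-registered but nonpositive at "
                    f"{row['country']} {int(row['year'])}"
                )
            return np.log(col)
        return col.astype(float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(
        cls, path: str | Path, log_vars: Iterable[str] = DEFAULT_LOG_VARS
    ) -> "PanelDataset":
        return cls(pd.read_csv(path), log_vars=log_vars)


@dataclass(frozen=True)
class ModelSpec:
    """One regression specification.

    ``estimator`` is ``prais_winsten_pcse`` or ``listwise_ols``;
    ``missing_handling`` (``pairwise``/``listwise``) governs how the
    contemporaneous covariance of an unbalanced panel is estimated.
    """

    response: str
    regressors: tuple[str, ...]
    fixed_effects: tuple[str, ...] = ()
    estimator: str = "prais_winsten_pcse"
    missing_handling: str = "pairwise"

    def __post_init__(self) -> None:
        if self.response in self.regressors:
            raise PanelError("response cannot appear among regressors")
        bad_fe = set(self.fixed_effects) - {"year", "country"}
        if bad_fe:
            raise PanelError(f"unknown fixed effects: {sorted(bad_fe)}")
        if self.estimator not in ("prais_winsten_pcse", "listwise_ols"):
            raise PanelError(f"unknown estimator '{self.estimator}'")
        if self.missing_handling not in ("pairwise", "listwise"):
            raise PanelError(f"unknown missing_handling '{self.missing_handling}'")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            response=d["response"],
            regressors=tuple(d["regressors"]),
            fixed_effects=tuple(d.get("fixed_effects", ())),
            estimator=d.get("estimator", "prais_winsten_pcse"),
            missing_handling=d.get("missing_handling", "pairwise"),
        )


@dataclass
class Design:
    """Estimation-ready design: complete-case rows sorted by (country, year)."""

    y: np.ndarray
    X: pd.DataFrame  # columns: const, substantive terms, dummies
    countries: np.ndarray
    years: np.ndarray
    substantive: list[str]  # non-intercept, non-dummy column names
    dropped_terms: list[str] = field(default_factory=list)


def _drop_collinear(X: pd.DataFrame, protect: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Rank-revealing pivoted QR; dependent columns dropped, protected kept."""
    cols = list(X.columns)
    M = X.to_numpy(dtype=float)
    norms = np.linalg.norm(M, axis=0)
    norms[norms == 0] = 1.0
    _, r = np.linalg.qr(M / norms)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > 1e-10 * max(diag.max(), 1.0)))
    if rank == len(cols):
        return X, []
    # greedy: keep columns in order while they extend the column space
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(len(cols)):
        trial = M[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-10 * max(norms.max(), 1.0)) > len(keep):
            keep.append(j)
        elif cols[j] in protect:
            keep.append(j)  # protected columns are never dropped
        else:
            dropped.append(cols[j])
    warnings.warn(
        f"collinear design: dropped {dropped} (highly singular variance matrix)",
        stacklevel=3,
    )
    return X.iloc[:, keep], dropped


def build_design(panel: PanelDataset, spec: ModelSpec) -> Design:
    """Transform, dummy-encode and screen the regression design.

    Rows with a missing response or any missing regressor are excluded from
    the estimation rows (they remain in the panel for pairwise
    bookkeeping).  Duplicate regressors and collinear columns are dropped
    and reported in ``dropped_terms``.
    """
    missing_vars = [
        v for v in (spec.response, *spec.regressors) if v not in panel.frame.columns
    ]
    if missing_vars:
        raise PanelError(f"panel lacks variables: {missing_vars}")

    dropped: list[str] = []
    regressors: list[str] = []
    for v in spec.regressors:
        if v in regressors:
            dropped.append(v)
        else:
            regressors.append(v)
    if dropped:
        warnings.warn(f"duplicate regressors dropped: {dropped}", stacklevel=2)

    df = panel.frame
    y = panel.transformed(spec.response)
    cols = {"const": pd.Series(1.0, index=df.index)}
    for v in regressors:
        cols[v] = panel.transformed(v)
    X = pd.DataFrame(cols)

    for fe in spec.fixed_effects:
        dummies = pd.get_dummies(
            df[fe].astype("category"), prefix=fe, drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)

    complete = y.notna() & X.notna().all(axis=1)
    ys = y[complete].to_numpy(dtype=float)
    Xs = X.loc[complete]
    countries = df.loc[complete, "country"].to_numpy()
    years = df.loc[complete, "year"].to_numpy(dtype=int)

    order = np.lexsort((years, countries))
    ys, Xs = ys[order], Xs.iloc[order]
    countries, years = countries[order], years[order]

    Xs, collinear = _drop_collinear(Xs, protect=["const"])
    dropped.extend(collinear)
    substantive = [c for c in Xs.columns if c != "const" and c in regressors]
    return Design(
        y=ys,
        X=Xs.reset_index(drop=True),
        countries=countries,
        years=years,
        substantive=substantive,
        dropped_terms=dropped,
    )


def estimate_rho(
    residuals: np.ndarray, countries: np.ndarray, years: np.ndarray
) -> float:
    """Common AR(1) coefficient pooled over consecutive within-country pairs.

    ``rho = sum_i sum_t e_{i,t} e_{i,t-1} / sum_i sum_t e_{i,t-1}^2`` where
    the sums run over pairs of consecutive observed years; clamped into
    (-0.999, 0.999) with a warning if the raw ratio falls outside.
    """
    num = den = 0.0
    pairs = 0
    for c in pd.unique(countries):
        m = countries == c
        yrs, e = years[m], residuals[m]
        consec = np.where(np.diff(yrs) == 1)[0]
        if consec.size:
            lag, cur = e[consec], e[consec + 1]
            num += float(lag @ cur)
            den += float(lag @ lag)
            pairs += consec.size
    if pairs == 0 or den == 0.0:
        raise PanelError("no consecutive within-country pairs; cannot estimate rho")
    rho = num / den
    if abs(rho) >= 0.999:
        warnings.warn(f"rho estimate {rho:.4f} clamped to (-0.999, 0.999)", stacklevel=2)
        rho = float(np.clip(rho, -0.999, 0.999))
    return rho


def prais_winsten_transform(
    y: np.ndarray,
    X: np.ndarray,
    countries: np.ndarray,
    years: np.ndarray,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-difference each within-country run of consecutive years.

    The first observation of every run is scaled by ``sqrt(1 - rho^2)``
    (Prais-Winsten keeps it rather than dropping it); each subsequent
    observation becomes ``v_t - rho v_{t-1}``.  A gap in the year index
    restarts the first-observation rule.  Applied to the response and every
    design column, including the constant and dummies.
    """
    if not abs(rho) < 1:
        raise PanelError("|rho| must be < 1 for the Prais-Winsten transform")
    yt = np.array(y, dtype=float)
    Xt = np.array(X, dtype=float)
    scale = np.sqrt(1.0 - rho**2)
    n = len(y)
    is_first = np.ones(n, dtype=bool)
    if n > 1:
        same_country = countries[1:] == countries[:-1]
        consecutive = np.diff(years) == 1
        is_first[1:] = ~(same_country & consecutive)
    follow = ~is_first
    yt[follow] = y[follow] - rho * y[np.where(follow)[0] - 1]
    Xt[follow] = X[follow] - rho * X[np.where(follow)[0] - 1]
    yt[is_first] = scale * y[is_first]
    Xt[is_first] = scale * X[is_first]
    return yt, Xt


def contemporaneous_covariance(
    residuals: np.ndarray,
    countries: np.ndarray,
    years: np.ndarray,
    missing_handling: str = "pairwise",
) -> pd.DataFrame:
    """Entrywise cross-country covariance of (transformed) residuals.

    Pairwise: ``Sigma_ij = sum_t e_i e_j / n_ij`` over the years both i and
    j are observed; pairs that never overlap get 0 with a warning.
    Listwise: only the years in which every panel is observed are used.
    """
    table = pd.DataFrame(
        {"country": countries, "year": years, "e": residuals}
    ).pivot(index="year", columns="country", values="e")
    if missing_handling == "listwise":
        table = table.dropna(axis=0, how="any")
        if table.empty:
            raise PanelError("no jointly observed years for listwise covariance")
    E = table.to_numpy()
    obs = (~np.isnan(E)).astype(float)
    E0 = np.nan_to_num(E)
    cross = E0.T @ E0
    counts = obs.T @ obs
    if np.any(np.diag(counts) == 0):
        raise PanelError("a panel has no usable years for its variance term")
    zero_overlap = counts == 0
    if zero_overlap.any():
        warnings.warn(
            "some country pairs never overlap in time; their covariance is set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.where(zero_overlap, 0.0, cross / np.where(counts == 0, 1.0, counts))
    sigma = (sigma + sigma.T) / 2.0
    return pd.DataFrame(sigma, index=table.columns, columns=table.columns)


def _project_psd(sigma: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues: pairwise denominators on an unbalanced
    panel can break positive semidefiniteness, which would let sandwich
    variances go negative."""
    eigvals, eigvecs = np.linalg.eigh(sigma)
    tol = -1e-12 * max(float(eigvals.max()), 1.0)
    if eigvals.min() < tol:
        warnings.warn(
            "contemporaneous covariance was indefinite "
            f"(min eigenvalue {eigvals.min():.2e}); negative eigenvalues clipped",
            stacklevel=3,
        )
        sigma = (eigvecs * np.clip(eigvals, 0.0, None)) @ eigvecs.T
        sigma = (sigma + sigma.T) / 2.0
    return sigma


def pcse_covariance(
    X: np.ndarray,
    residuals: np.ndarray,
    countries: np.ndarray,
    years: np.ndarray,
    missing_handling: str = "pairwise",
) -> np.ndarray:
    """Sandwich covariance ``(X'X)^-1 X' Omega X (X'X)^-1``.

    ``Omega`` is block-diagonal by year with blocks taken from the
    estimated contemporaneous covariance, restricted to the countries
    observed in that year.
    """
    sigma = contemporaneous_covariance(
        residuals, countries, years, missing_handling
    )
    order = list(sigma.index)
    pos = {c: i for i, c in enumerate(order)}
    S = _project_psd(sigma.to_numpy())
    k = X.shape[1]
    meat = np.zeros((k, k))
    for yr in np.unique(years):
        sel = np.where(years == yr)[0]
        idx = [pos[c] for c in countries[sel]]
        Xt_yr = X[sel]
        meat += Xt_yr.T @ S[np.ix_(idx, idx)] @ Xt_yr
    xtx_inv = np.linalg.inv(X.T @ X)
    V = xtx_inv @ meat @ xtx_inv
    V = (V + V.T) / 2.0
    min_eig = float(np.linalg.eigvalsh(V).min())
    if min_eig < -1e-10 * max(abs(V).max(), 1.0):
        warnings.warn(
            f"PCSE covariance is indefinite (min eigenvalue {min_eig:.2e})",
            stacklevel=2,
        )
    return V


@dataclass
class PanelResults:
    """Estimates, panel-corrected uncertainties and fit diagnostics."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    rho: float
    rsquared: float
    wald_chi2: float
    wald_df: int
    nobs: int
    substantive: list[str]
    dropped_terms: list[str]
    estimator: str
    rsquared_adj: float = float("nan")
    spec: ModelSpec | None = None

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        stat_name = "z" if self.estimator == "prais_winsten_pcse" else "t"
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "std_err": self.bse,
                stat_name: self.zvalues,
                "p_value": self.pvalues,
            }
        )

    def summary(self) -> str:
        label = (
            "Prais-Winsten with panel-corrected standard errors"
            if self.estimator == "prais_winsten_pcse"
            else "Listwise-deletion OLS (classical standard errors)"
        )
        lines = [label, "=" * len(label)]
        if self.spec is not None:
            fe = ", ".join(self.spec.fixed_effects) or "none"
            lines.append(f"Response: {self.spec.response}    Fixed effects: {fe}")
        lines.append(f"Observations: {self.nobs}")
        if np.isfinite(self.rho):
            lines.append(f"Common AR(1) rho: {self.rho:.4f}")
        lines.append(f"R-squared: {self.rsquared:.4f}")
        if np.isfinite(self.rsquared_adj):
            lines.append(f"Adjusted R-squared: {self.rsquared_adj:.4f}")
        if np.isfinite(self.wald_chi2):
            lines.append(
                f"Wald chi2({self.wald_df}): {self.wald_chi2:.2f}"
            )
        if self.dropped_terms:
            lines.append(f"Dropped (collinear/duplicate): {self.dropped_terms}")
        show = [c for c in self.params.index if not _is_dummy(c)]
        lines.append("")
        lines.append(self.to_frame().loc[show].to_string(float_format=lambda v: f"{v: .4f}"))
        n_dummies = len(self.params) - len(show)
        if n_dummies:
            lines.append(f"(+ {n_dummies} fixed-effect dummies not shown)")
        return "\n".join(lines)


def _is_dummy(name: str) -> bool:
    return name.startswith("year_") or name.startswith("country_")


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


class PraisWinstenPCSE:
    """Prais-Winsten panel model with panel-corrected standard errors.

    Parameters
    ----------
    panel
        The :class:`PanelDataset` holding the long country-year table.
    spec
        The :class:`ModelSpec` naming response, regressors, fixed effects
        and the missing-data handling for the contemporaneous covariance.

    Examples
    --------
    >>> model = PraisWinstenPCSE.from_dataframe(
    ...     frame, response="under5_mortality",
    ...     regressors=("integration", "nem", "prod_so2", "fertility",
    ...                 "health_expenditure", "urbanization"),
    ...     fixed_effects=("year",))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, panel: PanelDataset, spec: ModelSpec):
        self.panel = panel
        self.spec = spec
        self.design = build_design(panel, spec)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        response: str,
        regressors: Sequence[str],
        fixed_effects: Sequence[str] = (),
        missing_handling: str = "pairwise",
        log_vars: Iterable[str] = DEFAULT_LOG_VARS,
    ) -> "PraisWinstenPCSE":
        panel = PanelDataset(frame, log_vars=log_vars)
        spec = ModelSpec(
            response=response,
            regressors=tuple(regressors),
            fixed_effects=tuple(fixed_effects),
            missing_handling=missing_handling,
        )
        return cls(panel, spec)

    def fit(
        self,
        rho: float | None = None,
        iterate: bool = False,
        max_rho_iter: int = 50,
        rho_tol: float = 1e-8,
        cov_type: str = "pcse",
    ) -> PanelResults:
        """Run the full estimation pipeline.

        ``rho=None`` estimates the common AR(1) coefficient from pooled-OLS
        residuals (one step by default; ``iterate=True`` re-estimates until
        convergence).  ``cov_type='classical'`` replaces the PCSE sandwich
        with the homoskedastic OLS covariance ``s^2 (X'X)^-1`` -- the
        degenerate setting under which the estimator collapses to textbook
        OLS.
        """
        d = self.design
        X = d.X.to_numpy(dtype=float)
        names = list(d.X.columns)
        n, k = X.shape
        if n <= k:
            raise PanelError(f"too few estimation rows ({n}) for {k} parameters")

        if rho is None:
            beta0 = _ols(d.y, X)
            resid0 = d.y - X @ beta0
            rho_hat = estimate_rho(resid0, d.countries, d.years)
            if iterate:
                for _ in range(max_rho_iter):
                    yt, Xt = prais_winsten_transform(
                        d.y, X, d.countries, d.years, rho_hat
                    )
                    beta = _ols(yt, Xt)
                    resid_orig = d.y - X @ beta
                    new_rho = estimate_rho(resid_orig, d.countries, d.years)
                    if abs(new_rho - rho_hat) < rho_tol:
                        rho_hat = new_rho
                        break
                    rho_hat = new_rho
        else:
            rho_hat = float(rho)

        yt, Xt = prais_winsten_transform(d.y, X, d.countries, d.years, rho_hat)
        beta = _ols(yt, Xt)
        resid_t = yt - Xt @ beta

        if cov_type == "pcse":
            V = pcse_covariance(
                Xt, resid_t, d.countries, d.years, self.spec.missing_handling
            )
        elif cov_type == "classical":
            s2 = float(resid_t @ resid_t) / (n - k)
            V = s2 * np.linalg.inv(Xt.T @ Xt)
        else:
            raise PanelError(f"unknown cov_type '{cov_type}'")

        bse = np.sqrt(np.diag(V))
        if not np.all(np.isfinite(bse)):
            raise PanelError("non-finite standard error in PCSE covariance")
        zvals = beta / bse
        pvals = 2 * stats.norm.sf(np.abs(zvals))

        sst = float(((yt - yt.mean()) ** 2).sum())
        ssr = float(resid_t @ resid_t)
        rsq = 1.0 - ssr / sst if sst > 0 else np.nan

        sub_idx = [names.index(s) for s in d.substantive]
        if sub_idx:
            b_sub = beta[sub_idx]
            V_sub = V[np.ix_(sub_idx, sub_idx)]
            try:
                wald = float(b_sub @ np.linalg.solve(V_sub, b_sub))
            except np.linalg.LinAlgError:
                wald = float(b_sub @ np.linalg.pinv(V_sub) @ b_sub)
                warnings.warn("singular Wald covariance; pseudo-inverse used", stacklevel=2)
        else:
            wald = np.nan

        idx = pd.Index(names)
        return PanelResults(
            params=pd.Series(beta, index=idx, name="coefficient"),
            bse=pd.Series(bse, index=idx, name="pcse"),
            zvalues=pd.Series(zvals, index=idx, name="z"),
            pvalues=pd.Series(pvals, index=idx, name="p"),
            cov_params=pd.DataFrame(V, index=idx, columns=idx),
            rho=rho_hat,
            rsquared=rsq,
            wald_chi2=wald,
            wald_df=len(sub_idx),
            nobs=n,
            substantive=list(d.substantive),
            dropped_terms=list(d.dropped_terms),
            estimator="prais_winsten_pcse",
            spec=self.spec,
        )


def fit(panel: PanelDataset, spec: ModelSpec, **fit_kw) -> PanelResults:
    """Dispatch on ``spec.estimator``."""
    if spec.estimator == "listwise_ols":
        return fit_listwise_ols(panel, spec)
    return PraisWinstenPCSE(panel, spec).fit(**fit_kw)


def fit_listwise_ols(panel: PanelDataset, spec: ModelSpec) -> PanelResults:
    """Listwise-deletion OLS with classical standard errors.

    The robustness variant: rows with any missing value among the model's
    variables are excluded, and conventional t statistics and adjusted
    R-squared are reported.
    """
    import statsmodels.api as sm

    d = build_design(panel, spec)
    res = sm.OLS(d.y, d.X).fit()
    idx = pd.Index(d.X.columns)
    return PanelResults(
        params=pd.Series(res.params.to_numpy(), index=idx, name="coefficient"),
        bse=pd.Series(res.bse.to_numpy(), index=idx, name="std_err"),
        zvalues=pd.Series(res.tvalues.to_numpy(), index=idx, name="t"),
        pvalues=pd.Series(res.pvalues.to_numpy(), index=idx, name="p"),
        cov_params=pd.DataFrame(
            res.cov_params().to_numpy(), index=idx, columns=idx
        ),
        rho=np.nan,
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        wald_chi2=np.nan,
        wald_df=0,
        nobs=int(res.nobs),
        substantive=list(d.substantive),
        dropped_terms=list(d.dropped_terms),
        estimator="listwise_ols",
        spec=spec,
    )


def descriptive_stats(panel: PanelDataset) -> pd.DataFrame:
    """Per-variable mean, SD and observation count on the model scale.

    Log-registered variables are summarized after the log transform,
    matching how they enter the regressions.  All-missing variables report
    a count of 0 and missing moments.
    """
    rows = []
    for var in panel.variables:
        vals = panel.transformed(var).dropna()
        rows.append(
            {
                "variable": var,
                "logged": var in panel.log_vars,
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "n_obs": int(len(vals)),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
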