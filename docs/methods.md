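# Methods

`ecotrade` chains three pieces of machinery over a multi-regional
input-output (MRIO) trade system and validates all of them against a
synthetic world with fully known ground truth.  This note documents the
models, the generator, the numerical choices, and what the tests do and do
not establish.

## 1. Environmentally-extended input-output accounting

One year's system consists of the inter-industry flow matrix `Z`
(country-sector × country-sector, monetary units), final demand `Y`
(country-sector × consuming country), value added per sector, and an SO2
satellite vector (physical units, Gg) aligned to the sector axis.  Axis
order is countries-major, sectors-minor everywhere.

Gross output is the accounting identity `x = Z·1 + Y·1`.  The
technical-coefficient matrix is `A = Z diag(x)^-1` (columns of zero-output
sectors are zeroed; a sector that emits SO2 while producing nothing is an
error, not a silent zero — it indicates corrupted data).  The Leontief
inverse `L = (I − A)^-1` is computed by a dense LU solve of `(I − A) X = I`
and validated against `L(I − A) = I` at 1e-10; the equivalent Neumann
series `Σ A^k` is retained purely as an independent test oracle.  A
spectral radius of `A` at or above 1 (a non-productive economy) raises an
error naming the offending modulus.

Production-based SO2 per country sums the satellite over the country's
sectors.  Consumption-based SO2 applies direct intensities `q = so2 / x`
to the gross outputs triggered by a country's final demand:
`cons_c = q' L Y[:,c]`.  When `Y` spans all final use, the consumption
totals conserve the global production total; the test suite checks this at
1e-8 relative on every generated system.

Shares are computed per year over the countries present in that year:
`%SO2_c` of global production-based SO2 and `%VA_c` of global value added,
each summing to 100.  The normalized efficiency measure is
`NEM_c = %SO2_c / %VA_c`, so the value-added-weighted mean of NEM is
exactly 1 (`Σ NEM_c · %VA_c = 100`) — an identity the tests assert at
1e-9.  Value added is defined from the accounts as gross output minus
intermediate purchases (column sums of `Z`); an alternative GDP-based
denominator would change levels but not the identity.

## 2. Trade network and continuous core/periphery scores

All sectors are aggregated into one directed country-by-country trade
matrix (exporter rows, importer columns); cross-border final-demand
purchases are included by default (`include_final_demand=True`, switchable)
because the bilateral relation of interest is total trade, not only
intermediate trade.  Domestic flows are excluded: the network model
ignores self-ties.  The matrix is added to its transpose — keeping the
structure of trade rather than its direction — and an elementwise square
root tames the heavy right skew of trade volumes.

The continuous core/periphery model seeks nonnegative scores `c` such that
expected tie strength is the product of endpoint scores, minimizing the
diagonal-ignoring least squares `Σ_{i≠j} (W_ij − c_i c_j)²` (MINRES).  The
optimizer is coordinate descent: the update
`c_i ← Σ_{j≠i} W_ij c_j / Σ_{j≠i} c_j²` is the exact one-dimensional
minimizer, so the objective is non-increasing across sweeps (asserted in
tests).  Initialization is the absolute leading eigenvector of `W` scaled
by the square root of its eigenvalue, sign-flipped so its sum is
nonnegative.  Convergence is declared when the relative objective drop per
sweep falls below `tol` (default 1e-10, max 10 000 sweeps); non-convergence
returns a flagged result rather than raising.

Scores are max-normalized to [0, 1] — the simplest map achieving the
conventional score range while preserving ratios; the unnormalized vector
is also reported.  Under `W → kW` the unnormalized solution scales by √k,
so normalized scores and the fit correlation (Pearson r between
off-diagonal `W_ij` and `c_i c_j`) are scale-invariant.  The per-year
scores are reported as the country's *integration* in world trade.

Not implemented by design: discrete core/periphery partitions, multi-core
block models, and directed coreness.

## 3. Prais-Winsten estimation with panel-corrected standard errors

The country-year panel keys rows by (country, year); within each country
the year index is made contiguous at construction so that gaps are visible
to the transform.  A log-transform registry records which variables enter
models in natural logs (both SO2 measures, integration, NEM, population,
both mortality rates, fertility); urbanization (% urban) and health
expenditure (% of GDP) enter in levels.  Values that are nonpositive but
registered for a log become missing with a counted warning rather than
being offset — adding a constant inside a log silently changes every
elasticity.

Estimation of a specification (response, regressors, optional year and/or
country dummies with one reference level dropped) proceeds:

1. **Design screening.**  Complete-case rows only (a row missing the
   response or any regressor cannot enter the normal equations);
   duplicate regressors and collinear columns are dropped and reported —
   country dummies on near-time-invariant regressors routinely trigger
   this.  Rank is checked by QR.
2. **Pooled OLS** for initial residuals.
3. **Common AR(1) coefficient** pooled over every within-country pair of
   consecutive observed years, `ρ̂ = Σ e_t e_{t−1} / Σ e_{t−1}²`, clamped
   to (−0.999, 0.999) with a warning.  One step by default (an
   `iterate=True` flag re-estimates to convergence); iterating changed
   nothing material in calibration runs.
4. **Prais-Winsten transform.**  The first observation of each
   within-country run of consecutive years is scaled by `√(1−ρ²)` rather
   than dropped; later observations are quasi-differenced.  A gap restarts
   the first-observation rule.  The constant and all dummies are
   transformed like any other column.
5. **OLS on the transformed data**; the reported R² is from this
   transformed regression.
6. **PCSE sandwich.**  The cross-country contemporaneous covariance is
   estimated entrywise from transformed residuals,
   `Σ̂_ij = Σ_t e_{i,t} e_{j,t} / n_ij`, where under *pairwise* handling
   `n_ij` counts the years both panels are observed (maximizing the usable
   observations of an unbalanced panel) and under *listwise* only jointly
   observed years enter.  Country pairs that never overlap get covariance
   0 with a warning.  The coefficient covariance is
   `(X'X)^-1 X' Ω X (X'X)^-1` with `Ω` block-diagonal by year.

Pairwise denominators can break positive semidefiniteness of `Σ̂`; its
negative eigenvalues are clipped (projection onto the PSD cone) with a
warning so that no sandwich variance can go negative.  The Wald χ²
statistic `b'V^-1 b` covers the substantive regressors only — not the
intercept or fixed-effect dummies.

The robustness variant is listwise-deletion OLS with classical standard
errors and adjusted R², fitted through `statsmodels`.  Forcing ρ = 0 and a
homoskedastic diagonal covariance reduces the full pipeline to textbook
OLS, coefficient and standard errors alike, to 1e-10 — the degenerate
equivalence the tests assert.

### Calibration caveat

With the number of panels exceeding the number of years (here 40 > 21) and
highly persistent regressors, the plug-in `Σ̂` makes PCSE mildly
optimistic: in specifications without time dummies the fitted model
absorbs roughly k/T of the cross-sectionally correlated error, and
measured 95% coverage drops to ≈0.87 even when the true ρ is supplied —
while the same sandwich evaluated at the *true* contemporaneous covariance
is exactly nominal.  Including year dummies absorbs the common year shock
and restores near-nominal coverage (≈0.97 measured).  The recovery study
therefore fits the mortality specification with year fixed effects — the
same specification the default roster uses — and the caveat stands as a
known limitation for specifications without time effects.

## 4. The synthetic world

The generator is the package's test bed: it emulates the *structure* of a
multi-country trade and mortality panel with every parameter known, so
that each downstream stage has a recovery target.  Defaults mirror the
study window at desk scale: 30 countries × 4 sectors × 21 years (1990–2010),
a quarter of countries in the core class.

**Trade.**  Countries receive a latent size (core countries roughly an
order of magnitude larger, lognormal within class) and sizes drift by a
small per-country growth rate.  Bilateral weight follows a gravity rule,
`(size_i · size_j)^γ` with `γ = gravity_exponent` (default 1), with a 4×
home bias on domestic flows.  One year's accounts are built from the
technology side out: the coefficient matrix `A` is drawn with column sums
uniform in (0.3, 0.6) — so the spectral radius is below 1 and value added
nonnegative *by construction* — final demand allocates `trade_scale ×
size_d` over suppliers by gravity, and then `x = (I−A)^-1 Y·1`,
`Z = A diag(x)`.  The balance identity is exact, not approximate.  SO2
intensity per sector scales as `size^emission_elasticity` (default 0.3:
larger, core countries are dirtier per unit output, which is what makes
the pollution-wealth ratio vary with integration) times lognormal noise.

**Panel.**  Covariates follow linear per-country trends plus bounded
noise: population grows 2%/year from a size-linked base; urbanization
trends up 0.4 points/year, clamped to [0, 100]; fertility declines slowly
with a floor at 0.5; health expenditure is clamped to [0.5, 15] % of GDP.
Core countries start more urban, less fertile and higher-spending.
Log-mortality (under-1 and under-5, per 1000 live births) is the linear
combination of log integration, log NEM, log production SO2, log
fertility, health expenditure and urbanization with the planted
coefficients (defaults: −0.4, 0.05, 0.02, 1.2, −0.034, −0.016, intercept
2.0, under-5 shifted +0.3), plus an error with innovation sd 0.3 that is
AR(1) within country (default ρ = 0.5, stationary start) and exchangeably
correlated across countries within a year (default 0.3, via a common year
factor).  A missing-at-random mask (default rate 0.1, independent per
cell and variable) is applied to the attribute and mortality columns only
— in real data of this kind the unbalancedness comes from the statistical
covariates, while the MRIO-derived series are complete for covered
countries.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: actual sector taxonomies and price concepts;
measurement error in emissions inventories; missingness that is informative
(correlated with development); structural breaks, wars, or re-basing of
national accounts; and any causal structure — the mortality equation is a
planted *association* in the spirit of the reproduced design, so parameter
recovery demonstrates estimator correctness, not epidemiological truth.

## 5. Reproducibility and problem sizes

Every random draw derives from a single integer seed through independent
named streams (world parameters, per-year technology, covariates, errors,
missingness), so equal configurations are bit-identical; the pipeline's
numeric outputs are byte-identical across reruns under one seed, and the
provenance block records a config hash.  The test suite and the
acceptance script use desk-scale problems chosen to exercise every code
path while keeping the whole suite fast: Leontief oracles on systems up to
30 sectors, core/periphery grid-search oracles on 4-node networks (the
0.05-grid has 194 481 candidates), planted-partition detection across 100
seeded 30-country worlds, and a 500-replicate recovery study at 40
countries × 21 years for the panel estimator, with 200 further replicates
at contemporaneous correlation 0.7 for the PCSE-versus-OLS coverage
contrast.
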