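# ecotrade

Who pollutes, who pays, and where does each country sit in world trade?
`ecotrade` implements, as one tested pipeline, the computational chain used
to study how integration in the global trade network relates to
sulfur-dioxide emissions and to infant/child mortality across countries:

1. **MRIO accounting** — from a multi-regional input-output system
   (inter-industry flows `Z`, final demand `Y`, value added, and an SO2
   satellite), compute the Leontief inverse `L = (I − A)⁻¹` with
   `A = Z diag(x)⁻¹`, production-based SO2 (emitted within borders) and
   consumption-based SO2 (`q′ L Y[:,c]`, the footprint triggered by country
   *c*'s final demand), each country's share of global SO2 (%SO2) and of
   global value added (%VA), and the normalized efficiency measure
   **NEM = %SO2 / %VA** — above 1 means a larger share of world pollution
   than of world income.
2. **Trade-network integration** — aggregate all sectors to a
   country-by-country trade matrix, symmetrize (`T + T′`), take elementwise
   square roots, and fit the continuous core/periphery model: nonnegative
   scores `c` minimizing `Σ_{i≠j} (W_ij − c_i c_j)²`, max-normalized to
   [0, 1].  High scores mark countries at the core of world trade.
3. **Panel estimation** — Prais-Winsten regression for a common AR(1)
   disturbance (`ρ` pooled over within-country consecutive-year pairs,
   first observations kept and scaled by `√(1−ρ²)`) with panel-corrected
   standard errors (`(X′X)⁻¹ X′ Ω X (X′X)⁻¹`, contemporaneous cross-country
   covariance estimated pairwise on unbalanced panels), plus a
   listwise-deletion OLS robustness variant.

A synthetic-data generator plants a gravity-style core/periphery trade
structure and a known linear-in-logs mortality process, so every stage has
a recovery target; real MRIO tables and country panels can be ingested
from CSV instead.

## Worked example

```python
import ecotrade as et

cfg = et.SyntheticConfig(n_countries=12, n_sectors=3, n_years=6, seed=42)
systems = et.generate_mrio_series(cfg)
print(et.footprint_accounts(systems[0]).round(2).head())
```

```
         year  prod_so2  cons_so2  value_added  share_so2  share_va   nem
country
C000     1990    516.46   1308.52       598.11       0.92      1.88  0.49
C001     1990    550.83   1400.31       709.99       0.98      2.24  0.44
C002     1990   1028.01   1918.91      1040.16       1.83      3.28  0.56
C003     1990   7393.35   8697.22      4931.19      13.18     15.54  0.85
C004     1990  18089.19  13985.29      8479.56      32.24     26.72  1.21
```

C004 emits 32% of world SO2 but earns only 27% of world value added
(NEM = 1.21: more pollution than wealth); C000's footprint (1309 Gg) is
over twice its territorial emissions (516 Gg) — it imports embodied
pollution.  Regressing log production SO2 on log integration with year
effects:

```python
fp = et.footprint_series(systems)
integ = et.integration_series(systems)
panel, truth = et.generate_panel(cfg, fp, integ)
model = et.PraisWinstenPCSE(
    panel,
    et.ModelSpec("prod_so2", ("integration", "population", "urbanization"),
                 ("year",)),
)
print(model.fit().summary())
```

```
Prais-Winsten with panel-corrected standard errors
==================================================
Response: prod_so2    Fixed effects: year
Observations: 51
Common AR(1) rho: -0.4185
R-squared: 0.9980
Wald chi2(3): 14954.37

              coefficient  std_err        z  p_value
const              9.7769   0.2539  38.5058   0.0000
integration        3.1478   0.1178  26.7124   0.0000
population        -0.0183   0.0642  -0.2855   0.7752
urbanization       0.0011   0.0013   0.8032   0.4218
(+ 5 fixed-effect dummies not shown)
```

The integration elasticity (3.15, z = 26.7) recovers the planted positive
association between coreness and emissions in this synthetic world: a 1%
higher integration score goes with ~3% higher SO2.

The same chain runs from a shell:

```sh
ecotrade simulate --out sim/                 # MRIO CSVs + panel + ground truth
ecotrade footprint --mrio-dir sim/mrio --out footprints.csv
ecotrade coreness  --mrio-dir sim/mrio --out integration.csv
ecotrade run-all   --seed 1 --out results/   # everything incl. regressions
```

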