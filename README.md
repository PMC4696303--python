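# saltmod

Community-level sodium and iodine intake assessment from store-sales data,
and simulation of salt-reduction strategies with iodine coupling.

## The problem

In remote communities where a single store is the main food source,
store-sales records ("apparent consumption") give an objective, low-burden
measure of what a whole community eats over long periods. Two public-health
questions collide there:

* **Sodium** intakes far above recommendations drive hypertension,
  cardiovascular disease and chronic kidney disease, so salt-reduction
  strategies (reformulation of processed foods, reduced discretionary salt
  use) are a priority.
* **Iodine** deficiency is prevented largely through iodised salt — both
  the table salt people buy and the mandatory iodised salt in bread. Any
  strategy that removes salt also removes iodine.

`saltmod` implements the full analysis pipeline for this trade-off:

1. **Apparent consumption** — link sales records (store, week, product,
   weight) to a food-composition table (per-100 g energy, sodium, iodine),
   screen outlying event weeks with a robust-z rule, and compute pooled and
   per-store nutrient *densities*: sodium mg/MJ and iodine μg/MJ of
   purchased energy. Density is the scale-free quantity sales data measure
   directly — it does not require knowing how many people ate the food.
2. **Population-weighted requirements** — weight the 2006 Australian/NZ
   Nutrient Reference Values (sodium AI midpoint and UL; iodine RDI, EAR
   and UL) by the community's age/gender distribution, including fractional
   reallocation of women 19–50 to pregnancy/lactation reference values from
   the birth rate. The population-weighted estimated energy requirement
   (EER) is Schofield BMR × physical activity level 1.6 at reference
   weights (BMI 22 at 1.70 m men / 1.60 m women for adults).
3. **Adequacy** — estimated average intake = density × weighted EER
   (what the average person meeting their energy requirement would
   consume), reported as percent of each recommendation on per-day and
   per-MJ bases.
4. **Scenario modelling** — reduce the sodium of target categories by a
   fraction *r*; iodine riding on iodisable salt scales away with it
   (fully for discretionary salt and bread, a configurable salt-derived
   fraction for other processed foods). Post-scenario intake is affine in
   *r*, so the minimal reduction reaching the sodium UL has the closed
   form *r\** = (Na<sub>total</sub> − UL) / Na<sub>targeted</sub>, cross-checked
   by an independent bisection solver.
5. **Synthetic data** — a calibration-first generator emits two years of
   weekly sales for 20 stores (~8300 people) whose pooled densities,
   category shares and iodised-salt profile match the published study
   conditions exactly, with realistic between-store and week-to-week
   variation and injectable event-week outliers, plus the matching
   demography and composition tables. Ground truth is bookkept so every
   pipeline stage can be tested for exact parameter recovery.

## Worked example

```bash
saltmod simulate --out-dir fixture --seed 3
saltmod assess    --sales fixture/sales.csv --composition fixture/composition.csv \
                  --demography fixture/demography.csv --out-dir assess
saltmod scenarios --sales fixture/sales.csv --composition fixture/composition.csv \
                  --demography fixture/demography.csv --out-dir scen
```

`assess` prints the adequacy table (per-day values to integers, per-MJ to
one decimal, store ranges in the min/max columns):

```
nutrient reference  density_per_mj  intake_per_day  nrv_per_mj  nrv_per_day  pct_per_mj  pct_per_day  intake_per_day_min  intake_per_day_max
  sodium        AI           311.0            2774        70.0          624         444          444                2434                3419
  sodium        UL           311.0            2774       232.5         2074         134          134                2434                3419
  iodine        UL            23.1             206        97.5          870          24           24                 173                 254
  iodine       RDI            23.1             206        15.7          140         147          147                 173                 254
  iodine       EAR            23.1             206        10.5           94         219          219                 173                 254
```

Reading it: purchased food carries 311.0 mg sodium per MJ, so the average
person meeting the 8.92 MJ/day weighted EER consumes ~2774 mg sodium —
134% of the population-weighted upper limit (2074 mg) and 444% of the
adequate-intake midpoint. Iodine (206 μg/day) sits comfortably between the
EAR (94 μg, 219%) and the upper limit (870 μg, 24%). Two event weeks (both
in one store) are flagged and excluded; 71.7% of discretionary salt is
iodised by weight.

`scenarios` reports each canonical scenario at full reduction and the
minimal reduction *r\** reaching the UL:

| scenario | targets | Na at r=1 (mg/d) | I at r=1 (μg/d) | r* | I at r* (μg/d) |
|---|---|---|---|---|---|
| 1 | discretionary salt | 2244 | 162 | infeasible | — |
| 2 | bread | 2264 | 135 | infeasible | — |
| 3 | salt + bread | 1734 | 91 | 0.673 | 128 |
| 4 | all processed foods | 903 | 124 | 0.374 | 175 |
| 5 | salt + all processed | 373 | 80 | 0.292 | 169 |

Neither reduced discretionary salt nor bread reformulation alone can bring
sodium under the UL, but their combination does at a 67% reduction — and in
every scenario at its minimal reduction, iodine stays above the 94 μg/day
EAR. That is the analysis' central safety finding: salt reduction and
iodine-deficiency prevention are compatible in this setting.

## Layout

| module | role |
|---|---|
| `saltmod.composition` | composition-table I/O, validation, sales linkage |
| `saltmod.consumption` | aggregation, densities, source attribution, outlier screen, salt profile |
| `saltmod.requirements` | Schofield EERs, pregnancy/lactation fractions, NRV weighting |
| `saltmod.adequacy` | intake estimates and percent-of-recommendation reports |
| `saltmod.scenarios` | scenario engine, iodine coupling, minimal-reduction solvers |
| `saltmod.synthetic` | calibrated generator for sales/composition/demography + ground truth |
| `saltmod.cli` | `saltmod simulate / assess / scenarios` |

See `docs/methods.md` for the model, calibration details, numerical
choices and limitations.
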