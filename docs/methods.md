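# Methods

This note documents the models, calibration choices and numerical
conventions behind `saltmod`, and what the synthetic study does and does
not establish about real data.

## Apparent consumption

A sales record is (store, week, product, quantity, total weight in grams).
Linking multiplies weight/100 by the product's per-100 g energy (kJ),
sodium (mg) and iodine (μg); the composition table always stores sodium,
never salt, so the ×0.4 salt-to-sodium conversion never appears in the
pipeline. Records whose product is missing from the table are excluded and
counted; linkage fails when the unmatched share of total purchased weight
exceeds a configurable limit (default 1%). Nutrient totals are additive
over any partition of records and linear in record weight — both are
property-tested.

Densities (sodium mg/MJ, iodine μg/MJ of purchased energy) are the primary
estimands: they are invariant to uniform scaling of all purchases, so they
do not depend on knowing the eating population, only on the composition of
what was bought.

**Outlier weeks.** Event weeks (funerals, festivals, influxes of visitors)
make store sales unrepresentative of usual intake. The screen computes,
per store, the robust z-score |x − median| / (1.4826 × MAD) of weekly
purchased energy and flags weeks exceeding a threshold (default 4.0). When
MAD is zero the rule degenerates gracefully to flagging exact deviants
from the median. A store needs at least 8 weeks for the screen to run.
The original identification of such weeks in practice is contextual; the
robust-z rule is this package's reproducible, automatable equivalent, and
a user-supplied exclusion list can represent genuinely contextual
knowledge.

**Source attribution.** Category shares of each nutrient are computed at
any taxonomy level (major / sub-major / minor); shares at a complete level
sum to 100% and a sub-major share equals the sum of its minors. The
per-100 g column is the weight-weighted mean content of the category's
purchased weight (nutrient total ÷ purchased weight × 100) — the natural
quantity sales data produce; an unweighted product mean would ignore what
people actually bought.

## Population-weighted requirements

Reference values are the 2006 Australian/New Zealand NRVs, bundled as a
versioned CSV (any same-shaped table can be substituted). Weighting is the
count-weighted mean over age/gender cells; values undefined for a band
(no sodium UL or iodine EAR/UL for infants) are averaged over the cells
where they are defined. The sodium AI enters as the midpoint of its range.

EER = Schofield BMR × PAL. Defaults: PAL 1.6 ("sedentary"), adult
reference weight BMI 22 × height² with heights 1.70 m (men) and 1.60 m
(women); child/adolescent bands use bundled reference weights. The
Schofield coefficient table ships as a data file so another BMR family can
be swapped in. Children's EER carries an optional growth allowance
(default 0 — at these ages the growth term is ~1–2% of EER and the PAL
uncertainty dominates).

Pregnancy and lactation: with B births/year among W women aged 19–50, a
fraction B·(gestation/52)/W of those women is pregnant and B·(lactation
months/12)/W is lactating at any time (defaults 40 weeks and 6 months,
clipped to [0,1]). Those fractions are reallocated to pregnancy/lactation
NRV rows, which also carry EER offsets (+1.4 and +2.0 MJ/day).

Internal computation is full precision; reports round per-day values to
integers and per-MJ values to one decimal. Percent-of-recommendation is
emitted on both the per-day and per-MJ basis, explicitly labelled: the two
agree exactly before rounding, but published tables sometimes mix bases
after rounding, so both are shown.

## Scenario engine

A baseline profile holds each sub-major category's per-day sodium and
iodine contributions (category share × estimated intake) plus the
population-weighted UL and EAR. A scenario reduces targeted categories'
sodium by a single fraction r; coupled iodine scales identically:

    Na(r) = Na_total − r · Σ_targets Na_c
    I(r)  = I_total  − r · Σ_targets f_c · I_c

where f_c is the salt-derived fraction of category c's iodine:
1.0 for discretionary salt (its iodine is the fortificant itself) and for
bread (mandatory iodised-salt fortification), 0.4 by default for other
processed foods, 0 elsewhere (milk and egg iodine is not salt-borne). The
0.4 default is a calibration: it is the value under which the simulated
wide-reformulation scenarios reproduce the published post-scenario iodine
intakes, and it is overridable per category for sensitivity analysis.

Because intake is affine in r, the minimal reduction reaching a sodium
limit is closed-form: r* = (Na_total − limit)/Σ Na_targets, clipped to
[0,1], with an infeasibility report (residual excess at r = 1) when even
full reduction is insufficient. An independent bisection solver over the
forward engine (scipy bisect, xtol 1e-12) is kept as a cross-check; the
two agree to <1e-9 on randomized baselines in the test suite. Targets
within a scenario must be disjoint — overlapping category sets raise
rather than double-count.

The five canonical scenarios are: (1) discretionary salt; (2) bread;
(3) = 1+2; (4) all processed foods; (5) = 1+4. "All processed foods" is a
shipped default list of sub-major codes (breads, processed meats,
preserved fruit, cereal-based dishes, pastries, sauces, noodles, soft
drinks, other processed) excluding fresh produce, plain meat, plain dairy,
eggs and discretionary salt itself. Incremental grids (default 10/25/50%)
evaluate any scenario on a fraction ladder.

## Synthetic study

The generator's defaults are the study conditions: 20 stores × 104 weeks,
415 persons/store (8300 total), pooled sodium density 311.0 mg/MJ, iodine
23.1 μg/MJ, category sodium shares led by discretionary salt 19.1%, bread
18.4% and processed meat 9.0% (46.5% jointly), bread carrying 34.4% and
iodised salt 21.5% of iodine, 71.7% of salt weight iodised, and two
injected event weeks in one store.

**Calibration.** Product sodium targets follow from category shares and
fixed within-category splits; purchase weight per MJ is sodium over
per-100 g content. Two closure steps make the system exactly consistent:
the residual staples/fresh-produce category's energy density is solved so
category weights sum to 1 MJ of energy per MJ, and each category's product
iodine contents are scaled so pooled iodine shares and density hit their
targets. Per-100 g contents stay near published category means (e.g.
iodised salt 38,168 mg Na and ≈4,450 μg I per 100 g; bread ≈445 mg
Na/100 g).

**Realisation.** Weekly quantities are negative-binomial counts (size
k = 300) around store-week means composed of: store size (lognormal,
σ = 0.25), store-level category multipliers (lognormal, CV 0.15, ×3 for
salt — discretionary-salt habits vary far more between communities than
staple purchases), and a bounded store-week demand multiplier
(Beta(2,2) scaled to [0.8, 1.2]) shared by all products of a store-week.
Marginal weekly counts are therefore overdispersed, but the bounded demand
term means natural weeks cannot stray more than ~2.3 robust SD from the
store median once the MAD is estimated from a full 104-week series — so
the default robust-z screen recovers injected ≥3× event weeks exactly,
with essentially no false flags, by construction rather than by luck.
After drawing, each product's effective unit weight is rescaled once
(equivalent to adjusting pack size, constant per product) so pooled
totals over non-event weeks hit the calibration targets exactly; event
weeks are then injected by scaling their quantities. This one-pass
proportional correction replaces an iterative proportional fit — with a
single multiplicative margin per product the fixed point is reached in one
step, and integer-count noise is absorbed into the unit weights rather
than left as a residual. Exact ground truth (totals, shares,
outlier list) is bookkept from the emitted arrays.

**Demography.** The age/gender cell fractions are frozen from a dev-time
optimisation: they are chosen so that, with the bundled NRV table and the
Schofield/PAL energy model, population weighting reproduces the study's
per-MJ weighted reference values (sodium AI 70.0 and UL 231.8 mg/MJ;
iodine RDI 15.7, EAR 10.5, UL ~97 μg/MJ; EER 8.92 MJ/day). Per-MJ ratios
are the calibration targets because published per-day values are rounded
to the nearest 10. The resulting pyramid is young-skewed but is a
calibration artefact, not a census extract; the birth rate (0.034/person/
year) is likewise calibrated. Counts are integers by largest-remainder
rounding, summing exactly to the population.

**What passing tests show.** On synthetic data the pipeline recovers the
generator's targets essentially exactly, because the generator closes its
books. That validates the arithmetic and the plumbing — linkage,
aggregation, weighting, scenario algebra — not the measurement properties
of real sales data: real data bring unmatched products, composition-table
averaging error, wastage, non-store food sources, and outlier weeks that
are ambiguous rather than injected. The generator also omits seasonality,
price/promotion dynamics and product churn.

## Numerical conventions

* Robust-z threshold 4.0; MAD zero → exact-deviant fallback; ≥8 weeks
  per store required.
* Unmatched-sales failure threshold: 1% of purchased weight.
* Zero purchased energy raises an explicit undefined-density error; an
  empty aggregation group is zero totals, not an error.
* Scenario reductions are confined to [0,1]; solver cross-check tolerance
  1e-12 in r.
* All generator randomness flows from a single integer seed
  (numpy default_rng); identical seeds give byte-identical CSVs, and
  emitted files record the seed in a header comment.
* Test problem sizes: unit tests run a 6-store × 30-week simulation; the
  outlier-recovery property uses 100 replicates of 4 stores × 104 weeks
  (the full series length matters for a stable MAD); headline-reproduction
  tests run the full 20 × 104 default once per session.

## Limitations

* Population-level only: no individual intake distributions, no
  prevalence-of-deficiency estimates.
* Intake estimates assume average energy consumption equals the weighted
  EER; under food insecurity they scale accordingly.
* The iodine coupling fraction for non-bread processed foods (0.4) is a
  calibrated scalar, not a measured constant; per-category overrides are
  the intended way to explore it.
* No wastage adjustment and no non-store food sources (wild-harvest,
  municipal water).
* The scenario engine models content reduction only — it does not shift
  purchases between foods or optimise diet composition under cost
  constraints.
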