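# Methods

## Scope and data model

`ferrodiet` analyses two-day dietary diaries: one record per (individual,
survey day, food code, grams). A food composition table supplies, per
food code, the energy density (kcal/g), total iron density (mg/g), the
recipe fractions of wheat and rice (g grain per g food, label-derived in
real surveys), the wholegrain/brown shares of those grain components, and
the component iron densities of refined/wholegrain wheat and white/brown
rice. A reference schedule supplies the iron PRI (mg/day) per sex and age
range.

The unit of analysis is the individual's two-day arithmetic mean. Group
statistics (mean, sample SD with n−1, median, P5/P95 with linear
interpolation between order statistics) are reported per sex × age class
(<1, 1–2, 3–9, 10–17, 18–64, 65–74 completed years).

## Recipe decomposition

Each diary entry splits into wheat, rice and other components. Masses are
`grams × fraction`; component iron is mass times the share-weighted
component iron density; other-iron is the residual to the item total and
is clamped at zero (with a warning) if component iron exceeds item iron by
more than rounding noise — a validated table cannot trigger this. Energy
is attributed mass-proportionally: the grain component inherits the energy
density of the food carrying it. This understates grain energy relative to
a flour-equivalent accounting (cooked foods dilute energy but not the
grain mass convention), which affects only the descriptive grain-energy
summaries, not iron, adequacy or any scenario quantity.

## Reference schedule

The shipped default schedule (mg/day): infants <1 y: 11; 1–3 y: 8; 4–6 y:
11; 7–10 y: 13; males 11–14: 10, 15–17: 13, ≥18: 10; females 11–14: 10/18,
15–29: 18, 30–59: 18/10, ≥60: 10. The two split ranges carry no published
switch age; the package resolves them at 12 y (menarche proxy) and 50 y
(menopause proxy), both configurable, and validates the resolved table to
be disjoint and to cover 0–74 y per sex. Ages are completed years.
Adequacy gaps are computed per individual before any group averaging, so
mixed-PRI groups are handled correctly.

## Scenario engine

Five scenarios, all holding consumed grams and energy fixed:

| name  | grain-iron multiplier | wholegrain target | brown-rice target |
|-------|----------------------|-------------------|-------------------|
| basic | 0.8                  | unchanged         | unchanged         |
| s1    | 0.8 × 1.3            | unchanged         | unchanged         |
| s2    | 0.8                  | 0.5               | unchanged         |
| s3    | 0.8                  | unchanged         | 1.0               |
| s4    | 0.8 × 1.3            | 0.5               | 1.0               |

The 0.8 depletion encodes the projected ~20% decline of grain iron under
elevated CO₂; 1.3 encodes 30% biofortification of component iron content,
which at fixed consumption equals +30% of component iron intake. Share
shifts are upward-only (`max(s_i, target)`): individuals already above the
target keep their share. The shift is applied to component iron via the
density difference `g·(s′−s)·(ρ_high−ρ_low)` and the multipliers apply to
the shifted component; because the blend is affine in the share, the two
orderings commute (asserted in tests to 1e-12). Deltas are per-individual
scenario-minus-baseline iron, averaged per group; infants (<1 y) are
excluded from all projections. Significance uses the least significant
delta z·sd/√n computed from each group's *current-diet* iron distribution
(z = 1.96 by default; a t quantile can be substituted via the z argument),
with strict inequality.

## Statistical layer

The Kruskal–Wallis H uses mid-ranks, the tie correction
1 − Σ(t³−t)/(N³−N) and a chi-square(k−1) p-value. When all pooled values
are identical H is defined as 0 (p = 1). The implementation is
cross-checked in tests against `scipy.stats.kruskal` and against an
independent variance-of-ranks identity, H = (N−1)·SS_between/SS_total.

## Synthetic survey generator

The generator emulates the structure of the Italian national dietary
survey (IV SCAI 2017–2020), whose micro-data are unpublished: two
non-consecutive diary days at least 15 days apart, sex × age
stratification with the published group sizes (total n = 1969), uniform
geographic-area strata and season/holiday flags (metadata only; the
published analyses report no area or season effects).

Per-person latent two-day means for total iron, energy, food mass and
wheat grams are lognormal, moment-matched to the published group means and
SDs (medians below means in the published tables indicate right skew; the
lognormal is the standard choice for strictly positive intakes). The four
latents share a one-factor correlation structure (loadings 0.85 energy,
0.80 iron, 0.70 mass, 0.50 wheat): people who eat more overall eat more of
everything. This is both realistic and necessary for internal consistency
— with independent draws the residual non-grain diet occasionally demands
an implausible iron-to-energy ratio, and the non-negativity clamps then
bias group mean energy upward by about two standard errors. With the
factor structure all group means are recovered within Monte-Carlo noise
(bias below one standard error of the group mean at the published n).

Rice is zero-inflated: a Bernoulli non-consumer gate (default probability
0.25 — published tables show P5 = 0 in most groups but medians above zero,
bracketing the zero share between 5% and 50%) times a conditional
lognormal whose moments are adjusted so the unconditional mean and SD hit
the targets.

Wheat and rice grams are laid out over a fixed food list — pure flours and
raw grains, bread, cooked pasta, biscuits, pizza, cooked/raw rice, rice
salad — with fixed allocation weights, so composite foods with grain
fractions strictly inside (0, 1) dominate and the decomposition step is
exercised non-trivially. Baseline wholegrain and brown-rice shares default
to 0.08 and 0.05 (wholegrain consumption in Italy is low). The iron and
energy not supplied by grain foods are filled by two aggregates (a
meat/fish/legumes pool at 0.025 mg Fe/g, 1.8 kcal/g and a
plant/dairy pool at 0.0005 mg Fe/g, 1.0 kcal/g) solved as a 2×2 linear
system per person; when the residual mix falls outside the bracket the
iron target takes priority. Water tops up total mass. Day totals are the
latent mean times (1 ± δ), δ ~ N(0, 0.3) truncated to (−0.95, 0.95) per
component group (with rice placed on a single day for 35% of consumers),
so the two-day mean is preserved exactly.

Component iron densities default to refined wheat 0.012, wholegrain wheat
0.024, white rice 0.006, brown rice 0.012 mg/g (wholegrain:refined ratio
2). These are calibration choices, not measured values: combined with the
published group mean wheat/rice grams they reproduce the published
wheat- and rice-attributed iron means (e.g. adolescent males: 163.1 g/day
× 0.01296 mg/g ≈ 2.1 mg/day wheat iron), and the ratio of 2 puts the
wholegrain-shift scenario in the published 0.2–0.8 mg/day range. All four
are configuration fields.

What the generator does **not** emulate: true day-of-week/season effects,
correlated food choices beyond the one-factor structure, under/over-
reporting, supplements, infant weaning foods (infants are ordinary diaries
with small amounts, and are excluded from scenarios anyway), and any
real-food heterogeneity in component densities (densities are uniform
across foods). Passing calibration tests therefore demonstrates that the
pipeline recovers the group-level structure it is fed, not that it would
reproduce person-level features of the real survey.

## Numerical and design choices

- Percentiles: NumPy's default linear interpolation ("type 7").
- Sample SD uses n−1; SD of a single observation is reported as 0.
- Individuals with zero energy on both days are retained with missing
  (NaN) iron density rather than dropped.
- Cereal-contribution percentages are ratio-of-group-means (headline) with
  mean-of-individual-ratios emitted alongside.
- The ~9 kcal/day whole-sample rice energy sometimes quoted for such
  surveys is inconsistent with the published table mean (59.7 kcal/day);
  the package reports the table-style mean and does not attempt the former.
- Published 65–74 half-widths (1.17 / 0.67 mg/day) do not equal z·sd/√n of
  the same tables' SD and n (≈1.12 / 0.64); the package computes the
  formula value and documents the discrepancy rather than reproducing it.
- Problem sizes: tests run cohorts of 8–380 individuals per cell; the
  acceptance script runs the full 1969-person cohort; the Monte-Carlo
  checks use 100 seeds (calibration coverage) and 2000 replicates
  (rank-test type-I error). A full run completes in seconds.

## File formats

All I/O is UTF-8 CSV with a header row and '.' decimals.

- `individuals.csv`: individual_id, sex, age_class, age_years, area,
  day1_date, day2_date, day1_holiday, day2_holiday.
- `diaries.csv`: individual_id, day_index (1|2), food_code, grams.
- `composition.csv`: food_code, category, energy_density, iron_density,
  wheat_fraction, rice_fraction, wholegrain_share, brown_share,
  iron_density_wheat_refined, iron_density_wheat_whole,
  iron_density_rice_white, iron_density_rice_brown.
- `pri_schedule.csv`: sex, age_min_years, age_max_years, pri_mg_day.
- Survey/run configuration: flat YAML (`seed` mandatory; optional
  `rice_zero_prob`, `wholegrain_share0`, `brown_share0`,
  `within_person_cv`, `densities`, `groups`, `scenarios`, `z_value`).
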