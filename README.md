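# ferrodiet

Dietary iron intake estimation, adequacy assessment and biofortification
scenario projection from two-day food diaries, for nutrition researchers and
public-health analysts studying grain-derived iron.

Cereals carry a large share of dietary iron in Mediterranean diets, and the
iron concentration of wheat and rice grains is projected to fall by roughly
20% under elevated atmospheric CO₂. `ferrodiet` quantifies what that means
for a population's iron adequacy and how far corrective actions —
biofortified grain, a shift to wholegrain wheat or brown rice — can recover
it, using individual-level dietary survey data (or a calibrated synthetic
stand-in when the survey micro-data are not available).

## The model

For individual *i*, intake is the arithmetic mean over two non-consecutive
diary days of per-food contributions. Each consumed food *f* with mass
*g*<sub>if</sub> decomposes through its recipe fractions into wheat, rice
and other components; the wheat-attributed iron is

    Fe_w(i) = Σ_f g_if · w_f · [ s_f ρ_whole + (1 − s_f) ρ_refined ]

where *w<sub>f</sub>* is grams of wheat per gram of food, *s<sub>f</sub>*
its wholegrain share, and ρ the component iron densities (mg/g); rice is
analogous with white/brown densities, and "other" iron is the residual to
the food's total. Adequacy is judged per person against the sex- and
age-specific Population Reference Intake (PRI) schedule; the gap
Fe(i) − PRI(i) is negative when intake is inadequate.

Scenarios hold consumption constant and rescale component iron:

    Fe_w'(i) = [ Fe_w(i) + g_w(i) (max(s_i, s*) − s_i)(ρ_whole − ρ_refined) ] · d · b

with depletion *d* = 0.8 (climate baseline), biofortification *b* = 1.3
(scenario s1/s4), and wholegrain/brown share targets *s\** = 0.5 / 1.0
(s2, s3, s4). A group's mean increase over the baseline is declared
significant when it exceeds the least significant delta
*z·sd/√n* (*z* = 1.96), the 95% CI half-width of the group's mean daily
iron intake. Group differences in wheat/rice variables are tested with the
tie-corrected Kruskal–Wallis rank test.

## Worked example

```python
import ferrodiet as fd

cfg = fd.single_group_config("male", "18-64", seed=42, n=200)
res = fd.DietaryIronModel.from_simulation(cfg).fit()
print(res.group_summaries(["iron_mg_day"], include_overall=False).round(2))
print(res.project().delta_table("s4").round(3))
```

```
 sex age_class    variable   n  mean   sd  median   p5  p95
male     18-64 iron_mg_day 200 13.12 3.95   12.66 7.72 19.7

 sex age_class   n  half_width_mg_day  mean_delta_vs_baseline  significant
male     18-64 200              0.548                   1.417         True
```

The simulated adult-male cohort averages 13.12 mg iron/day (target
calibration: mean 13.1, SD 4.1), i.e. a +3.12 mg/day adequacy gap over the
10 mg/day PRI. Under the cumulative scenario s4 (20% climate depletion,
then 30% biofortification plus a shift to 50% wholegrain wheat and 100%
brown rice), mean intake rises 1.417 mg/day above the depleted baseline —
larger than the 0.548 mg/day least significant delta, hence a significant
recovery.

The same analysis runs from the shell:

```sh
ferrodiet report --seed 42 --outdir out/       # synthetic end-to-end
ferrodiet simulate --seed 1 --outdir survey/   # survey CSVs only
ferrodiet analyze --individuals survey/individuals.csv \
    --diaries survey/diaries.csv --composition survey/composition.csv \
    --outdir out/                              # external-CSV mode
```

`report` writes the intake/adequacy table, wheat and rice summaries, the
cereal-contribution table, the scenario significance table, figure-ready
adequacy series and a JSON run manifest (seed, config hash, version).

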