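# alcoburden

Comparative risk assessment of the alcohol-attributable cancer burden, built
around the 2018 Argentine setting: a national quantity–frequency survey for
exposure, ICD-10 vital registration for mortality, WHO-style life tables and
GBD-style YLD inputs for disability, and meta-analytic relative risks per
consumption level. The package estimates how many cancer deaths and DALYs are
attributable to alcohol, how they split across light, moderate and heavy
drinking, and how much would be prevented under counterfactual shifts of the
population's consumption distribution.

It is aimed at epidemiologists and burden-of-disease analysts who want a
tested, scriptable implementation of this pipeline. Because the real microdata
(survey, death registry, GBD exports) require downloads and licences, the
package ships a synthetic-data generator with known ground truth, calibrated
to the published 2018 Argentine marginals, so the entire pipeline runs and is
validated end to end out of the box. Point the same functions at real CSV
extracts to run an actual analysis.

## The model

Exposure is classified from self-reported beverage-specific units per week or
month, converted to grams of pure ethanol per day (14 g per standard unit by
default) and grouped as non-drinker (0 g/day, reference, including former
drinkers), light (0.1–12.5), moderate (12.6–50) and heavy (>50 g/day).

For each cancer site and sex, with survey-weighted prevalences $P_i$ and
relative risks $RR_i$ over the $n=3$ exposed levels, the population
attributable fraction is the Levin-type multi-level formula

$$
\mathrm{PAF} \;=\; \frac{\sum_{i=1}^{n} P_i\,(RR_i - 1)}
                        {\sum_{i=1}^{n} P_i\,(RR_i - 1) + 1},
\qquad
\mathrm{PAF}_i \;=\; \frac{P_i\,(RR_i - 1)}{\sum_{j} P_j\,(RR_j - 1) + 1},
$$

the proportional reduction in deaths or DALYs if exposure were reduced to
zero; the level-wise terms $\mathrm{PAF}_i$ share the common denominator and
therefore add up exactly to the total. Non-significant associations are
censored to $RR=1$ before attribution.

Burden accounting follows standard DALY bookkeeping: attributable deaths are
site deaths × PAF; YLL = deaths × residual life expectancy at the age band;
YLD = population × Σ (sequela prevalence × disability weight) over the four
cancer phases (diagnosis/primary therapy, controlled, metastatic, terminal);
DALY = YLL + YLD, attributed with the same sex-level PAF. Counterfactual
scenarios move whole consumption categories downward (heavy→moderate,
moderate→light, both combined) and report the prevented attributable burden.

## Worked example

```python
import alcoburden as ab

p = [0.425, 0.19, 0.045]          # light, moderate, heavy prevalence in men
rr = [1.26, 2.23, 4.95]           # esophageal cancer relative risks
print("total PAF:", round(ab.paf_total(p, rr), 3))
print("by level :", ab.paf_by_level(p, rr).round(3))

truth = ab.default_ground_truth(seed=1)
survey = ab.generate_survey(truth, 29_224)
prev = ab.weighted_prevalence(survey)
print(prev[["sex", "non_drinker", "light", "moderate", "heavy"]].round(3).to_string(index=False))

rr_table, sites = ab.load_risk_config()
deaths, report = ab.filter_and_group(ab.generate_registry(truth), sites)
inputs = ab.PipelineInputs(
    prevalence=prev, rr=rr_table, sites=sites, deaths=deaths,
    life_table=ab.generate_life_table(), yld_inputs=ab.generate_yld_table(truth),
)
burden = inputs.burden()
print(f"attributable deaths: {burden['deaths_attrib'].sum():.0f} "
      f"of {burden['deaths_total'].sum():.0f} six-site cancer deaths")
result = ab.evaluate_scenario(inputs, ab.MODERATE_TO_LIGHT)
print(f"moderate->light would prevent {result.prevented_deaths:.0f} deaths "
      f"({result.pct_deaths_prevented:.0f}% of attributable)")
```

prints

```
total PAF: 0.343
by level : [0.073 0.154 0.117]
sex  non_drinker  light  moderate  heavy
  F        0.579  0.343     0.073  0.005
  M        0.338  0.427     0.191  0.044
attributable deaths: 1123 of 17456 six-site cancer deaths
moderate->light would prevent 437 deaths (39% of attributable)
```

Reading the output: 34.3 % of male esophageal-cancer deaths are attributable
to alcohol under these inputs, decomposed additively into 7.3/15.4/11.7
percentage points from light/moderate/heavy drinking. The synthetic survey
recovers the generating prevalences (e.g. 4.4 % heavy drinkers among men vs a
ground truth of 4.5 %), and of ~17.5k deaths from the six alcohol-associated
cancer sites, ~1.1k are attributable to alcohol, 39 % of which would be
prevented if all moderate drinkers drank lightly.

## Command line

```bash
alcoburden run-all --seed 1 --out run/          # full pipeline, all outputs
alcoburden simulate --out inputs/ --seed 1      # synthetic inputs only
alcoburden prevalence --survey inputs/survey.csv --by sex,age --out prev.csv
alcoburden paf --prev prev.csv --out paf.csv
alcoburden scenario --inputs-dir inputs/ --name combined --out scenario.csv
```

`run-all` writes the prevalence tables, PAFs, the full-precision burden table,
scenario results, display-rounded site × sex × level report tables for deaths
and DALYs, and a seed/config-hash-stamped run log; outputs are byte-identical
for identical seeds and configs. `--extended-sites` adds the
sensitivity-analysis sites (melanoma, pancreas, prostate).

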