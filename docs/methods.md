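# Methods

## Scope and design

`alcoburden` implements a comparative risk assessment of alcohol-attributable
cancer burden in the style of national burden-of-disease studies: exposure
prevalence from a survey, Levin-type multi-level population attributable
fractions (PAFs), attribution of deaths and DALYs, and counterfactual
consumption-shift scenarios. The pipeline is deterministic given its inputs;
all randomness lives in the synthetic-data generator and the micro-simulation
oracle, both driven by explicit seeds (numpy `default_rng` with a distinct
fixed stream offset per generator, so adding a generator never perturbs the
others).

## Exposure

Respondents report habitual units of beer, wine and spirits per week, or per
month when they drink less than weekly. Conversion to grams of ethanol per
day uses a configurable grams-per-standard-unit (default 14 g, the common
convention in the Americas) and a monthly divisor of 30.44 days (the mean
Gregorian month; the choice is not dictated by any source, so it is a
parameter). Classification uses half-open intervals — 0, (0, 12.5],
(12.5, 50], (50, ∞) g/day — so every non-negative intake has exactly one
category; the nominal gap between "12.5" and "12.6" in the categorical
definitions is resolved by assigning exactly 12.5 to light, since a continuous
quantity needs a total classification. Former drinkers cannot be identified
from a quantity-frequency instrument and are classified by current intake,
which matches the meta-analytic reference group (non-drinkers including
former drinkers).

Prevalence is the Hájek (ratio) estimator: the weighted share of each category
per stratum, with the Kish effective sample size (Σw)²/Σw² reported per
stratum. Strata expected but empty are excluded with a warning rather than
reported as zero. Variance estimation for the complex design is out of scope;
the analysis uses point prevalences only.

## Relative risks

RRs per cancer site × sex × exposed level are configuration data (YAML), not
code. The shipped defaults are taken from the public Bagnardi et al. (2015)
dose–response meta-analysis of alcohol and cancer, with significance flags
set so that associations not established for a sex/level (e.g. colorectal
cancer in women, light drinking and larynx cancer in men) are censored to
RR = 1 before any attribution — absent or non-significant associations
contribute no burden. A missing (site, sex, level) entry likewise resolves to
RR = 1 with a logged warning, while an inapplicable site/sex combination
(breast cancer in men under the default config) is a configuration error. The
engine permits RR < 1 (negative contributions), although the shipped cancer
config never produces one after censoring.

The core site set and its ICD-10 codes: oral cavity and pharynx C00–C14,
esophagus C15, colorectal C18–C20, liver C22, larynx C32, breast C50 (women
only). The sensitivity extension adds melanoma C43, pancreas C25 and prostate
C61, treated as legitimate associations when enabled. Code sets are validated
to be pairwise disjoint.

## PAF

With exposed-level prevalences P_i and censored RRs,

    PAF = Σ P_i (RR_i − 1) / (Σ P_i (RR_i − 1) + 1)

and the level-wise decomposition shares the common denominator,
PAF_i = P_i (RR_i − 1) / (Σ_j P_j (RR_j − 1) + 1). This is the only
decomposition whose level terms sum exactly to the total, which is what makes
per-level burden columns additive. PAFs are computed per sex only: the RRs
are sex-specific and the exposure prevalences feeding the PAF are sex-level;
age enters through age-specific death counts and residual life expectancy,
not through the PAF.

## Burden accounting

Death records with missing sex or age are excluded and counted; malformed
ICD-10 codes are skipped with a warning; codes outside the configured site
sets are tallied as non-target. The remaining records are grouped on the
first three ICD-10 characters into a complete site × sex × age-band grid
(zeros filled), using six adult bands (18–29 … 60–69, 70+). The exclusion
report reconciles exactly: excluded + malformed + non-target + grouped =
records read.

YLL = deaths × residual life expectancy at the band (read at the band, not
interpolated, since the whole pipeline works per age category). YLD =
population × Σ over the four sequelae (diagnosis/primary therapy, controlled,
metastatic, terminal) of prevalence × disability weight, weights validated to
lie strictly in (0, 1). DALY = YLL + YLD. Attributable quantities multiply
each total by the site/sex PAF (total or per level); the same PAF is used for
mortality and morbidity, as no morbidity-specific PAF is defined for these
inputs. Everything is kept real-valued internally; rounding to integer deaths
/DALYs and whole-percent PAFs happens only in the reporting layer. This is
also why a rendered total can differ from the sum of its rendered parts by
±1 per rounding step — the reporting tests use exactly that slack.

## Scenarios

A scenario is a map from source to destination categories, applied
simultaneously to the baseline prevalence (every source's mass is taken from
the baseline table, so in the combined scenario the moderate category ends up
holding exactly the former heavy mass). Shifted drinkers adopt the
destination category's RR wholesale; no within-category dose modelling is
attempted. Only downward shifts are allowed. Prevented burden is baseline
attributable minus counterfactual attributable, also expressed as a
percentage of baseline attributable burden; full abstention therefore
prevents exactly 100 % by the definition of the PAF. With RRs non-decreasing
across levels, the combined scenario dominates each single shift (verified
property).

## Synthetic data: what it emulates and what it does not

The generator produces all five inputs with known ground truth:

- **Survey.** Respondents drawn from a stylised adult population
  (~31.6 M, six age bands per sex) with age-dependent sampling intensity
  (young adults oversampled by up to 1.3×, the oldest band undersampled to
  0.7×); weights are the inverse sampling probability times lognormal noise
  (σ = 0.25), so unweighted and weighted estimators genuinely differ.
  Consumption categories are drawn per sex from the ground-truth prevalence —
  defaults calibrated to the 2018 Argentine survey marginals (men
  34/42.5/19/4.5 %, women 58/34.3/7.2/0.5 % for non/light/moderate/heavy).
  A g/day value is drawn uniformly within the category (with a safety margin
  of ~0.1–0.4 g/day from the 12.5 and 50 boundaries) and converted back into
  beverage unit counts via a Dirichlet split, so generated responses always
  classify into the category they were drawn for. Light drinkers respond
  monthly 40 % of the time; others weekly.
- **Registry.** Stratum death counts are Poisson with mean population ×
  baseline (non-drinker) rate × exposure inflation 1 + Σ P_i (RR_i − 1), so
  the analytic PAF is the expected attributable share by construction.
  Baseline rates are derived by dividing per-site/sex expected death totals
  (magnitudes of the 2018 Argentine registration for these sites, e.g.
  ~1,160 male esophageal-cancer deaths) by that inflation, with a fixed
  age profile concentrating ~70 % of deaths above age 60. ICD codes are drawn
  from the site's code set, 35 % with a fourth digit to exercise prefix
  matching; 10 % of records carry non-target filler codes; 0.7 % of records
  have age and/or sex blanked. The three sensitivity-analysis sites always
  generate deaths — whether they are analysed is the site config's decision,
  which exercises non-target filtering in the core run.
- **Life table.** Residual life expectancy is 0.8 × (max_age − band
  midpoint), strictly decreasing — a stylised WHO-like schedule, not a fitted
  one.
- **YLD inputs.** Sequela prevalences are fixed multiples of the stratum's
  disease rate (3×, 12×, 1.5×, 0.5× for diagnosis/controlled/metastatic/
  terminal) with GBD-style disability weights 0.288/0.049/0.451/0.540.

Passing tests on these data demonstrate the estimators and accounting are
correct under the stated generating model. They do not demonstrate realism of
the joint distribution of real survey responses (beverage mix, digit
preference, top-coding), time trends or lagged exposure effects, unrecorded
consumption, or binge patterns — all deliberately out of scope. Synthetic
default DALY levels are larger relative to deaths than in published national
tables because the stylised YLD prevalences are generous; the YLD table is an
input, so real GBD extracts slot in unchanged.

## Micro-simulation oracle

`simulate_cohort_deaths` validates the PAF formula independently: each of n
people gets a level (multinomial) and dies with probability baseline × RR.
Observed and counterfactual deaths are coupled through common random numbers
(a person dies counterfactually iff their uniform draw falls below the
baseline risk), implemented exactly via nested binomials — for RR ≥ 1 the
counterfactual deaths are a Binomial(observed, 1/RR) thinning, and vice versa
for RR < 1. The coupling makes the null case (all RR = 1) yield an excess of
exactly zero and reduces the variance of the excess-fraction estimator
(D − D_cf)/D, which is compared to the analytic PAF within three standard
errors (delta method, covariance conservatively dropped) across random
configurations of two million people each.

## Numerical and interface choices

- Tolerances: level-PAF decomposition is exact to 1e-12; DALY = YLL + YLD to
  1e-9 per stratum; prevalence proportions sum to 1 to 1e-9 per stratum.
- Degenerate inputs: zero attributable burden makes level shares and
  prevented percentages undefined — reported as NaN with a warning, never as
  silent zeros.
- Ages below 18 in a registry map to the youngest band so grouping is total;
  the synthetic populations are adult, so this path only concerns degraded
  real inputs.
- Problem sizes in the test suite and acceptance script follow the study
  setting: survey n = 29,224 (50,000 for the recovery check), full-size
  registry (~30k records), 2,000,000-person oracle cohorts; the whole
  acceptance run completes in seconds.
- The CLI is a thin typer layer; every subcommand is a library call plus CSV
  I/O. `run-all` output directories are deterministic per (seed, config):
  logs carry no timestamps, and the metadata stamp contains the seed and a
  SHA-256 hash of the configuration (excluding the output path).

## Known limitations

- No uncertainty propagation: RR confidence limits and survey design variance
  are not carried through (point estimates only, by design).
- Sex-level PAFs applied uniformly across age bands; if exposure varies
  strongly by age, age-specific PAFs would differ.
- The scenario machinery models complete category shifts; partial-compliance
  (fractional) shifts would need fractional shift maps.
- The shipped RR defaults are approximate literature values intended as a
  working configuration; a substantive analysis should supply its own vetted
  RR file.
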