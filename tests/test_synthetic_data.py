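"""Synthetic survey / registry / life-table / YLD generators and the cohort
micro-simulation: determinism, calibration, and structural guarantees."""

import numpy as np
import pandas as pd
import pytest

from alcoburden.exposure import categorize, grams_per_day
from alcoburden.strata import LEVELS, NON_DRINKER
from alcoburden.synthetic_data import (
    DEFAULT_EXPECTED_DEATHS,
    FILLER_CODES,
    default_ground_truth,
    empirical_paf,
    generate_life_table,
    generate_registry,
    generate_survey,
    generate_yld_table,
    simulate_cohort_deaths,
)


def degenerate_prevalence(level):
    return {
        sex: {lvl: (1.0 if lvl == level else 0.0) for lvl in LEVELS}
        for sex in ("M", "F")
    }


@pytest.fixture(scope="module")
def truth():
    return default_ground_truth(seed=7)


class TestSurveyGenerator:
    def test_deterministic_under_fixed_seed(self, truth):
        a = generate_survey(truth, 500)
        b = generate_survey(truth, 500)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, truth):
        a = generate_survey(truth, 500)
        b = generate_survey(truth, 500, seed=truth.seed + 1)
        assert not a.equals(b)

    def test_all_non_drinkers_have_zero_units(self):
        truth = default_ground_truth(seed=3, prevalence=degenerate_prevalence(NON_DRINKER))
        survey = generate_survey(truth, 400)
        assert (survey[["beer_units", "wine_units", "spirits_units"]] == 0).all().all()

    @pytest.mark.parametrize("level", ["light", "moderate", "heavy"])
    def test_responses_classify_into_assigned_category(self, level):
        """Generated unit counts always imply a g/day inside the category the
        respondent was drawn for."""
        truth = default_ground_truth(seed=3, prevalence=degenerate_prevalence(level))
        survey = generate_survey(truth, 400)
        gpd = grams_per_day(
            survey["beer_units"], survey["wine_units"], survey["spirits_units"],
            survey["freq_unit"],
        )
        assert (categorize(gpd) == level).all()

    def test_weights_positive_and_variable(self, truth):
        survey = generate_survey(truth, 1000)
        assert (survey["weight"] > 0).all()
        assert survey["weight"].nunique() > 100  # estimator genuinely weighted

    def test_ages_adult(self, truth):
        survey = generate_survey(truth, 1000)
        assert survey["age"].between(18, 95).all()

    def test_rejects_empty_sample(self, truth):
        with pytest.raises(ValueError, match="n_respondents"):
            generate_survey(truth, 0)


class TestRegistryGenerator:
    def test_deterministic_under_fixed_seed(self, truth):
        pd.testing.assert_frame_equal(
            generate_registry(truth), generate_registry(truth)
        )

    def test_missingness_rate_calibrated(self):
        # scale expected deaths up to ~100k records for a tight binomial check
        scaled = {
            site: {sex: n * 6 for sex, n in by_sex.items()}
            for site, by_sex in DEFAULT_EXPECTED_DEATHS.items()
        }
        truth = default_ground_truth(seed=9, expected_deaths=scaled)
        registry = generate_registry(truth)
        assert len(registry) > 80_000
        blank = (registry["sex"].isna() | registry["age"].isna()).mean()
        assert blank == pytest.approx(0.007, abs=0.002)

    def test_zero_rates_give_empty_registry(self):
        truth = default_ground_truth(seed=2, expected_deaths={"liver": {"M": 0}})
        registry = generate_registry(truth)
        assert registry.empty

    def test_breast_records_women_only(self, truth):
        registry = generate_registry(truth)
        breast = registry[registry["icd10"].str.startswith("C50")]
        assert len(breast) > 0
        assert set(breast["sex"].dropna()) == {"F"}

    def test_filler_codes_present_at_configured_rate(self, truth):
        registry = generate_registry(truth)
        filler = registry["icd10"].str[:3].isin(FILLER_CODES)
        assert filler.mean() == pytest.approx(truth.filler_rate, abs=0.01)

    def test_expected_volume_matches_calibration(self, truth):
        registry = generate_registry(truth)
        target = sum(n for by_sex in DEFAULT_EXPECTED_DEATHS.values() for n in by_sex.values())
        non_filler = (~registry["icd10"].str[:3].isin(FILLER_CODES)).sum()
        assert non_filler == pytest.approx(target, rel=0.05)


class TestLifeAndYldTables:
    def test_life_expectancy_strictly_decreasing(self):
        lt = generate_life_table()
        e = lt["life_expectancy_years"].to_numpy()
        assert (np.diff(e) < 0).all()
        assert e[-1] < e[0]

    def test_invalid_max_age_rejected(self):
        with pytest.raises(ValueError):
            generate_life_table(0)

    def test_disability_weights_in_open_unit_interval(self, truth):
        yld = generate_yld_table(truth)
        dw = yld[[c for c in yld.columns if c.startswith("dw_")]]
        assert ((dw > 0) & (dw < 1)).all().all()

    def test_zero_rates_give_zero_sequela_prevalence(self):
        truth = default_ground_truth(seed=2)
        zeroed = truth.model_copy(
            update={
                "baseline_death_rate": {
                    site: {sex: {b: 0.0 for b in bands} for sex, bands in by_sex.items()}
                    for site, by_sex in truth.baseline_death_rate.items()
                }
            }
        )
        yld = generate_yld_table(zeroed)
        prev_cols = [c for c in yld.columns if c.startswith("prev_")]
        assert (yld[prev_cols] == 0).all().all()


class TestCohortSimulation:
    def test_worked_attributable_fraction(self):
        value = empirical_paf([0.5, 0.2, 0.1], [1.2, 2.0, 4.0], 0.01, 2_000_000, seed=1)
        assert value == pytest.approx(0.375, abs=0.01)

    def test_null_effect_is_exactly_zero(self):
        """With all RR = 1 the coupling makes observed and counterfactual
        deaths identical, not merely close."""
        sim = simulate_cohort_deaths([0.5, 0.2, 0.1], [1, 1, 1], 0.01, 100_000, seed=5)
        assert (sim.deaths == sim.deaths_counterfactual).all()

    def test_no_exposure_attributes_nothing(self):
        assert empirical_paf([0, 0, 0], [1.2, 2.0, 4.0], 0.01, 100_000, seed=5) == 0.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            simulate_cohort_deaths([0.5], [3.0], 0.5, 1000, seed=0)

    def test_person_counts_conserved(self):
        sim = simulate_cohort_deaths([0.3, 0.2], [1.5, 2.5], 0.01, 50_000, seed=8)
        assert sim.persons.sum() == 50_000
        assert (sim.deaths <= sim.persons).all()
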