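"""Registry filtering/grouping and the deaths -> YLL/YLD -> DALY accounting."""

import numpy as np
import pandas as pd
import pytest

from alcoburden.burden import (
    ExclusionReport,
    aggregate_burden,
    assemble_burden,
    attributable_deaths,
    filter_and_group,
    yld,
    yll,
)
from alcoburden.errors import ConfigurationError
from alcoburden.paf_engine import paf_table
from alcoburden.risk_inputs import default_sites
from alcoburden.strata import AGE_BANDS

from conftest import make_prevalence


def make_registry(rows):
    return pd.DataFrame(
        [
            {"record_id": f"D{i}", "icd10": icd, "sex": sex, "age": age, "year": 2018}
            for i, (icd, sex, age) in enumerate(rows)
        ]
    )


def make_life_table(e_by_band=None):
    e_by_band = e_by_band or {b: e for b, e in zip(AGE_BANDS, (60, 50, 40, 30, 20, 10))}
    return pd.DataFrame(
        [{"age_band": b, "life_expectancy_years": e} for b, e in e_by_band.items()]
    )


class TestFilterAndGroup:
    def test_code_mapping_and_exclusions(self):
        registry = make_registry(
            [
                ("C15", "M", 63),      # esophagus, 60-69
                ("C19", "F", None),    # missing age -> excluded
                ("J18", "M", 70),      # non-target -> ignored
                ("C509", "F", 55),     # breast via prefix, 50-59
                ("C02", "male", 41),   # oral cavity, sex alias accepted
            ]
        )
        deaths, report = filter_and_group(registry, default_sites())
        lookup = deaths.set_index(["site", "sex", "age_band"])["deaths_total"]
        assert lookup[("esophagus", "M", "60-69")] == 1
        assert lookup[("breast", "F", "50-59")] == 1
        assert lookup[("oral_cavity_pharynx", "M", "40-49")] == 1
        assert report == ExclusionReport(
            n_input=5, n_missing_excluded=1, n_malformed=0, n_nontarget=1, n_grouped=3
        )
        assert report.reconciles()

    def test_malformed_codes_warn_and_are_counted(self):
        registry = make_registry([("15C", "M", 40), ("", "F", 50), ("C15", "M", 60)])
        with pytest.warns(UserWarning, match="malformed"):
            deaths, report = filter_and_group(registry, default_sites())
        assert report.n_malformed == 2
        assert report.reconciles()
        assert deaths["deaths_total"].sum() == 1

    def test_grid_is_complete_with_zeros(self):
        deaths, _ = filter_and_group(make_registry([("C15", "M", 63)]), default_sites())
        # 11 applicable (site, sex) pairs x 6 age bands
        assert len(deaths) == 66
        assert deaths["deaths_total"].sum() == 1

    def test_breast_not_gridded_for_men(self):
        deaths, _ = filter_and_group(make_registry([("C15", "M", 63)]), default_sites())
        assert deaths.query("site == 'breast' and sex == 'M'").empty


class TestAttribution:
    def _deaths(self, n=100.0):
        return pd.DataFrame(
            [{"site": "esophagus", "sex": "M", "age_band": "60-69", "deaths_total": n}]
        )

    def _paf(self, total=0.07):
        return pd.DataFrame(
            [
                {
                    "site": "esophagus", "sex": "M",
                    "paf_light": total / 7, "paf_moderate": total * 2 / 7,
                    "paf_heavy": total * 4 / 7, "paf_total": total,
                }
            ]
        )

    def test_linear_scaling(self):
        out = attributable_deaths(self._deaths(100.0), self._paf(0.07))
        assert out["deaths_attrib"].iloc[0] == pytest.approx(7.0)

    def test_zero_paf_attributes_nothing(self):
        out = attributable_deaths(self._deaths(), self._paf(0.0))
        assert out["deaths_attrib"].iloc[0] == 0.0

    def test_missing_paf_rejected(self):
        paf = self._paf().assign(site="larynx")
        with pytest.raises(ConfigurationError, match="no PAF"):
            attributable_deaths(self._deaths(), paf)

    def test_level_attributions_sum_to_total(self):
        out = attributable_deaths(self._deaths(123.0), self._paf(0.21))
        levels = out[[f"deaths_attrib_{l}" for l in ("light", "moderate", "heavy")]]
        assert levels.sum(axis=1).iloc[0] == pytest.approx(
            out["deaths_attrib"].iloc[0], abs=1e-9
        )


class TestYll:
    def test_definition(self):
        deaths = pd.DataFrame(
            [{"site": "s", "sex": "M", "age_band": "60-69", "deaths_total": 10.0}]
        )
        out = yll(deaths, make_life_table())
        assert out["yll_total"].iloc[0] == pytest.approx(200.0)

    def test_zero_deaths_zero_yll(self):
        deaths = pd.DataFrame(
            [{"site": "s", "sex": "M", "age_band": "60-69", "deaths_total": 0.0}]
        )
        assert yll(deaths, make_life_table())["yll_total"].iloc[0] == 0.0

    def test_linearity_in_deaths(self):
        deaths = pd.DataFrame(
            [{"site": "s", "sex": "M", "age_band": "30-39", "deaths_total": 7.0}]
        )
        base = yll(deaths, make_life_table())["yll_total"].iloc[0]
        double = yll(deaths.assign(deaths_total=14.0), make_life_table())["yll_total"].iloc[0]
        assert double == pytest.approx(2 * base)

    def test_missing_band_rejected(self):
        deaths = pd.DataFrame(
            [{"site": "s", "sex": "M", "age_band": "60-69", "deaths_total": 1.0}]
        )
        lt = make_life_table().query("age_band != '60-69'")
        with pytest.raises(ConfigurationError, match="life table"):
            yll(deaths, lt)


class TestYld:
    def _inputs(self, **overrides):
        row = {
            "site": "s", "sex": "F", "age_band": "50-59", "population": 1000,
            "prev_diagnosis": 0.001, "prev_controlled": 0.0,
            "prev_metastatic": 0.0, "prev_terminal": 0.0,
            "dw_diagnosis": 0.3, "dw_controlled": 0.049,
            "dw_metastatic": 0.451, "dw_terminal": 0.54,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_single_sequela(self):
        assert yld(self._inputs())["yld_total"].iloc[0] == pytest.approx(0.3)

    def test_zero_prevalence_zero_yld(self):
        assert yld(self._inputs(prev_diagnosis=0.0))["yld_total"].iloc[0] == 0.0

    def test_sequela_order_irrelevant(self):
        a = self._inputs(prev_diagnosis=0.002, prev_terminal=0.001)
        b = self._inputs(prev_diagnosis=0.001, prev_terminal=0.002,
                         dw_diagnosis=0.54, dw_terminal=0.3)
        assert yld(a)["yld_total"].iloc[0] == pytest.approx(yld(b)["yld_total"].iloc[0])

    @pytest.mark.parametrize("bad", [0.0, 1.0, 1.4])
    def test_weight_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError, match="disability weights"):
            yld(self._inputs(dw_controlled=bad))


class TestAssemble:
    def _pipeline(self, prev=None):
        registry = make_registry(
            [("C15", "M", 63)] * 50 + [("C15", "F", 55)] * 20 + [("C50", "F", 45)] * 30
        )
        sites = default_sites()
        deaths, _ = filter_and_group(registry, sites)
        from alcoburden.risk_inputs import default_rr_table

        paf = paf_table(
            prev if prev is not None else make_prevalence(), default_rr_table(), sites
        )
        yld_inputs = pd.DataFrame(
            [
                {
                    "site": "esophagus", "sex": "M", "age_band": "60-69",
                    "population": 10_000, "prev_diagnosis": 0.005,
                    "prev_controlled": 0.01, "prev_metastatic": 0.002,
                    "prev_terminal": 0.001, "dw_diagnosis": 0.288,
                    "dw_controlled": 0.049, "dw_metastatic": 0.451,
                    "dw_terminal": 0.54,
                }
            ]
        )
        return assemble_burden(deaths, make_life_table(), yld_inputs, paf)

    def test_daly_is_yll_plus_yld_everywhere(self):
        burden = self._pipeline()
        np.testing.assert_allclose(
            burden["daly_total"], burden["yll_total"] + burden["yld_total"]
        )
        np.testing.assert_allclose(
            burden["daly_attrib"],
            burden["yll_attrib"] + burden["yld_attrib"],
            atol=1e-9,
        )

    def test_yll_yld_example_additivity(self):
        burden = self._pipeline()
        row = burden.query("site == 'esophagus' and sex == 'M' and age_band == '60-69'")
        assert row["daly_total"].iloc[0] == pytest.approx(
            row["yll_total"].iloc[0] + row["yld_total"].iloc[0]
        )
        assert row["yld_total"].iloc[0] > 0

    def test_level_daly_shares_sum_to_total(self):
        burden = self._pipeline()
        levels = burden[[f"daly_attrib_{l}" for l in ("light", "moderate", "heavy")]]
        np.testing.assert_allclose(
            levels.sum(axis=1), burden["daly_attrib"], atol=1e-9
        )

    def test_aggregates_are_additive(self):
        burden = self._pipeline()
        by_sex = aggregate_burden(burden, ["sex"])
        total = aggregate_burden(burden, [])
        assert by_sex["deaths_attrib"].sum() == pytest.approx(
            total["deaths_attrib"].iloc[0]
        )
        assert by_sex["daly_attrib"].sum() == pytest.approx(
            total["daly_attrib"].iloc[0]
        )

    def test_zero_paf_zero_attributable(self):
        prev = make_prevalence(m=(1, 0, 0, 0), f=(1, 0, 0, 0))
        burden = self._pipeline(prev)
        assert (burden["deaths_attrib"] == 0).all()
        assert (burden["daly_attrib"] == 0).all()
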