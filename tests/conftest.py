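import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from alcoburden.risk_inputs import CancerSite
from alcoburden.strata import LEVELS

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_survey(rows):
    """Build a survey DataFrame from (sex, age, weight, beer, wine, spirits, freq)."""
    return pd.DataFrame(
        [
            {
                "respondent_id": f"R{i}",
                "sex": sex,
                "age": age,
                "weight": weight,
                "beer_units": beer,
                "wine_units": wine,
                "spirits_units": spirits,
                "freq_unit": freq,
            }
            for i, (sex, age, weight, beer, wine, spirits, freq) in enumerate(rows)
        ]
    )


def make_prevalence(m=(0.3, 0.4, 0.2, 0.1), f=(0.6, 0.3, 0.08, 0.02)):
    """Sex-level prevalence table (non, light, moderate, heavy per sex)."""
    return pd.DataFrame(
        [
            {"sex": "M", **dict(zip(LEVELS, m)), "n_eff": 1000.0},
            {"sex": "F", **dict(zip(LEVELS, f)), "n_eff": 1000.0},
        ]
    )


def make_rr(entries):
    """RR table from (site, sex, level, rr, significant) tuples."""
    return pd.DataFrame(
        entries, columns=["site", "sex", "level", "rr", "significant"]
    )


@pytest.fixture
def sites_fixture():
    return [
        CancerSite(name="upper_gi", icd10_codes=("C15",)),
        CancerSite(name="breast", icd10_codes=("C50",), sexes=("F",)),
    ]


@pytest.fixture
def rr_fixture():
    return make_rr(
        [
            ("upper_gi", "M", "light", 1.2, True),
            ("upper_gi", "M", "moderate", 2.0, True),
            ("upper_gi", "M", "heavy", 4.0, True),
            ("upper_gi", "F", "light", 1.2, False),
            ("upper_gi", "F", "moderate", 2.0, True),
            ("upper_gi", "F", "heavy", 4.0, True),
            ("breast", "F", "light", 1.05, True),
            ("breast", "F", "moderate", 1.25, True),
            ("breast", "F", "heavy", 1.6, True),
        ]
    )


@pytest.fixture
def prev_fixture():
    return make_prevalence()
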