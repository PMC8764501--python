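"""Quantity–frequency survey responses → grams of ethanol per day → consumption
levels → survey-weighted prevalence.

Respondents report habitual units of beer, wine and spirits per week (or per
month when they drink less than weekly). A standard unit is taken to contain
14 g of pure ethanol by default (the usual convention in the Americas); the
monthly-to-daily divisor defaults to the mean Gregorian month length, 30.44
days. Both are configurable because unit content and conventions vary by
country.

Classification uses half-open intervals so that every non-negative g/day value
has exactly one category: 0 -> non-drinker, (0, 12.5] -> light,
(12.5, 50] -> moderate, (50, inf) -> heavy. A g/day of exactly 12.5 is light.
Former drinkers are not observable in the quantity-frequency schema and are
classified by current consumption, matching the reference group of the
meta-analysis (non-drinkers including former drinkers).
"""

from __future__ import annotations

import warnings
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .strata import (
    AGE_BANDS,
    EXPOSED_LEVELS,
    HEAVY,
    LEVELS,
    LIGHT,
    LIGHT_MAX_GPD,
    MODERATE,
    MODERATE_MAX_GPD,
    NON_DRINKER,
    SEXES,
    age_to_band,
    normalize_sex,
)

DEFAULT_GRAMS_PER_UNIT = 14.0
DEFAULT_MONTHLY_DIVISOR = 30.44

SURVEY_COLUMNS = (
    "respondent_id", "sex", "age", "weight",
    "beer_units", "wine_units", "spirits_units", "freq_unit",
)


def grams_per_day(
    beer_units,
    wine_units,
    spirits_units,
    freq_unit,
    grams_per_unit: float = DEFAULT_GRAMS_PER_UNIT,
    monthly_divisor: float = DEFAULT_MONTHLY_DIVISOR,
):
    """Total ethanol intake in g/day from beverage-specific unit counts.

    ``freq_unit`` is ``"week"`` or ``"month"`` (scalar or element-wise).
    Vectorised over numpy arrays / pandas Series; scalars return a float.
    """
    if grams_per_unit <= 0:
        raise ValueError("grams_per_unit must be positive")
    if monthly_divisor <= 0:
        raise ValueError("monthly_divisor must be positive")
    beer = np.asarray(beer_units, dtype=float)
    wine = np.asarray(wine_units, dtype=float)
    spirits = np.asarray(spirits_units, dtype=float)
    if np.any(beer < 0) or np.any(wine < 0) or np.any(spirits < 0):
        raise ValueError("unit counts must be non-negative")
    freq = np.asarray(freq_unit, dtype=object)
    known = np.isin(freq, ("week", "month"))
    if not np.all(known):
        bad = np.unique(freq[~known]) if freq.ndim else freq
        raise ValueError(f"freq_unit must be 'week' or 'month', got {bad!r}")
    days = np.where(freq == "week", 7.0, monthly_divisor)
    gpd = (beer + wine + spirits) * grams_per_unit / days
    if np.ndim(gpd) == 0:
        return float(gpd)
    return gpd


def categorize(gpd):
    """Classify g/day into the four consumption levels (vectorised)."""
    arr = np.asarray(gpd, dtype=float)
    if np.any(np.isnan(arr)) or np.any(arr < 0):
        raise ValueError("g/day must be non-negative and non-missing")
    cats = np.select(
        [arr == 0, arr <= LIGHT_MAX_GPD, arr <= MODERATE_MAX_GPD],
        [NON_DRINKER, LIGHT, MODERATE],
        default=HEAVY,
    )
    if np.ndim(gpd) == 0:
        return str(cats[()])
    return cats.astype(object)


def classify_survey(
    survey: pd.DataFrame,
    grams_per_unit: float = DEFAULT_GRAMS_PER_UNIT,
    monthly_divisor: float = DEFAULT_MONTHLY_DIVISOR,
) -> pd.DataFrame:
    """Return a copy of the survey with ``gpd`` and ``category`` columns added
    and the sex column normalised to M/F."""
    df = survey.copy()
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey is missing columns: {sorted(missing)}")
    if (df["weight"] <= 0).any() or df["weight"].isna().any():
        raise ValueError("sampling weights must be positive")
    if (df["age"] < 18).any():
        raise ValueError("survey respondents must be adults (age >= 18)")
    df["sex"] = df["sex"].map(normalize_sex)
    if df["sex"].isna().any():
        raise ValueError("survey contains unrecognised or missing sex codes")
    df["gpd"] = grams_per_day(
        df["beer_units"], df["wine_units"], df["spirits_units"], df["freq_unit"],
        grams_per_unit=grams_per_unit, monthly_divisor=monthly_divisor,
    )
    df["category"] = categorize(df["gpd"].to_numpy())
    return df


def _expected_strata(by: Sequence[str]) -> list[tuple]:
    domains = []
    for col in by:
        if col == "sex":
            domains.append(SEXES)
        elif col == "age_band":
            domains.append(AGE_BANDS)
        else:
            return []  # unknown grouping column: no expectation to enforce
    return list(product(*domains))


def weighted_prevalence(
    survey: pd.DataFrame,
    by: Sequence[str] = ("sex",),
    grams_per_unit: float = DEFAULT_GRAMS_PER_UNIT,
    monthly_divisor: float = DEFAULT_MONTHLY_DIVISOR,
) -> pd.DataFrame:
    """Survey-weighted prevalence of the four consumption levels per stratum.

    P̂(level | stratum) = Σ weights of respondents at that level / Σ weights in
    the stratum, honouring the complex-design sampling weights. ``by`` may be
    ``("sex",)`` or ``("sex", "age_band")``; ``age_band`` is derived from age.

    Returns a DataFrame with the grouping columns, one proportion column per
    level (summing to 1 per stratum) and ``n_eff``, the Kish effective sample
    size (Σw)²/Σw². Expected strata with no respondents are excluded with a
    warning rather than reported as silent zeros.
    """
    by = tuple(by)
    if not by:
        raise ValueError("at least one grouping column is required")
    df = classify_survey(survey, grams_per_unit, monthly_divisor)
    if "age_band" in by:
        df["age_band"] = age_to_band(df["age"].to_numpy())

    rows = []
    seen = set()
    for key, grp in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        seen.add(key)
        w_total = grp["weight"].sum()
        props = {
            lvl: grp.loc[grp["category"] == lvl, "weight"].sum() / w_total
            for lvl in LEVELS
        }
        n_eff = w_total**2 / (grp["weight"] ** 2).sum()
        rows.append({**dict(zip(by, key)), **props, "n_eff": n_eff})

    absent = [s for s in _expected_strata(by) if s not in seen]
    if absent:
        warnings.warn(
            f"empty strata excluded from prevalence table: {absent}",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def prevalence_vector(prevalence: pd.DataFrame, sex: str) -> np.ndarray:
    """Exposed-level proportions (light, moderate, heavy) for one sex from a
    sex-level prevalence table."""
    match = prevalence.loc[prevalence["sex"] == sex]
    if len(match) != 1:
        raise ValueError(f"prevalence table must have exactly one row for sex={sex!r}")
    return match.iloc[0][list(EXPOSED_LEVELS)].to_numpy(dtype=float)
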