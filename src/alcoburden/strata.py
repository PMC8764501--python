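"""Shared stratification vocabulary: sexes, age bands, consumption levels.

The four consumption levels follow the dose categories of the alcohol–cancer
meta-analysis literature: non-drinker (0 g/day, the reference, including
former drinkers), light (0.1–12.5 g/day), moderate (12.6–50 g/day) and heavy
(>50 g/day). Age is grouped into the six adult bands used by the national
risk-factor survey.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

SEX_MALE = "M"
SEX_FEMALE = "F"
SEXES: tuple[str, ...] = (SEX_MALE, SEX_FEMALE)

_SEX_ALIASES = {
    "m": SEX_MALE, "male": SEX_MALE, "men": SEX_MALE, "man": SEX_MALE,
    "f": SEX_FEMALE, "female": SEX_FEMALE, "women": SEX_FEMALE, "woman": SEX_FEMALE,
}

NON_DRINKER = "non_drinker"
LIGHT = "light"
MODERATE = "moderate"
HEAVY = "heavy"

#: total ordering non < light < moderate < heavy
LEVELS: tuple[str, ...] = (NON_DRINKER, LIGHT, MODERATE, HEAVY)
EXPOSED_LEVELS: tuple[str, ...] = (LIGHT, MODERATE, HEAVY)
LEVEL_ORDER: dict[str, int] = {lvl: i for i, lvl in enumerate(LEVELS)}

#: category boundaries in grams of pure ethanol per day (upper bounds, inclusive)
LIGHT_MAX_GPD = 12.5
MODERATE_MAX_GPD = 50.0

AGE_BANDS: tuple[str, ...] = ("18-29", "30-39", "40-49", "50-59", "60-69", "70+")
#: [lower, upper] integer-age range used when drawing ages inside a band
AGE_BAND_RANGES: dict[str, tuple[int, int]] = {
    "18-29": (18, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-69": (60, 69),
    "70+": (70, 90),
}
_BAND_EDGES = np.array([30, 40, 50, 60, 70])


def normalize_sex(value) -> str | None:
    """Map common sex encodings to 'M'/'F'; missing/unrecognised -> None."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return None
    key = str(value).strip().lower()
    if not key or key in ("na", "nan", "none"):
        return None
    return _SEX_ALIASES.get(key)


def age_to_band(age):
    """Map age in years to one of the six adult bands.

    Vectorised: accepts a scalar, array or Series. Ages below 18 fall into
    the youngest band (the pipeline's populations are adults; the mapping is
    total so degraded inputs never crash grouping).
    """
    arr = np.asarray(age, dtype=float)
    idx = np.digitize(arr, _BAND_EDGES)
    bands = np.asarray(AGE_BANDS, dtype=object)[idx]
    if np.ndim(age) == 0:
        return str(bands if bands.ndim == 0 else bands[()])
    return bands


def validate_levels(levels: Iterable[str]) -> None:
    unknown = set(levels) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown consumption level(s): {sorted(unknown)}")
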