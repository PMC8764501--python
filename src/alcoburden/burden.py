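"""From death records, life tables and YLD inputs to attributable burden.

Deaths come from a vital-registration extract (ICD-10 coded). Records with
missing sex or age are excluded and counted; codes outside the configured
cancer-site sets are ignored and counted; the remainder are grouped per
site x sex x age band. Attribution multiplies stratum deaths by the sex-level
PAF of the site (age enters through age-specific death counts and residual
life expectancy, not through the PAF). YLL = deaths x residual life expectancy
at the age band; YLD = population x sum over the four cancer sequelae
(diagnosis/primary therapy, controlled, metastatic, terminal) of
prevalence x disability weight; DALY = YLL + YLD. Attributable quantities are
kept real-valued throughout; rounding to integers happens only in the
reporting layer.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .paf_engine import PAF_LEVEL_COLUMNS
from .risk_inputs import CancerSite, code_to_site_map
from .strata import AGE_BANDS, EXPOSED_LEVELS, age_to_band, normalize_sex

REGISTRY_COLUMNS = ("record_id", "icd10", "sex", "age", "year")

SEQUELAE = ("diagnosis", "controlled", "metastatic", "terminal")
YLD_PREV_COLUMNS = tuple(f"prev_{s}" for s in SEQUELAE)
YLD_DW_COLUMNS = tuple(f"dw_{s}" for s in SEQUELAE)

_ICD_PREFIX_RE = re.compile(r"^[A-Za-z]\d{2}")

_KEY = ["site", "sex", "age_band"]


@dataclass
class ExclusionReport:
    """Accounting of what happened to every input death record."""

    n_input: int
    n_missing_excluded: int
    n_malformed: int
    n_nontarget: int
    n_grouped: int

    def reconciles(self) -> bool:
        return (
            self.n_missing_excluded + self.n_malformed + self.n_nontarget + self.n_grouped
            == self.n_input
        )


def filter_and_group(
    records: pd.DataFrame, sites: Sequence[CancerSite]
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Group death records into total deaths per site x sex x age band.

    Returns a complete grid (every applicable site/sex/band combination, zero
    filled) plus an :class:`ExclusionReport`. Malformed ICD-10 codes are
    skipped with a warning; records missing sex and/or age are excluded; codes
    outside the site config are tallied as non-target.
    """
    missing_cols = set(REGISTRY_COLUMNS) - set(records.columns)
    if missing_cols:
        raise ValueError(f"registry is missing columns: {sorted(missing_cols)}")
    df = records.copy()
    n_input = len(df)

    icd = df["icd10"].astype("string").str.strip()
    valid_icd = icd.notna() & icd.str.match(_ICD_PREFIX_RE)
    n_malformed = int((~valid_icd).sum())
    if n_malformed:
        warnings.warn(
            f"skipped {n_malformed} record(s) with malformed ICD-10 codes",
            UserWarning,
            stacklevel=2,
        )
    df = df[valid_icd].copy()
    df["prefix"] = icd[valid_icd].str[:3].str.upper()

    df["sex_n"] = df["sex"].map(normalize_sex)
    df["age_n"] = pd.to_numeric(df["age"], errors="coerce")
    missing_mask = df["sex_n"].isna() | df["age_n"].isna()
    n_missing = int(missing_mask.sum())
    df = df[~missing_mask]

    site_map = code_to_site_map(sites)
    df["site"] = df["prefix"].map(site_map)
    n_nontarget = int(df["site"].isna().sum())
    df = df.dropna(subset=["site"]).copy()
    df["sex"] = df["sex_n"]
    df["age_band"] = age_to_band(df["age_n"].to_numpy())
    n_grouped = len(df)

    counts = (
        df.groupby(_KEY).size().rename("deaths_total").reset_index()
    )
    grid = pd.DataFrame(
        [
            {"site": s.name, "sex": sex, "age_band": band}
            for s in sites
            for sex in s.sexes
            for band in AGE_BANDS
        ]
    )
    grid = grid.merge(counts, on=_KEY, how="left").fillna({"deaths_total": 0})
    grid["deaths_total"] = grid["deaths_total"].astype(float)

    report = ExclusionReport(n_input, n_missing, n_malformed, n_nontarget, n_grouped)
    return grid, report


def _require_paf(deaths: pd.DataFrame, paf: pd.DataFrame) -> pd.DataFrame:
    merged = deaths.merge(paf, on=["site", "sex"], how="left")
    orphan = merged["paf_total"].isna() & (merged["deaths_total"] > 0)
    if orphan.any():
        combos = merged.loc[orphan, ["site", "sex"]].drop_duplicates().to_records(index=False)
        raise ConfigurationError(f"no PAF available for strata with deaths: {list(combos)}")
    return merged.dropna(subset=["paf_total"]).reset_index(drop=True)


def attributable_deaths(deaths: pd.DataFrame, paf: pd.DataFrame) -> pd.DataFrame:
    """Attach attributable deaths (total and per consumption level)."""
    merged = _require_paf(deaths, paf)
    merged["deaths_attrib"] = merged["deaths_total"] * merged["paf_total"]
    for lvl, col in zip(EXPOSED_LEVELS, PAF_LEVEL_COLUMNS):
        merged[f"deaths_attrib_{lvl}"] = merged["deaths_total"] * merged[col]
    return merged


def _life_expectancy_map(life_table: pd.DataFrame) -> dict[str, float]:
    required = {"age_band", "life_expectancy_years"}
    if not required <= set(life_table.columns):
        raise ValueError(f"life table must have columns {sorted(required)}")
    if (life_table["life_expectancy_years"] <= 0).any():
        raise ValueError("life expectancy must be strictly positive")
    return dict(
        zip(life_table["age_band"], life_table["life_expectancy_years"].astype(float))
    )


def yll(deaths: pd.DataFrame, life_table: pd.DataFrame) -> pd.DataFrame:
    """Years of life lost: deaths x residual life expectancy at the age band."""
    e_map = _life_expectancy_map(life_table)
    missing = set(deaths.loc[deaths["deaths_total"] > 0, "age_band"]) - set(e_map)
    if missing:
        raise ConfigurationError(f"life table has no entry for age band(s) {sorted(missing)}")
    out = deaths.copy()
    out["yll_total"] = out["deaths_total"] * out["age_band"].map(e_map).fillna(0.0)
    return out


def yld(yld_inputs: pd.DataFrame) -> pd.DataFrame:
    """Years lived with disability per stratum:
    population x sum over sequelae of prevalence x disability weight."""
    required = set(_KEY) | set(YLD_PREV_COLUMNS) | set(YLD_DW_COLUMNS) | {"population"}
    missing = required - set(yld_inputs.columns)
    if missing:
        raise ValueError(f"YLD inputs missing columns: {sorted(missing)}")
    df = yld_inputs.copy()
    for col in YLD_DW_COLUMNS:
        vals = df[col].astype(float)
        if ((vals <= 0) | (vals >= 1)).any():
            raise ValueError(f"disability weights must lie strictly in (0, 1): {col}")
    for col in YLD_PREV_COLUMNS:
        vals = df[col].astype(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"sequela prevalences must lie in [0, 1]: {col}")
    if (df["population"] < 0).any():
        raise ValueError("population counts must be non-negative")
    total = np.zeros(len(df))
    for prev_col, dw_col in zip(YLD_PREV_COLUMNS, YLD_DW_COLUMNS):
        total += df[prev_col].to_numpy(float) * df[dw_col].to_numpy(float)
    out = df[_KEY].copy()
    out["yld_total"] = df["population"].to_numpy(float) * total
    return out


def assemble_burden(
    deaths: pd.DataFrame,
    life_table: pd.DataFrame,
    yld_inputs: pd.DataFrame | None,
    paf: pd.DataFrame,
) -> pd.DataFrame:
    """Full burden table per site x sex x age band.

    Columns: total and attributable deaths, YLL, YLD and DALY, with per-level
    splits for deaths and DALYs. DALY = YLL + YLD by construction, and the
    attributable DALY is the sum of attributable YLL and YLD, each obtained by
    multiplying the total by the same sex-level PAF.
    """
    work = attributable_deaths(deaths, paf)
    work = yll(work, life_table)

    if yld_inputs is None:
        work["yld_total"] = 0.0
    else:
        yld_df = yld(yld_inputs)
        # YLD rows for sites outside the analysed config are non-target inputs
        yld_df = yld_df[yld_df["site"].isin(set(work["site"]))]
        extra = set(map(tuple, yld_df[_KEY].to_numpy())) - set(
            map(tuple, work[_KEY].to_numpy())
        )
        if extra:
            raise ConfigurationError(
                f"YLD inputs contain strata unknown to the death grid: {sorted(extra)[:5]}"
            )
        work = work.merge(yld_df, on=_KEY, how="left").fillna({"yld_total": 0.0})

    work["daly_total"] = work["yll_total"] + work["yld_total"]
    work["yll_attrib"] = work["yll_total"] * work["paf_total"]
    work["yld_attrib"] = work["yld_total"] * work["paf_total"]
    work["daly_attrib"] = work["yll_attrib"] + work["yld_attrib"]
    for lvl, col in zip(EXPOSED_LEVELS, PAF_LEVEL_COLUMNS):
        work[f"daly_attrib_{lvl}"] = work["daly_total"] * work[col]
    return work


MEASURE_COLUMNS = (
    ["deaths_total", "deaths_attrib"]
    + [f"deaths_attrib_{lvl}" for lvl in EXPOSED_LEVELS]
    + ["yll_total", "yll_attrib", "yld_total", "yld_attrib", "daly_total", "daly_attrib"]
    + [f"daly_attrib_{lvl}" for lvl in EXPOSED_LEVELS]
)


def aggregate_burden(burden: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Sum every burden measure over strata, grouped by ``by`` (may be empty
    for a grand total)."""
    cols = [c for c in MEASURE_COLUMNS if c in burden.columns]
    if not by:
        return burden[cols].sum().to_frame().T
    return burden.groupby(list(by), sort=True)[cols].sum().reset_index()
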