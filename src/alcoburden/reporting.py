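"""Render burden results as publication-style tables and level-share summaries.

Display rounding follows the usual convention for national burden tables:
deaths and DALYs to the nearest integer, attributable fractions to the nearest
whole percent. Machine-readable outputs keep full precision; rounding happens
here and only here, which is also why a rendered total can differ from the sum
of its rendered parts by ±1 per rounding step.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .strata import EXPOSED_LEVELS, SEXES

ALL_ROW_LABEL = "All selected cancer types"
_LEVEL_DISPLAY = ("all",) + EXPOSED_LEVELS


def _measure_columns(measure: str) -> tuple[str, dict[str, str]]:
    if measure == "deaths":
        total = "deaths_total"
        attrib = {"all": "deaths_attrib"} | {
            lvl: f"deaths_attrib_{lvl}" for lvl in EXPOSED_LEVELS
        }
    elif measure == "dalys":
        total = "daly_total"
        attrib = {"all": "daly_attrib"} | {
            lvl: f"daly_attrib_{lvl}" for lvl in EXPOSED_LEVELS
        }
    else:
        raise ValueError(f"measure must be 'deaths' or 'dalys', got {measure!r}")
    return total, attrib


def render_burden_table(
    burden: pd.DataFrame, measure: str = "deaths", rounded: bool = True
) -> pd.DataFrame:
    """Site x sex table of attributable burden, one N and PAF column pair per
    (sex, consumption level), with an all-sites summary row first.

    The PAF denominator is the total burden of that site (and, in the summary
    row, of all selected sites combined). Site/sex combinations with no strata
    (e.g. breast in men) render as blanks (NaN).
    """
    total_col, attrib_cols = _measure_columns(measure)
    agg_cols = [total_col] + list(attrib_cols.values())
    per_site = burden.groupby(["site", "sex"], sort=False)[agg_cols].sum()

    sites = list(dict.fromkeys(burden["site"]))
    columns = pd.MultiIndex.from_tuples(
        [(sex, lvl, stat) for sex in SEXES for lvl in _LEVEL_DISPLAY for stat in ("N", "PAF")],
        names=["sex", "level", "stat"],
    )
    table = pd.DataFrame(index=[ALL_ROW_LABEL] + sites, columns=columns, dtype=float)
    table.index.name = "site"

    present = per_site.index.get_level_values("sex")
    totals = {
        sex: (
            per_site.xs(sex, level="sex").sum()
            if sex in present
            else pd.Series(0.0, index=agg_cols)
        )
        for sex in SEXES
    }
    for sex in SEXES:
        for row_label in table.index:
            if row_label == ALL_ROW_LABEL:
                vals = totals[sex]
            elif (row_label, sex) in per_site.index:
                vals = per_site.loc[(row_label, sex)]
            else:
                continue  # inapplicable combination stays blank
            denom = vals[total_col]
            for lvl in _LEVEL_DISPLAY:
                n = vals[attrib_cols[lvl]]
                paf_pct = 100.0 * n / denom if denom > 0 else 0.0
                table.loc[row_label, (sex, lvl, "N")] = n
                table.loc[row_label, (sex, lvl, "PAF")] = paf_pct

    if rounded:
        for col in table.columns:
            table[col] = table[col].round(0)
    return table


def level_share_summary(
    burden: pd.DataFrame, measure: str = "deaths", by: Sequence[str] = ("sex",)
) -> pd.DataFrame:
    """Share of attributable burden per consumption level (shares sum to 1).

    Groups with zero attributable burden are reported as NaN with a warning
    rather than as silent zeros.
    """
    _, attrib_cols = _measure_columns(measure)
    level_cols = [attrib_cols[lvl] for lvl in EXPOSED_LEVELS]
    grouped = (
        burden.groupby(list(by), sort=True)[[attrib_cols["all"]] + level_cols].sum()
        if by
        else burden[[attrib_cols["all"]] + level_cols].sum().to_frame().T
    )
    total = grouped[attrib_cols["all"]]
    zero = total == 0
    if zero.any():
        warnings.warn(
            f"zero attributable {measure} in {int(zero.sum())} group(s); "
            "level shares undefined",
            UserWarning,
            stacklevel=2,
        )
    out = grouped.reset_index() if by else grouped.reset_index(drop=True)
    for lvl in EXPOSED_LEVELS:
        share = grouped[attrib_cols[lvl]].to_numpy(float) / np.where(zero, np.nan, total)
        out[f"share_{lvl}"] = share
    return out
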