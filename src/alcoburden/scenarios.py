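"""Counterfactual consumption-distribution scenarios.

A scenario moves the entire population mass of one or more consumption
categories to a lower category, simultaneously (every source proportion is
taken from the *baseline* table). Shifted drinkers adopt the destination
category's relative risk wholesale. Prevented burden is the difference
between baseline and counterfactual attributable burden, reported absolutely
and as a percentage of the baseline attributable burden.

Predefined scenarios: heavy drinkers become moderate; moderate become light;
both shifts combined; and full abstention (all drinkers become non-drinkers),
which by the definition of the attributable fraction prevents exactly 100 %
of the attributable burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

from .burden import assemble_burden
from .paf_engine import paf_table
from .risk_inputs import CancerSite
from .strata import HEAVY, LEVEL_ORDER, LEVELS, LIGHT, MODERATE, NON_DRINKER


class ScenarioSpec(BaseModel):
    """A named map source level -> destination level (reductions only)."""

    name: str
    shifts: dict[str, str] = {}

    @field_validator("shifts")
    @classmethod
    def _known_levels(cls, shifts: dict[str, str]) -> dict[str, str]:
        for src, dst in shifts.items():
            if src not in LEVELS or dst not in LEVELS:
                raise ValueError(f"unknown consumption level in shift {src!r} -> {dst!r}")
        return shifts

    @model_validator(mode="after")
    def _downward_only(self) -> "ScenarioSpec":
        for src, dst in self.shifts.items():
            if LEVEL_ORDER[dst] >= LEVEL_ORDER[src]:
                raise ValueError(
                    f"scenario {self.name!r}: shift {src} -> {dst} does not reduce consumption"
                )
        return self


HEAVY_TO_MODERATE = ScenarioSpec(name="heavy_to_moderate", shifts={HEAVY: MODERATE})
MODERATE_TO_LIGHT = ScenarioSpec(name="moderate_to_light", shifts={MODERATE: LIGHT})
COMBINED = ScenarioSpec(name="combined", shifts={HEAVY: MODERATE, MODERATE: LIGHT})
FULL_ABSTENTION = ScenarioSpec(
    name="full_abstention",
    shifts={LIGHT: NON_DRINKER, MODERATE: NON_DRINKER, HEAVY: NON_DRINKER},
)
PREDEFINED: dict[str, ScenarioSpec] = {
    s.name: s for s in (HEAVY_TO_MODERATE, MODERATE_TO_LIGHT, COMBINED, FULL_ABSTENTION)
}


def apply_scenario(prevalence: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Apply the shift map simultaneously to every stratum of a prevalence
    table; proportions still sum to 1 per stratum."""
    missing = set(LEVELS) - set(prevalence.columns)
    if missing:
        raise ValueError(f"prevalence table missing level columns: {sorted(missing)}")
    out = prevalence.copy()
    baseline = {lvl: prevalence[lvl].to_numpy(float) for lvl in LEVELS}
    for lvl in LEVELS:
        mass = np.zeros(len(prevalence)) if lvl in spec.shifts else baseline[lvl].copy()
        for src, dst in spec.shifts.items():
            if dst == lvl:
                mass = mass + baseline[src]
        out[lvl] = mass
    return out


@dataclass
class PipelineInputs:
    """Everything needed to evaluate the burden pipeline end to end."""

    prevalence: pd.DataFrame  # sex-level prevalence table
    rr: pd.DataFrame
    sites: Sequence[CancerSite]
    deaths: pd.DataFrame  # site x sex x age band grid with deaths_total
    life_table: pd.DataFrame
    yld_inputs: pd.DataFrame | None = None

    def burden(self, prevalence: pd.DataFrame | None = None) -> pd.DataFrame:
        prev = self.prevalence if prevalence is None else prevalence
        paf = paf_table(prev, self.rr, self.sites)
        return assemble_burden(self.deaths, self.life_table, self.yld_inputs, paf)


@dataclass
class ScenarioResult:
    name: str
    prevented_deaths: float
    prevented_dalys: float
    pct_deaths_prevented: float
    pct_dalys_prevented: float
    baseline_attrib_deaths: float = field(repr=False, default=float("nan"))
    baseline_attrib_dalys: float = field(repr=False, default=float("nan"))


def evaluate_scenario(inputs: PipelineInputs, spec: ScenarioSpec) -> ScenarioResult:
    """Recompute PAFs and burden under the shifted prevalence and report the
    prevented attributable deaths and DALYs."""
    base = inputs.burden()
    shifted = inputs.burden(apply_scenario(inputs.prevalence, spec))

    base_deaths = base["deaths_attrib"].sum()
    base_dalys = base["daly_attrib"].sum()
    prevented_deaths = base_deaths - shifted["deaths_attrib"].sum()
    prevented_dalys = base_dalys - shifted["daly_attrib"].sum()

    def pct(prevented, baseline):
        if baseline == 0:
            warnings.warn(
                f"scenario {spec.name!r}: baseline attributable burden is zero; "
                "prevented percentage undefined",
                UserWarning,
                stacklevel=3,
            )
            return float("nan")
        return 100.0 * prevented / baseline

    return ScenarioResult(
        name=spec.name,
        prevented_deaths=float(prevented_deaths),
        prevented_dalys=float(prevented_dalys),
        pct_deaths_prevented=pct(prevented_deaths, base_deaths),
        pct_dalys_prevented=pct(prevented_dalys, base_dalys),
        baseline_attrib_deaths=float(base_deaths),
        baseline_attrib_dalys=float(base_dalys),
    )


def evaluate_scenarios(
    inputs: PipelineInputs, specs: Sequence[ScenarioSpec]
) -> pd.DataFrame:
    rows = [evaluate_scenario(inputs, s).__dict__ for s in specs]
    return pd.DataFrame(rows)
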