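"""End-to-end orchestration: simulate or load inputs, estimate prevalence,
compute PAFs, assemble burden, evaluate scenarios, and write reports.

Every output of :func:`run_all` is a plain CSV (full precision alongside the
display-rounded report tables) plus a text run log and a JSON metadata stamp
carrying the seed and a hash of the configuration, so identical configs
reproduce byte-identical output directories.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .burden import filter_and_group
from .errors import StageError
from .exposure import weighted_prevalence
from .paf_engine import paf_table
from .reporting import level_share_summary, render_burden_table
from .risk_inputs import load_risk_config
from .scenarios import PREDEFINED, PipelineInputs, ScenarioSpec, evaluate_scenarios
from .synthetic_data import (
    default_ground_truth,
    generate_life_table,
    generate_registry,
    generate_survey,
    generate_yld_table,
)


class RunConfig(BaseModel):
    """Everything a full run needs; all inputs optional (simulated if absent)."""

    seed: int = 0
    out_dir: str = "alcoburden_run"
    n_respondents: int = Field(29_224, ge=1)
    year: int = 2018
    grams_per_unit: float = Field(14.0, gt=0)
    monthly_divisor: float = Field(30.44, gt=0)
    extended_sites: bool = False
    scenarios: list[str] = ["heavy_to_moderate", "moderate_to_light", "combined"]
    #: optional paths to pre-existing inputs; simulated when None
    survey_path: str | None = None
    registry_path: str | None = None
    life_table_path: str | None = None
    yld_path: str | None = None
    rr_config_path: str | None = None

    def config_hash(self) -> str:
        # the output location is not part of the scientific configuration
        payload = json.dumps(
            self.model_dump(mode="json", exclude={"out_dir"}), sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def scenario_specs(self) -> list[ScenarioSpec]:
        specs = []
        for name in self.scenarios:
            if name not in PREDEFINED:
                raise ValueError(
                    f"unknown scenario {name!r}; choose from {sorted(PREDEFINED)}"
                )
            specs.append(PREDEFINED[name])
        return specs


@contextmanager
def _stage(name: str, log: list[str]):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, str(exc)) from exc
    log.append(f"[{name}] ok")


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    with _stage("risk_inputs", log):
        rr, sites = load_risk_config(
            config.rr_config_path, extended=config.extended_sites
        )
        log.append(f"[risk_inputs] {len(rr)} RR entries, {len(sites)} sites")

    with _stage("synthetic_data", log):
        truth = default_ground_truth(seed=config.seed)
        survey = (
            pd.read_csv(config.survey_path)
            if config.survey_path
            else generate_survey(truth, config.n_respondents)
        )
        registry = (
            pd.read_csv(config.registry_path, dtype={"sex": "string"})
            if config.registry_path
            else generate_registry(truth, year=config.year)
        )
        life_table = (
            pd.read_csv(config.life_table_path)
            if config.life_table_path
            else generate_life_table()
        )
        yld_inputs = (
            pd.read_csv(config.yld_path) if config.yld_path else generate_yld_table(truth)
        )
        log.append(f"[synthetic_data] survey n={len(survey)}, registry n={len(registry)}")

    with _stage("exposure", log):
        prevalence = weighted_prevalence(
            survey,
            by=("sex",),
            grams_per_unit=config.grams_per_unit,
            monthly_divisor=config.monthly_divisor,
        )
        prevalence_by_age = weighted_prevalence(
            survey,
            by=("sex", "age_band"),
            grams_per_unit=config.grams_per_unit,
            monthly_divisor=config.monthly_divisor,
        )

    with _stage("paf_engine", log):
        paf = paf_table(prevalence, rr, sites)
        log.append(f"[paf_engine] {len(paf)} (site, sex) PAFs")

    with _stage("burden", log):
        deaths, exclusions = filter_and_group(registry, sites)
        inputs = PipelineInputs(
            prevalence=prevalence,
            rr=rr,
            sites=sites,
            deaths=deaths,
            life_table=life_table,
            yld_inputs=yld_inputs,
        )
        burden = inputs.burden()
        log.append(
            "[burden] records read={0.n_input} excluded_missing={0.n_missing_excluded} "
            "malformed={0.n_malformed} non_target={0.n_nontarget} "
            "grouped={0.n_grouped}".format(exclusions)
        )
        log.append(
            f"[burden] attributable deaths={burden['deaths_attrib'].sum():.1f} "
            f"DALYs={burden['daly_attrib'].sum():.1f}"
        )

    with _stage("scenarios", log):
        scenario_results = evaluate_scenarios(inputs, config.scenario_specs())
        for row in scenario_results.itertuples():
            log.append(
                f"[scenarios] {row.name}: prevented deaths={row.prevented_deaths:.1f} "
                f"({row.pct_deaths_prevented:.1f}%), "
                f"DALYs={row.prevented_dalys:.1f} ({row.pct_dalys_prevented:.1f}%)"
            )

    with _stage("reporting", log):
        report_deaths = render_burden_table(burden, "deaths")
        report_dalys = render_burden_table(burden, "dalys")
        shares = level_share_summary(burden, "deaths")

        meta = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.model_dump(mode="json", exclude={"out_dir"}),
        }
        survey.to_csv(out / "survey.csv", index=False)
        registry.to_csv(out / "registry.csv", index=False)
        life_table.to_csv(out / "life_table.csv", index=False)
        yld_inputs.to_csv(out / "yld_inputs.csv", index=False)
        prevalence.to_csv(out / "prevalence.csv", index=False)
        prevalence_by_age.to_csv(out / "prevalence_by_age.csv", index=False)
        paf.to_csv(out / "paf.csv", index=False)
        burden.to_csv(out / "burden.csv", index=False)
        scenario_results.to_csv(out / "scenarios.csv", index=False)
        report_deaths.to_csv(out / "report_deaths.csv")
        report_dalys.to_csv(out / "report_dalys.csv")
        shares.to_csv(out / "level_shares.csv", index=False)
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out
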