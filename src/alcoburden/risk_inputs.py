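"""Relative-risk table and cancer-site (ICD-10) configuration.

Relative risks are configuration data, not code: a structured YAML file holds
one record per (site, sex, exposed level) with the RR and a statistical-
significance flag. Non-significant associations are censored to RR = 1 before
any attribution, following standard comparative-risk-assessment practice when
an association is not established at a given dose. Non-drinkers are the
implicit reference (RR = 1) and are never stored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .strata import EXPOSED_LEVELS, NON_DRINKER, SEXES, normalize_sex

logger = logging.getLogger(__name__)

RR_COLUMNS = ("site", "sex", "level", "rr", "significant")

_ICD_RE = re.compile(r"^[A-Z]\d{2}$")


@dataclass(frozen=True)
class CancerSite:
    """One cancer site: name, its 3-character ICD-10 code set, the sexes it
    applies to, and whether it belongs to the core (established) set."""

    name: str
    icd10_codes: tuple[str, ...]
    sexes: tuple[str, ...] = SEXES
    in_core_set: bool = True

    def __post_init__(self):
        if not self.icd10_codes:
            raise ConfigurationError(f"site {self.name!r} has no ICD-10 codes")
        for code in self.icd10_codes:
            if not _ICD_RE.match(code):
                raise ConfigurationError(
                    f"site {self.name!r}: invalid ICD-10 code {code!r}"
                )


def expand_icd_range(spec: str) -> tuple[str, ...]:
    """Expand an ICD-10 spec like 'C18-C20' (or a single 'C15') into the tuple
    of 3-character codes it covers."""
    spec = spec.strip().upper()
    if "-" in spec:
        lo, hi = (s.strip() for s in spec.split("-", 1))
        if not (_ICD_RE.match(lo) and _ICD_RE.match(hi)) or lo[0] != hi[0]:
            raise ConfigurationError(f"invalid ICD-10 range {spec!r}")
        start, stop = int(lo[1:]), int(hi[1:])
        if stop < start:
            raise ConfigurationError(f"invalid ICD-10 range {spec!r}")
        return tuple(f"{lo[0]}{i:02d}" for i in range(start, stop + 1))
    if not _ICD_RE.match(spec):
        raise ConfigurationError(f"invalid ICD-10 code {spec!r}")
    return (spec,)


def validate_sites(sites: Sequence[CancerSite]) -> None:
    """Code sets must be pairwise disjoint across sites."""
    seen: dict[str, str] = {}
    for site in sites:
        for code in site.icd10_codes:
            if code in seen:
                raise ConfigurationError(
                    f"ICD-10 code {code} assigned to both {seen[code]!r} and {site.name!r}"
                )
            seen[code] = site.name


def code_to_site_map(sites: Sequence[CancerSite]) -> dict[str, str]:
    validate_sites(sites)
    return {code: s.name for s in sites for code in s.icd10_codes}


def validate_rr_table(rr: pd.DataFrame) -> pd.DataFrame:
    missing = set(RR_COLUMNS) - set(rr.columns)
    if missing:
        raise ConfigurationError(f"RR table missing columns: {sorted(missing)}")
    rr = rr.copy()
    rr["sex"] = rr["sex"].map(normalize_sex)
    if rr["sex"].isna().any():
        raise ConfigurationError("RR table contains unrecognised sex codes")
    if (rr["level"] == NON_DRINKER).any():
        raise ConfigurationError(
            "RR table must not store the non-drinker reference level (RR=1 implicit)"
        )
    if not rr["level"].isin(EXPOSED_LEVELS).all():
        bad = sorted(set(rr["level"]) - set(EXPOSED_LEVELS))
        raise ConfigurationError(f"unknown consumption level(s) in RR table: {bad}")
    if (rr["rr"] <= 0).any() or rr["rr"].isna().any():
        raise ConfigurationError("relative risks must be positive")
    if rr.duplicated(subset=["site", "sex", "level"]).any():
        raise ConfigurationError("duplicate (site, sex, level) entries in RR table")
    rr["significant"] = rr["significant"].astype(bool)
    return rr.reset_index(drop=True)


def censor_nonsignificant(rr: pd.DataFrame) -> pd.DataFrame:
    """Set RR to exactly 1 wherever the association is flagged non-significant;
    significant entries pass through unchanged."""
    rr = validate_rr_table(rr)
    rr.loc[~rr["significant"], "rr"] = 1.0
    return rr


def _find_site(sites: Sequence[CancerSite], name: str) -> CancerSite:
    for s in sites:
        if s.name == name:
            return s
    raise ConfigurationError(f"unknown cancer site {name!r}")


def lookup_rr(
    rr: pd.DataFrame,
    site: str,
    sex: str,
    level: str,
    sites: Sequence[CancerSite] | None = None,
) -> float:
    """Censored relative risk for one (site, sex, level).

    The non-drinker reference always returns 1.0. A missing (site, sex, level)
    entry returns 1.0 with a logged warning (absent association = no effect).
    An inapplicable site/sex combination (e.g. breast x male under the default
    config) raises :class:`ConfigurationError`.
    """
    sex_n = normalize_sex(sex)
    if sex_n is None:
        raise ConfigurationError(f"unrecognised sex {sex!r}")
    if sites is None:
        sites = default_sites(extended=True)
    site_cfg = _find_site(sites, site)
    if sex_n not in site_cfg.sexes:
        raise ConfigurationError(f"site {site!r} is not applicable to sex {sex_n!r}")
    if level == NON_DRINKER:
        return 1.0
    if level not in EXPOSED_LEVELS:
        raise ConfigurationError(f"unknown consumption level {level!r}")
    censored = censor_nonsignificant(rr)
    hit = censored.loc[
        (censored["site"] == site)
        & (censored["sex"] == sex_n)
        & (censored["level"] == level),
        "rr",
    ]
    if hit.empty:
        logger.warning(
            "no RR entry for (%s, %s, %s); assuming RR = 1", site, sex_n, level
        )
        return 1.0
    return float(hit.iloc[0])


def rr_vector(rr: pd.DataFrame, site: str, sex: str,
              sites: Sequence[CancerSite] | None = None) -> np.ndarray:
    """Censored RRs over the exposed levels (light, moderate, heavy)."""
    return np.array(
        [lookup_rr(rr, site, sex, lvl, sites=sites) for lvl in EXPOSED_LEVELS]
    )


def _parse_config(doc: dict) -> tuple[pd.DataFrame, list[CancerSite]]:
    sites = []
    for entry in doc.get("sites", []):
        codes: tuple[str, ...] = ()
        for spec in entry["icd10"]:
            codes += expand_icd_range(str(spec))
        sites.append(
            CancerSite(
                name=entry["name"],
                icd10_codes=codes,
                sexes=tuple(normalize_sex(s) for s in entry.get("sexes", SEXES)),
                in_core_set=bool(entry.get("core", True)),
            )
        )
    validate_sites(sites)
    rr = validate_rr_table(pd.DataFrame(doc.get("relative_risks", [])))
    known = {s.name for s in sites}
    unknown = set(rr["site"]) - known
    if unknown:
        raise ConfigurationError(f"RR entries for unconfigured site(s): {sorted(unknown)}")
    return rr, sites


def load_risk_config(path: str | Path | None = None,
                     extended: bool = False) -> tuple[pd.DataFrame, list[CancerSite]]:
    """Load (RR table, site list) from YAML; ``path=None`` loads the packaged
    defaults. ``extended=False`` restricts both to the core site set."""
    if path is None:
        text = (resources.files("alcoburden") / "data" / "default_risk.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"risk config file not found: {path}")
        text = path.read_text()
    rr, sites = _parse_config(yaml.safe_load(text))
    if not extended:
        sites = [s for s in sites if s.in_core_set]
        rr = rr[rr["site"].isin({s.name for s in sites})].reset_index(drop=True)
    return rr, sites


def default_sites(extended: bool = False) -> list[CancerSite]:
    return load_risk_config(extended=extended)[1]


def default_rr_table(extended: bool = False) -> pd.DataFrame:
    return load_risk_config(extended=extended)[0]
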