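"""Population attributable fraction (PAF) for a multi-level exposure.

For exposure levels i = 1..n with population proportions P_i and relative
risks RR_i against the unexposed reference (the remaining population mass),
the Levin-type attributable fraction is

    PAF = sum_i P_i (RR_i - 1) / (sum_i P_i (RR_i - 1) + 1)

the proportional reduction in deaths (or DALYs) that would occur if exposure
were reduced to zero. The level-wise decomposition shares the common
denominator,

    PAF_i = P_i (RR_i - 1) / (sum_j P_j (RR_j - 1) + 1)

which is the unique decomposition under which the level contributions add up
exactly to the total — the form implied by additive per-level burden tables.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .exposure import prevalence_vector
from .risk_inputs import CancerSite, censor_nonsignificant, rr_vector
from .strata import EXPOSED_LEVELS

PAF_LEVEL_COLUMNS = tuple(f"paf_{lvl}" for lvl in EXPOSED_LEVELS)


def _validate(p, rr) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if p.shape != rr.shape or p.ndim != 1:
        raise ValueError("p and rr must be 1-d arrays of equal length")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("exposure proportions must lie in [0, 1]")
    if p.sum() > 1 + 1e-12:
        raise ValueError("exposed proportions sum to more than 1")
    if np.any(rr <= 0):
        raise ValueError("relative risks must be positive")
    return p, rr


def paf_terms(p, rr) -> np.ndarray:
    """The per-level excess terms P_i (RR_i - 1)."""
    p, rr = _validate(p, rr)
    return p * (rr - 1.0)


def paf_total(p, rr) -> float:
    """Total attributable fraction over all exposed levels."""
    terms = paf_terms(p, rr)
    denom = terms.sum() + 1.0
    if denom <= 0:
        raise ValueError("degenerate inputs: PAF denominator is non-positive")
    return float(terms.sum() / denom)


def paf_by_level(p, rr) -> np.ndarray:
    """Level-wise attributable fractions; they sum to ``paf_total(p, rr)``."""
    terms = paf_terms(p, rr)
    denom = terms.sum() + 1.0
    if denom <= 0:
        raise ValueError("degenerate inputs: PAF denominator is non-positive")
    return terms / denom


def paf_table(
    prevalence: pd.DataFrame,
    rr: pd.DataFrame,
    sites: Sequence[CancerSite],
) -> pd.DataFrame:
    """One PAF row per applicable (site, sex).

    ``prevalence`` is a sex-level prevalence table (one row per sex with the
    four level proportions). RRs are censored before use. Sites not applicable
    to a sex (e.g. breast for men) produce no row.
    """
    rr = censor_nonsignificant(rr)
    rows = []
    for site in sites:
        for sex in site.sexes:
            try:
                p = prevalence_vector(prevalence, sex)
            except ValueError as exc:
                raise ConfigurationError(
                    f"prevalence stratum missing for sex {sex!r} (site {site.name!r})"
                ) from exc
            r = rr_vector(rr, site.name, sex, sites=sites)
            by_level = paf_by_level(p, r)
            rows.append(
                {
                    "site": site.name,
                    "sex": sex,
                    **dict(zip(PAF_LEVEL_COLUMNS, by_level)),
                    "paf_total": paf_total(p, r),
                    "n_levels": len(EXPOSED_LEVELS),
                }
            )
    return pd.DataFrame(rows)
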