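"""Indirect age-sex standardisation and incidence rates.

Indirect standardisation applies reference (study-wide) stratum-specific
rates to each area's stratum populations, giving the expected count

    E_i = sum_s pop_{i,s} * r_s,    r_s = total cases_s / total pop_s.

With an internal reference the expected counts calibrate exactly:
sum_i E_i = sum_i O_i.  Incidence confidence intervals use the exact Poisson
(gamma-quantile) method, which remains valid at the small per-area counts
typical of rare childhood disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import StratifiedCounts

__all__ = ["ExpectedCounts", "IncidenceEstimate", "expected_counts", "incidence_rate"]


@dataclass
class ExpectedCounts:
    """Per-area expected counts plus the reference rates that produced them."""

    expected: pd.Series  # E_i, indexed by area_id
    reference_rates: pd.Series  # r_s per stratum (cases per person per period)

    def __post_init__(self) -> None:
        if (self.expected < 0).any():
            raise ValueError("expected counts must be non-negative")


def expected_counts(counts: StratifiedCounts) -> ExpectedCounts:
    """Indirectly standardised expected counts with an internal reference.

    Raises ``ValueError`` for a stratum with zero total population but
    nonzero cases; strata with zero population and zero cases contribute a
    zero rate.
    """
    pop = counts.population
    cas = counts.cases
    tot_pop = pop.sum(axis=0).astype(float)
    tot_cas = cas.sum(axis=0).astype(float)
    bad = (tot_pop == 0) & (tot_cas > 0)
    if bad.any():
        raise ValueError(
            f"strata with zero reference population but nonzero cases: {list(tot_pop.index[bad])}"
        )
    rates = tot_cas.divide(tot_pop).where(tot_pop > 0, 0.0)
    E = (pop * rates).sum(axis=1)
    E.name = "E"
    rates.name = "rate"
    return ExpectedCounts(E, rates)


@dataclass
class IncidenceEstimate:
    """Incidence per 100,000 person-years with an exact Poisson CI."""

    rate: float
    ci_low: float
    ci_high: float
    cases: int
    person_years: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError("CI must bracket the rate")


def incidence_rate(cases: int, person_years: float, level: float = 0.95) -> IncidenceEstimate:
    """Incidence per 100,000 person-years, exact Poisson (gamma) CI.

    The lower bound is the gamma(cases) quantile at (1-level)/2 (0 when
    cases = 0) and the upper the gamma(cases+1) quantile at (1+level)/2,
    scaled by person-years.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if cases < 0:
        raise ValueError("cases must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    scale = 1e5 / person_years
    lo = 0.0 if cases == 0 else float(stats.gamma.ppf(alpha / 2, cases)) * scale
    hi = float(stats.gamma.ppf(1 - alpha / 2, cases + 1)) * scale
    return IncidenceEstimate(cases * scale, lo, hi, int(cases), float(person_years), level)
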