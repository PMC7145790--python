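"""Core tabular containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CODINGS = ("continuous", "percent", "decile", "class")


@dataclass
class StratifiedCounts:
    """Per-area, per-stratum population and case counts.

    ``population`` and ``cases`` are DataFrames indexed by ``area_id`` with one
    column per stratum (e.g. ``age0-4_F``).  Strata must be identical across
    areas (shared columns), all counts non-negative.
    """

    population: pd.DataFrame
    cases: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.population.columns) != list(self.cases.columns):
            raise ValueError("population and cases must share identical strata")
        if list(self.population.index) != list(self.cases.index):
            raise ValueError("population and cases must share identical areas")
        if (self.population.to_numpy() < 0).any() or (self.cases.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def area_ids(self) -> list[str]:
        return [str(a) for a in self.population.index]

    @property
    def strata(self) -> list[str]:
        return list(self.population.columns)

    def observed(self) -> pd.Series:
        """Total observed cases per area (O_i)."""
        return self.cases.sum(axis=1)

    def total_population(self) -> pd.Series:
        return self.population.sum(axis=1)


@dataclass
class ExposureMatrix:
    """Per-area covariate values with per-variable metadata.

    ``values``: DataFrame indexed by area_id, one column per variable
    (NaN = missing for that area).  ``coding`` maps variable name to one of
    ``continuous | percent | decile | class``.  ``units`` is free text.
    """

    values: pd.DataFrame
    coding: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var in self.values.columns:
            c = self.coding.setdefault(var, "continuous")
            if c not in VALID_CODINGS:
                raise ValueError(f"unknown coding {c!r} for variable {var!r}")
            self.units.setdefault(var, "")
        self._check_ranges()

    def _check_ranges(self) -> None:
        for var, c in self.coding.items():
            if var not in self.values.columns:
                continue
            x = self.values[var].dropna()
            if c == "percent" and ((x < 0) | (x > 100)).any():
                raise ValueError(f"percent variable {var!r} outside [0, 100]")
            if c == "decile":
                if not np.isin(x.to_numpy(), np.arange(1, 11)).all():
                    raise ValueError(f"decile variable {var!r} outside 1..10")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]
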