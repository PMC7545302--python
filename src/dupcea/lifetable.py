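"""Age-dependent annual all-cause mortality.

The default model is a Gompertz hazard fit through two anchor points of US
all-cause mortality — 0.87%/yr at age 60 and 0.18%/yr at age 45 — giving
h(a) = h60 * exp(slope * (a - 60)) with slope = ln(0.0087/0.0018)/15
(~0.1050 per year). Annual probabilities are clipped to 1 and death is
certain at ``max_age``. A tabulated life table (two-column CSV: age,
annual probability of death) can be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import MortalitySettings, ParameterError

__all__ = [
    "MortalityModel",
    "GompertzMortality",
    "TableMortality",
    "build_mortality",
    "annual_mortality",
    "life_expectancy",
]


@dataclass(frozen=True)
class GompertzMortality:
    """Exponential-in-age annual mortality anchored at ``anchor_age``."""

    h_anchor: float = 0.0087
    anchor_age: float = 60.0
    slope: float = math.log(0.0087 / 0.0018) / 15.0
    max_age: float = 100.0

    @classmethod
    def from_anchors(
        cls,
        age1: float,
        rate1: float,
        age2: float,
        rate2: float,
        max_age: float = 100.0,
    ) -> "GompertzMortality":
        if age1 == age2:
            raise ParameterError("mortality anchors must be at distinct ages")
        if not (0 < rate1 < 1 and 0 < rate2 < 1):
            raise ParameterError("mortality anchor rates must be in (0, 1)")
        slope = math.log(rate1 / rate2) / (age1 - age2)
        return cls(h_anchor=rate1, anchor_age=age1, slope=slope, max_age=max_age)

    def annual_probability(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ParameterError("age must be non-negative")
        h = self.h_anchor * np.exp(self.slope * (age - self.anchor_age))
        h = np.clip(h, 0.0, 1.0)
        h = np.where(age >= self.max_age, 1.0, h)
        return float(h) if h.ndim == 0 else h


@dataclass(frozen=True)
class TableMortality:
    """Step-function mortality from a (age, annual probability) table."""

    ages: np.ndarray
    probs: np.ndarray
    max_age: float = 100.0

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if ages.ndim != 1 or ages.shape != probs.shape or ages.size == 0:
            raise ParameterError("life table must be two equal-length columns")
        if np.any(np.diff(ages) <= 0):
            raise ParameterError("life-table ages must be strictly increasing")
        if np.any((probs < 0) | (probs > 1)):
            raise ParameterError("life-table probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def from_csv(cls, path: str, max_age: float = 100.0) -> "TableMortality":
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(ages=data[:, 0], probs=data[:, 1], max_age=max_age)

    def annual_probability(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ParameterError("age must be non-negative")
        idx = np.clip(np.searchsorted(self.ages, age, side="right") - 1, 0, self.ages.size - 1)
        h = self.probs[idx]
        h = np.where(age >= self.max_age, 1.0, h)
        return float(h) if h.ndim == 0 else h


MortalityModel = GompertzMortality | TableMortality


def build_mortality(settings: MortalitySettings) -> MortalityModel:
    """Construct the mortality model described by a parameter set."""
    if settings.kind == "gompertz":
        return GompertzMortality.from_anchors(
            settings.anchor_age,
            settings.rate_at_anchor,
            settings.low_anchor_age,
            settings.rate_at_low_anchor,
            max_age=settings.max_age,
        )
    if settings.kind == "table":
        if not settings.table_path:
            raise ParameterError("mortality.kind 'table' requires mortality.table_path")
        return TableMortality.from_csv(settings.table_path, max_age=settings.max_age)
    raise ParameterError(f"unknown mortality model kind {settings.kind!r}")


def annual_mortality(age, model: MortalityModel):
    """Annual probability of death at ``age`` (scalar or array)."""
    return model.annual_probability(age)


def life_expectancy(model: MortalityModel, start_age: float, discount_rate: float = 0.0) -> float:
    """(Discounted) remaining life expectancy in whole-year cycles.

    Uses the simulation's accounting convention: a patient alive at the
    start of a cycle accrues that full year and faces the mortality draw
    at the end of the cycle.
    """
    horizon = int(math.ceil(model.max_age - start_age)) + 1
    survival = 1.0
    total = 0.0
    for t in range(horizon):
        total += survival / (1.0 + discount_rate) ** t
        survival *= 1.0 - float(model.annual_probability(start_age + t))
        if survival < 1e-15:
            break
    return total
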