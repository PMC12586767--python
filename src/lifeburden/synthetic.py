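"""Synthetic aggregate cohorts with realistic cause-specific hazard shapes.

Generates long-format count tables whose death counts are Poisson draws
around closed-form age-specific hazards, so every downstream stage can be
tested against a known truth without external data.  The default scenario
is illustrative: a unimodal overdose-style hazard peaking in the late
40s, a rising-then-plateauing hepatitis-style hazard, three disease
hazards rising monotonically with age, and a residual category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .rates import AGE_END, AGE_START, DEFAULT_AGES, AgeCauseTable

#: The six default cause categories.
DEFAULT_CAUSES = (
    "smoking_related",
    "other_cancers",
    "cardiovascular",
    "drug_poisoning",
    "viral_hepatitis",
    "other",
)

_SHAPES = ("constant", "log-linear", "unimodal", "plateau")


@dataclass(frozen=True)
class HazardSpec:
    """Closed-form age-specific hazard for one cause.

    Shapes and their parameters (rates in deaths per person-year):

    ``constant``
        ``level``.
    ``log-linear``
        ``intercept``, ``slope``: rate = exp(intercept + slope * age).
    ``unimodal``
        ``peak_age``, ``peak_rate``, ``curvature`` (> 0); quadratic in
        log-rate with a unique interior maximum at ``peak_age``.
    ``plateau``
        ``level``, ``midpoint_age``, ``steepness`` (> 0); logistic rise
        towards ``level``, non-decreasing in age.
    """

    cause: str
    shape: str
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValidationError(f"unknown hazard shape: {self.shape!r}")
        p = self.parameters
        required = {
            "constant": ("level",),
            "log-linear": ("intercept", "slope"),
            "unimodal": ("peak_age", "peak_rate", "curvature"),
            "plateau": ("level", "midpoint_age", "steepness"),
        }[self.shape]
        missing = [k for k in required if k not in p]
        if missing:
            raise ValidationError(f"{self.shape} hazard missing parameters {missing}")
        if self.shape == "constant" and p["level"] <= 0:
            raise ValidationError("constant hazard level must be positive")
        if self.shape == "unimodal":
            if not (AGE_START < p["peak_age"] < AGE_END):
                raise ValidationError("unimodal peak must lie strictly inside the age range")
            if p["curvature"] <= 0 or p["peak_rate"] <= 0:
                raise ValidationError("unimodal curvature and peak rate must be positive")
        if self.shape == "plateau" and (p["steepness"] <= 0 or p["level"] <= 0):
            raise ValidationError("plateau steepness and level must be positive")


def true_rate(spec: HazardSpec, age: float) -> float:
    """Evaluate the closed-form hazard at one age (deaths per person-year)."""
    if not (AGE_START <= age <= AGE_END):
        raise ValidationError(f"age {age} outside modelled range [{AGE_START}, {AGE_END}]")
    return float(rate_array(spec, np.asarray([age]))[0])


def rate_array(spec: HazardSpec, ages: np.ndarray) -> np.ndarray:
    """Vectorised :func:`true_rate` over an age grid (no range check)."""
    ages = np.asarray(ages, dtype=float)
    p = spec.parameters
    if spec.shape == "constant":
        return np.full(len(ages), float(p["level"]))
    if spec.shape == "log-linear":
        return np.exp(p["intercept"] + p["slope"] * ages)
    if spec.shape == "unimodal":
        return p["peak_rate"] * np.exp(-p["curvature"] * (ages - p["peak_age"]) ** 2)
    # plateau
    return p["level"] / (1.0 + np.exp(-p["steepness"] * (ages - p["midpoint_age"])))


@dataclass(frozen=True)
class ExposureSchedule:
    """Person-years of observation per single year of age (18-69)."""

    person_years: np.ndarray

    def __post_init__(self):
        py = np.asarray(self.person_years, dtype=float)
        object.__setattr__(self, "person_years", py)
        if len(py) != len(DEFAULT_AGES):
            raise ValidationError(
                f"schedule must cover {len(DEFAULT_AGES)} ages, got {len(py)}"
            )
        if (py < 0).any() or not np.all(np.isfinite(py)):
            raise ValidationError("person-years must be non-negative and finite")
        if py.sum() <= 0:
            raise ValidationError("at least one age must have positive person-years")

    @property
    def ages(self) -> np.ndarray:
        return DEFAULT_AGES.copy()

    @classmethod
    def default(cls, total_person_years: float = 1_000_000.0) -> "ExposureSchedule":
        """Right-skewed profile concentrating observation in the 30s-40s.

        A gamma-shaped body carries 80% of the observation time; a
        uniform floor carries the rest so boundary ages keep enough
        person-years to anchor the spline fits.
        """
        weights = stats.gamma.pdf(DEFAULT_AGES - AGE_START + 0.5, a=3.5, scale=7.0)
        weights = 0.8 * weights / weights.sum() + 0.2 / len(DEFAULT_AGES)
        return cls(person_years=weights * total_person_years)

    @classmethod
    def uniform(cls, person_years_per_age: float) -> "ExposureSchedule":
        return cls(person_years=np.full(len(DEFAULT_AGES), float(person_years_per_age)))


def default_hazards() -> list[HazardSpec]:
    """Illustrative six-cause hazard set (not calibrated to any cohort).

    The overall premature-death risk implied by these hazards sits in the
    50-70% range; shapes follow the qualitative pattern of high-mortality
    opioid-using cohorts (overdose peak near 47, hepatitis plateau near
    58, smoking-related disease rising steeply with age).
    """
    return [
        HazardSpec(
            "smoking_related",
            "log-linear",
            {"intercept": math.log(2.5e-4) - 0.085 * AGE_START, "slope": 0.085},
        ),
        HazardSpec(
            "other_cancers",
            "log-linear",
            {"intercept": math.log(2e-4) - 0.07 * AGE_START, "slope": 0.07},
        ),
        HazardSpec(
            "cardiovascular",
            "log-linear",
            {"intercept": math.log(2.5e-4) - 0.065 * AGE_START, "slope": 0.065},
        ),
        HazardSpec(
            "drug_poisoning",
            "unimodal",
            {"peak_age": 47.0, "peak_rate": 6e-3, "curvature": 1.2e-3},
        ),
        HazardSpec(
            "viral_hepatitis",
            "plateau",
            {"level": 8e-4, "midpoint_age": 40.0, "steepness": 0.12},
        ),
        HazardSpec(
            "other",
            "log-linear",
            {"intercept": math.log(3.5e-3) - 0.025 * AGE_START, "slope": 0.025},
        ),
    ]


def true_hazard_matrix(specs: Sequence[HazardSpec]) -> dict[str, np.ndarray]:
    """Closed-form hazards per cause on the default age grid."""
    return {s.cause: rate_array(s, DEFAULT_AGES) for s in specs}


def generate_counts(
    specs: Sequence[HazardSpec],
    schedule: ExposureSchedule,
    seed: int,
) -> AgeCauseTable:
    """Draw an aggregate count table with Poisson death counts.

    Counts for (age, cause) are Poisson with mean hazard x person-years;
    one :class:`numpy.random.Generator` seeded by ``seed`` drives every
    draw, so output is fully reproducible.  All-cause counts equal the
    sum over causes by construction (the table stores only the causes).
    """
    causes = [s.cause for s in specs]
    if len(set(causes)) != len(causes):
        raise ValidationError(f"duplicate cause labels: {causes}")
    rng = np.random.default_rng(seed)
    py = schedule.person_years
    deaths = np.empty((len(DEFAULT_AGES), len(specs)))
    for j, spec in enumerate(specs):
        mu = rate_array(spec, DEFAULT_AGES) * py
        deaths[:, j] = rng.poisson(mu)
    return AgeCauseTable.from_arrays(deaths, py, causes, validate=False)


def default_cohort(
    seed: int, total_person_years: float = 1_000_000.0
) -> AgeCauseTable:
    """One draw from the default synthetic scenario."""
    return generate_counts(
        default_hazards(), ExposureSchedule.default(total_person_years), seed
    )
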