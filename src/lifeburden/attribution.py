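"""Exposure attribution: fractions of cause-specific deaths per exposure.

An :class:`AttributionMap` assigns each (exposure, cause) pair a fraction
in [0, 1]; fractions for a cause may not sum above 1 across exposures.
Applying a map to a life table decomposes premature-death risk and
years-of-life-lost into exposure buckets plus an "others" remainder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .lifetable import DEFAULT_HORIZON, LifeTable, yll_weights

#: Label of the residual bucket (burden not attributed to any exposure).
OTHERS = "others"

EXPOSURE_DRUGS = "illegal_drugs"
EXPOSURE_TOBACCO = "tobacco"


class AttributionMap:
    """Fractions of each cause's deaths attributable to each exposure."""

    def __init__(self, fractions: Mapping[str, Mapping[str, float]]):
        self._fractions: dict[str, dict[str, float]] = {
            e: dict(cs) for e, cs in fractions.items()
        }
        by_cause: dict[str, float] = {}
        for exposure, causes in self._fractions.items():
            for cause, f in causes.items():
                if not (0.0 <= f <= 1.0):
                    raise ValidationError(
                        f"fraction for ({exposure!r}, {cause!r}) must be in [0, 1], got {f}"
                    )
                by_cause[cause] = by_cause.get(cause, 0.0) + f
        for cause, total in by_cause.items():
            if total > 1.0 + 1e-12:
                raise ValidationError(
                    f"fractions for cause {cause!r} sum to {total} > 1 across exposures"
                )

    @property
    def exposures(self) -> tuple[str, ...]:
        return tuple(self._fractions)

    @property
    def causes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for causes in self._fractions.values():
            for c in causes:
                seen[c] = None
        return tuple(seen)

    def fraction(self, exposure: str, cause: str) -> float:
        """Attributable fraction; unmapped pairs default to zero."""
        return self._fractions.get(exposure, {}).get(cause, 0.0)

    def eliminated_multiplier(self, cause: str, eliminated: tuple[str, ...]) -> float:
        """Hazard multiplier 1 - sum of eliminated exposures' fractions."""
        mult = 1.0 - sum(self.fraction(e, cause) for e in eliminated)
        if mult < -1e-12:
            raise ValidationError(
                f"eliminated fractions for cause {cause!r} exceed 1"
            )
        return max(mult, 0.0)

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {e: dict(cs) for e, cs in self._fractions.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "AttributionMap":
        """Load from YAML or JSON ({exposure: {cause: fraction}})."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"attribution file {path} must hold a mapping")
        return cls(data)


def default_attribution() -> AttributionMap:
    """The shipped main-analysis map.

    Illegal drugs account for all drug-poisoning and viral-hepatitis
    deaths; tobacco for all smoking-specific (respiratory cancer / COPD)
    deaths, half of cardiovascular deaths and 30% of other cancers.
    """
    return AttributionMap(
        {
            EXPOSURE_DRUGS: {"drug_poisoning": 1.0, "viral_hepatitis": 1.0},
            EXPOSURE_TOBACCO: {
                "smoking_related": 1.0,
                "cardiovascular": 0.5,
                "other_cancers": 0.3,
            },
        }
    )


@dataclass
class BurdenSummary:
    """Premature-death risk and mean YLL decomposed into exposure buckets.

    Buckets are the map's exposures plus :data:`OTHERS`; they sum to the
    totals exactly.  Shares are percentages of the respective total.
    """

    scenario: str
    risk_total: float
    risk_by_bucket: dict[str, float]
    yll_total: float
    yll_by_bucket: dict[str, float]
    risk_share: dict[str, float] = field(default_factory=dict)
    yll_share: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not np.isclose(sum(self.risk_by_bucket.values()), self.risk_total, rtol=1e-9):
            raise ValidationError("risk buckets do not sum to the total")
        if not np.isclose(sum(self.yll_by_bucket.values()), self.yll_total, rtol=1e-9):
            raise ValidationError("YLL buckets do not sum to the total")
        if not self.risk_share:
            self.risk_share = _shares(self.risk_by_bucket, self.risk_total)
        if not self.yll_share:
            self.yll_share = _shares(self.yll_by_bucket, self.yll_total)

    @property
    def buckets(self) -> tuple[str, ...]:
        return tuple(self.risk_by_bucket)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": self.scenario,
                "bucket": "total",
                "risk": self.risk_total,
                "risk_share_pct": 100.0,
                "yll_per_person": self.yll_total,
                "yll_share_pct": 100.0,
            }
        ]
        for b in self.buckets:
            rows.append(
                {
                    "scenario": self.scenario,
                    "bucket": b,
                    "risk": self.risk_by_bucket[b],
                    "risk_share_pct": self.risk_share[b],
                    "yll_per_person": self.yll_by_bucket[b],
                    "yll_share_pct": self.yll_share[b],
                }
            )
        return pd.DataFrame(rows)


def _shares(by_bucket: Mapping[str, float], total: float) -> dict[str, float]:
    if total == 0:
        return {b: 0.0 for b in by_bucket}
    return {b: 100.0 * v / total for b, v in by_bucket.items()}


def attribute_burden(
    lt: LifeTable,
    amap: AttributionMap,
    scenario: str = "baseline",
    horizon: int = DEFAULT_HORIZON,
) -> BurdenSummary:
    """Decompose a life table's burden into exposure buckets.

    Each exposure's bucket sums cause-specific deaths weighted by the
    attributable fraction; YLL buckets apply the midpoint age weights to
    the same attributable deaths.  The remainder goes to "others".

    Map entries for causes the life table does not model are inert here
    (they weight zero deaths); cause-coverage validation against the
    declared category set happens at the pipeline level, where that set
    is known.
    """
    w = yll_weights(lt.ages, horizon)
    risk_total = float(lt.deaths_total.sum() / lt.radix)
    yll_total = float((lt.deaths_total * w).sum() / lt.radix)

    risk_by: dict[str, float] = {}
    yll_by: dict[str, float] = {}
    for exposure in amap.exposures:
        af = np.array([amap.fraction(exposure, c) for c in lt.causes])
        attributable = lt.deaths_by_cause @ af
        risk_by[exposure] = float(attributable.sum() / lt.radix)
        yll_by[exposure] = float((attributable * w).sum() / lt.radix)
    risk_by[OTHERS] = risk_total - sum(risk_by.values())
    yll_by[OTHERS] = yll_total - sum(yll_by.values())

    return BurdenSummary(
        scenario=scenario,
        risk_total=risk_total,
        risk_by_bucket=risk_by,
        yll_total=yll_total,
        yll_by_bucket=yll_by,
    )
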