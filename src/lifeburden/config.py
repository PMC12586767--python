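"""Pipeline configuration: every analysis constant in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .attribution import AttributionMap, default_attribution
from .errors import ValidationError
from .lifetable import DEFAULT_HORIZON, DEFAULT_RADIX, RATE_CONVERSIONS
from .rates import AGE_END, AGE_START, SplineSpec
from .scenarios import ScenarioSpec, default_scenarios


@dataclass
class PipelineConfig:
    """Everything needed for a full deterministic run.

    ``attribution`` is either an inline ``{exposure: {cause: fraction}}``
    mapping or a path to a YAML/JSON file holding one.  ``scenarios``
    entries are ``{"label": ..., "eliminated": [...]}`` mappings.
    """

    input_csv: str | None = None
    output_dir: str = "results"
    column_map: dict[str, str] = field(default_factory=dict)
    causes: list[str] | None = None
    spline_df: int = 3
    radix: float = DEFAULT_RADIX
    age_start: int = AGE_START
    age_end: int = AGE_END + 1
    horizon: int = DEFAULT_HORIZON
    conversion: str = "exponential"
    attribution: Any = None
    scenarios: list[dict] | None = None
    n_sims: int = 1000
    seed: int = 1
    report_decimals: int = 2

    def __post_init__(self):
        if self.age_start >= self.age_end:
            raise ValidationError("age_start must be below age_end")
        if (self.age_start, self.age_end) != (AGE_START, AGE_END + 1):
            raise ValidationError(
                f"only the [{AGE_START}, {AGE_END + 1}) age range is supported"
            )
        if self.horizon != self.age_end:
            raise ValidationError("YLL horizon must equal the end of the age range")
        if self.conversion not in RATE_CONVERSIONS:
            raise ValidationError(f"unknown conversion: {self.conversion!r}")

    @property
    def spline(self) -> SplineSpec:
        return SplineSpec(degrees_of_freedom=self.spline_df)

    def attribution_map(self) -> AttributionMap:
        if self.attribution is None:
            return default_attribution()
        if isinstance(self.attribution, (str, Path)):
            return AttributionMap.from_file(self.attribution)
        return AttributionMap(self.attribution)

    def scenario_specs(self) -> list[ScenarioSpec]:
        if self.scenarios is None:
            return default_scenarios()
        return [
            ScenarioSpec(s["label"], tuple(s.get("eliminated", ())))
            for s in self.scenarios
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["attribution"], Path):
            d["attribution"] = str(d["attribution"])
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
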