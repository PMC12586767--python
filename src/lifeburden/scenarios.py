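"""Counterfactual elimination scenarios under competing risks.

Eliminating an exposure scales each apportioned cause-specific hazard by
one minus the exposure's attributable fraction for that cause; the life
table is then rebuilt from the modified hazards, so people saved from
the eliminated exposure remain at risk of every other cause.  Scenarios
are deterministic transformations of one fitted model — counts are never
refit to a reduced dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import OTHERS, AttributionMap, BurdenSummary, attribute_burden
from .errors import ValidationError
from .lifetable import (
    DEFAULT_HORIZON,
    DEFAULT_RADIX,
    apportion_hazards,
    build_from_hazards,
)
from .rates import ALL_CAUSE, AgeCauseTable, SplineSpec, fit_all

BASELINE_LABEL = "baseline"


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual in which a set of exposures is eliminated."""

    label: str
    eliminated: tuple[str, ...] = ()

    def validate_against(self, amap: AttributionMap) -> None:
        unknown = sorted(set(self.eliminated) - set(amap.exposures))
        if unknown:
            raise ValidationError(f"scenario {self.label!r}: unknown exposures {unknown}")


def default_scenarios() -> list[ScenarioSpec]:
    """The three standard counterfactuals."""
    return [
        ScenarioSpec("eliminate_drugs", ("illegal_drugs",)),
        ScenarioSpec("eliminate_tobacco", ("tobacco",)),
        ScenarioSpec("eliminate_both", ("illegal_drugs", "tobacco")),
    ]


def apply_elimination(
    cause_hazards: Mapping[str, np.ndarray],
    amap: AttributionMap,
    spec: ScenarioSpec,
) -> dict[str, np.ndarray]:
    """Scale each cause hazard by 1 - sum of eliminated attributable fractions."""
    spec.validate_against(amap)
    return {
        cause: np.asarray(h) * amap.eliminated_multiplier(cause, spec.eliminated)
        for cause, h in cause_hazards.items()
    }


def counterfactual_map(amap: AttributionMap, spec: ScenarioSpec) -> AttributionMap:
    """Attribution map valid for the post-elimination hazards.

    Eliminated exposures drop to zero; remaining exposures' fractions are
    rescaled by the residual hazard multiplier so they still describe the
    share of the (smaller) remaining hazard they account for.  With the
    default map, where each cause maps to a single exposure, the rescale
    is a no-op.
    """
    out: dict[str, dict[str, float]] = {}
    for exposure in amap.exposures:
        if exposure in spec.eliminated:
            out[exposure] = {}
            continue
        causes: dict[str, float] = {}
        for cause in amap.causes:
            f = amap.fraction(exposure, cause)
            if f == 0.0:
                continue
            mult = amap.eliminated_multiplier(cause, spec.eliminated)
            causes[cause] = f / mult if mult > 0 else 0.0
        out[exposure] = causes
    return AttributionMap(out)


def run_scenario(
    table: AgeCauseTable,
    spline: SplineSpec,
    amap: AttributionMap,
    spec: ScenarioSpec,
    radix: float = DEFAULT_RADIX,
    horizon: int = DEFAULT_HORIZON,
    conversion: str = "exponential",
) -> BurdenSummary:
    """End to end: fit rates, apportion, eliminate, rebuild, attribute."""
    curves = fit_all(table, spline)
    hazards = apportion_hazards(curves[ALL_CAUSE], curves)
    return scenario_from_hazards(
        hazards, amap, spec, radix=radix, horizon=horizon, conversion=conversion
    )


def scenario_from_hazards(
    hazards: Mapping[str, np.ndarray],
    amap: AttributionMap,
    spec: ScenarioSpec,
    radix: float = DEFAULT_RADIX,
    horizon: int = DEFAULT_HORIZON,
    conversion: str = "exponential",
) -> BurdenSummary:
    """Scenario evaluation from already-apportioned hazards."""
    modified = apply_elimination(hazards, amap, spec)
    lt = build_from_hazards(modified, radix=radix, conversion=conversion)
    cf_map = counterfactual_map(amap, spec)
    summary = attribute_burden(lt, cf_map, scenario=spec.label, horizon=horizon)
    return summary


def evaluate_all(
    table: AgeCauseTable,
    spline: SplineSpec,
    amap: AttributionMap,
    scenarios: Sequence[ScenarioSpec],
    radix: float = DEFAULT_RADIX,
    horizon: int = DEFAULT_HORIZON,
    conversion: str = "exponential",
    causes: Sequence[str] | None = None,
) -> dict[str, BurdenSummary]:
    """Baseline plus every scenario from a single fit of the rate models."""
    unknown = sorted(set(amap.causes) - set(table.causes))
    if unknown:
        raise ValidationError(f"attribution map references unknown causes: {unknown}")
    curves = fit_all(table, spline, causes=causes)
    hazards = apportion_hazards(curves[ALL_CAUSE], curves)
    baseline_lt = build_from_hazards(hazards, radix=radix, conversion=conversion)
    out = {
        BASELINE_LABEL: attribute_burden(
            baseline_lt, amap, scenario=BASELINE_LABEL, horizon=horizon
        )
    }
    for spec in scenarios:
        out[spec.label] = scenario_from_hazards(
            hazards, amap, spec, radix=radix, horizon=horizon, conversion=conversion
        )
    return out


@dataclass
class ScenarioComparison:
    """Per-bucket change from baseline to a counterfactual."""

    baseline: BurdenSummary
    counterfactual: BurdenSummary
    risk_change_ppts: dict[str, float]
    yll_change_years: dict[str, float]


def decompose_change(
    baseline: BurdenSummary, counterfactual: BurdenSummary
) -> ScenarioComparison:
    """Differences (counterfactual - baseline) per bucket and in total.

    Risk changes are in percentage points; YLL changes in years per
    person.  Bucket changes sum to the total change exactly.
    """
    if baseline.buckets != counterfactual.buckets:
        raise ValidationError(
            f"bucket mismatch: {baseline.buckets} vs {counterfactual.buckets}"
        )
    risk_change = {
        b: 100.0 * (counterfactual.risk_by_bucket[b] - baseline.risk_by_bucket[b])
        for b in baseline.buckets
    }
    risk_change["total"] = 100.0 * (counterfactual.risk_total - baseline.risk_total)
    yll_change = {
        b: counterfactual.yll_by_bucket[b] - baseline.yll_by_bucket[b]
        for b in baseline.buckets
    }
    yll_change["total"] = counterfactual.yll_total - baseline.yll_total
    return ScenarioComparison(
        baseline=baseline,
        counterfactual=counterfactual,
        risk_change_ppts=risk_change,
        yll_change_years=yll_change,
    )


def comparisons_frame(comparisons: Mapping[str, ScenarioComparison]) -> pd.DataFrame:
    rows = []
    for label, cmp_ in comparisons.items():
        for bucket, change in cmp_.risk_change_ppts.items():
            rows.append(
                {
                    "scenario": label,
                    "bucket": bucket,
                    "risk_change_ppts": change,
                    "yll_change_years": cmp_.yll_change_years[bucket],
                }
            )
    return pd.DataFrame(rows)
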