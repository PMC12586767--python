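"""Monte-Carlo confidence intervals for every reported parameter.

Each simulation replaces the observed death count at every (age, cause)
with a Poisson draw whose mean is that observed count (person-years are
treated as fixed denominators), reruns rate fitting, life tables,
attribution and all scenarios, and the 0.025 / 0.975 quantiles of the
simulated parameters form the interval.  A master seed spawns one
independent substream per simulation, so results do not depend on how
the loop is chunked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import AttributionMap, BurdenSummary
from .errors import FitError, ValidationError
from .rates import ALL_CAUSE, AgeCauseTable, SplineSpec, fit_rate_model
from .lifetable import (
    DEFAULT_HORIZON,
    DEFAULT_RADIX,
    build_from_hazards,
    premature_death_risk,
    years_of_life_lost,
)
from .scenarios import ScenarioSpec, decompose_change, evaluate_all

#: Quantile levels of the reported interval.
QUANTILES = (0.025, 0.975)

#: Maximum tolerated fraction of failed simulations.
MAX_FAILURE_FRACTION = 0.01


@dataclass(frozen=True)
class UncertaintyResult:
    """Point estimate with empirical 2.5% / 97.5% simulation quantiles."""

    parameter: str
    point: float
    lower: float
    upper: float
    n_sims: int
    seed: int

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValidationError(f"{self.parameter}: lower quantile above upper")


def flatten_parameters(
    summaries: Mapping[str, BurdenSummary], include_changes: bool = True
) -> dict[str, float]:
    """One scalar per reported parameter.

    Keys follow ``<quantity>:<scenario>:<bucket>`` with quantities
    ``risk`` (fraction), ``risk_share`` / ``yll_share`` (percent),
    ``yll`` (years per person), and — for non-baseline scenarios —
    ``risk_change`` (percentage points) and ``yll_change`` (years).
    """
    params: dict[str, float] = {}
    baseline = summaries.get("baseline")
    for label, s in summaries.items():
        params[f"risk:{label}:total"] = s.risk_total
        params[f"yll:{label}:total"] = s.yll_total
        for b in s.buckets:
            params[f"risk:{label}:{b}"] = s.risk_by_bucket[b]
            params[f"yll:{label}:{b}"] = s.yll_by_bucket[b]
            params[f"risk_share:{label}:{b}"] = s.risk_share[b]
            params[f"yll_share:{label}:{b}"] = s.yll_share[b]
        if include_changes and baseline is not None and label != "baseline":
            cmp_ = decompose_change(baseline, s)
            for b, v in cmp_.risk_change_ppts.items():
                params[f"risk_change:{label}:{b}"] = v
            for b, v in cmp_.yll_change_years.items():
                params[f"yll_change:{label}:{b}"] = v
    return params


def _evaluate(
    table: AgeCauseTable,
    spline: SplineSpec,
    amap: AttributionMap | None,
    scenarios: Sequence[ScenarioSpec],
    radix: float,
    horizon: int,
    conversion: str,
) -> dict[str, float]:
    if amap is None:
        # Light path: only the all-cause model is needed for totals.
        curve = fit_rate_model(table, ALL_CAUSE, spline)
        lt = build_from_hazards({ALL_CAUSE: curve.rates}, radix=radix, conversion=conversion)
        return {
            "risk:baseline:total": premature_death_risk(lt),
            "yll:baseline:total": years_of_life_lost(lt, horizon),
        }
    summaries = evaluate_all(
        table, spline, amap, scenarios, radix=radix, horizon=horizon, conversion=conversion
    )
    return flatten_parameters(summaries)


def monte_carlo(
    table: AgeCauseTable,
    spline: SplineSpec | None = None,
    amap: AttributionMap | None = None,
    scenarios: Sequence[ScenarioSpec] = (),
    n_sims: int = 1000,
    seed: int = 0,
    radix: float = DEFAULT_RADIX,
    horizon: int = DEFAULT_HORIZON,
    conversion: str = "exponential",
) -> dict[str, UncertaintyResult]:
    """Poisson-resampling intervals for all pipeline parameters.

    With ``amap=None`` only the baseline all-cause totals are simulated
    (a fast path for coverage studies).  Simulations whose rate models
    fail to converge are excluded; more than ``MAX_FAILURE_FRACTION`` of
    failures raises.
    """
    if n_sims < 2:
        raise ValidationError("n_sims must be at least 2")
    spline = spline or SplineSpec()

    point = _evaluate(table, spline, amap, scenarios, radix, horizon, conversion)

    D = table.deaths_matrix()
    T = table.person_years
    causes = table.causes

    draws: dict[str, list[float]] = {k: [] for k in point}
    failures = 0
    for child_seed in np.random.SeedSequence(seed).spawn(n_sims):
        rng = np.random.default_rng(child_seed)
        resampled = AgeCauseTable.from_arrays(
            rng.poisson(D).astype(float), T, causes, validate=False
        )
        try:
            params = _evaluate(resampled, spline, amap, scenarios, radix, horizon, conversion)
        except FitError:
            failures += 1
            continue
        for k, v in params.items():
            draws[k].append(v)

    if failures > MAX_FAILURE_FRACTION * n_sims:
        raise RuntimeError(
            f"{failures}/{n_sims} simulations failed to fit (> {MAX_FAILURE_FRACTION:.0%})"
        )

    results: dict[str, UncertaintyResult] = {}
    for k, values in draws.items():
        lo, hi = np.quantile(np.asarray(values), QUANTILES, method="linear")
        results[k] = UncertaintyResult(
            parameter=k,
            point=point[k],
            lower=float(lo),
            upper=float(hi),
            n_sims=n_sims,
            seed=seed,
        )
    return results


def results_frame(results: Mapping[str, UncertaintyResult]) -> pd.DataFrame:
    rows = [
        {
            "parameter": r.parameter,
            "point": r.point,
            "lower": r.lower,
            "upper": r.upper,
            "n_sims": r.n_sims,
            "seed": r.seed,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows)
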