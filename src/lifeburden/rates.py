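"""Poisson spline models of age-specific mortality rates.

Death counts for each cause are modelled as Poisson with a log link, a
natural cubic spline of age as the linear predictor and the logged
person-years at risk as an offset.  Fitted models predict a smooth
mortality rate at every integer age of the modelled range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, ValidationError

#: First and last single-year age intervals of the analysis, inclusive.
AGE_START = 18
AGE_END = 69

#: Sentinel cause label for the all-cause model.
ALL_CAUSE = "all_causes"

#: Default integer age grid: one row per age interval [a, a+1).
DEFAULT_AGES = np.arange(AGE_START, AGE_END + 1)

#: IRLS convergence tolerance on the relative change in deviance.
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


class AgeCauseTable:
    """Aggregate death counts and person-years per (age, cause).

    The canonical long format has one row per (age, cause) with columns
    ``age``, ``cause``, ``deaths`` and ``person_years``.  Person-years
    measure cohort observation time at that age and must therefore agree
    across the cause rows of a given age.  Internally the table is stored
    as a dense ages x causes count matrix plus one person-years vector.

    Parameters
    ----------
    data:
        Long-format frame with the four canonical columns.
    causes:
        Declared cause categories.  Defaults to the categories present in
        ``data``; may be a superset (absent categories hold zero deaths).
    """

    REQUIRED_COLUMNS = ("age", "cause", "deaths", "person_years")

    def __init__(self, data: pd.DataFrame, causes: Sequence[str] | None = None):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        df = data.loc[:, list(self.REQUIRED_COLUMNS)].copy()

        ages = df["age"].to_numpy()
        if not np.all(ages == np.floor(ages)):
            bad = df.index[ages != np.floor(ages)].tolist()
            raise ValidationError(f"non-integer ages at rows {bad}")
        df["age"] = df["age"].astype(int)
        out_of_range = df.index[(df["age"] < AGE_START) | (df["age"] > AGE_END)]
        if len(out_of_range):
            raise ValidationError(
                f"ages outside [{AGE_START}, {AGE_END}] at rows {out_of_range.tolist()}"
            )
        if (df["deaths"] < 0).any():
            bad = df.index[df["deaths"] < 0].tolist()
            raise ValidationError(f"negative death counts at rows {bad}")
        if (df["person_years"] < 0).any():
            bad = df.index[df["person_years"] < 0].tolist()
            raise ValidationError(f"negative person-years at rows {bad}")
        dup = df.duplicated(subset=["age", "cause"])
        if dup.any():
            raise ValidationError(
                f"duplicate (age, cause) pairs at rows {df.index[dup].tolist()}"
            )
        bad = df.index[(df["person_years"] == 0) & (df["deaths"] > 0)]
        if len(bad):
            raise ValidationError(
                f"deaths recorded with zero person-years at rows {bad.tolist()}"
            )

        data_causes = list(dict.fromkeys(df["cause"]))
        if causes is None:
            causes = data_causes
        else:
            causes = list(causes)
            unknown = sorted(set(data_causes) - set(causes))
            if unknown:
                raise ValidationError(f"unknown cause labels: {unknown}")
            if len(set(causes)) != len(causes):
                raise ValidationError("duplicate labels in declared cause set")

        self._causes: tuple[str, ...] = tuple(causes)
        self._ages = DEFAULT_AGES.copy()

        n_ages = len(self._ages)
        deaths = np.zeros((n_ages, len(self._causes)))
        py = np.full(n_ages, np.nan)
        cause_index = {c: j for j, c in enumerate(self._causes)}
        for row in df.itertuples(index=True):
            i = row.age - AGE_START
            deaths[i, cause_index[row.cause]] = row.deaths
            if not np.isnan(py[i]) and not np.isclose(
                py[i], row.person_years, rtol=1e-6, atol=1e-9
            ):
                raise ValidationError(
                    f"row {row.Index}: person-years at age {row.age} disagree "
                    f"across causes ({py[i]!r} vs {row.person_years!r})"
                )
            py[i] = row.person_years
        py = np.nan_to_num(py, nan=0.0)

        self._deaths = deaths
        self._person_years = py

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        deaths: np.ndarray,
        person_years: np.ndarray,
        causes: Sequence[str],
        validate: bool = True,
    ) -> "AgeCauseTable":
        """Build directly from a dense ages x causes matrix (fast path)."""
        if validate:
            frame = _arrays_to_frame(np.asarray(deaths), np.asarray(person_years), causes)
            return cls(frame, causes=causes)
        obj = cls.__new__(cls)
        obj._causes = tuple(causes)
        obj._ages = DEFAULT_AGES.copy()
        obj._deaths = np.asarray(deaths, dtype=float)
        obj._person_years = np.asarray(person_years, dtype=float)
        return obj

    # -- accessors ------------------------------------------------------------

    @property
    def ages(self) -> np.ndarray:
        return self._ages.copy()

    @property
    def causes(self) -> tuple[str, ...]:
        return self._causes

    @property
    def person_years(self) -> np.ndarray:
        """Observation time per age, shared across causes."""
        return self._person_years.copy()

    def deaths(self, cause: str = ALL_CAUSE) -> np.ndarray:
        """Death counts per age for one cause, or summed over causes."""
        if cause == ALL_CAUSE:
            return self._deaths.sum(axis=1)
        if cause not in self._causes:
            raise ValidationError(f"unknown cause: {cause!r}")
        return self._deaths[:, self._causes.index(cause)].copy()

    def deaths_matrix(self) -> np.ndarray:
        return self._deaths.copy()

    @property
    def total_deaths(self) -> float:
        return float(self._deaths.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame in the canonical CSV dialect."""
        return _arrays_to_frame(self._deaths, self._person_years, self._causes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeCauseTable):
            return NotImplemented
        return (
            self._causes == other._causes
            and np.array_equal(self._deaths, other._deaths)
            and np.allclose(self._person_years, other._person_years, rtol=1e-12)
        )


def _arrays_to_frame(
    deaths: np.ndarray, person_years: np.ndarray, causes: Sequence[str]
) -> pd.DataFrame:
    records = []
    for j, cause in enumerate(causes):
        for i, age in enumerate(DEFAULT_AGES):
            records.append(
                {
                    "age": int(age),
                    "cause": cause,
                    "deaths": int(round(deaths[i, j])),
                    "person_years": float(person_years[i]),
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic regression spline of age.

    ``degrees_of_freedom`` counts the spline columns excluding the
    intercept; with ``df`` columns the basis uses ``df - 1`` interior
    knots placed at person-year-weighted quantiles of age, and boundary
    knots at the ends of the age range.  ``degrees_of_freedom = 0`` gives
    an intercept-only model.
    """

    degrees_of_freedom: int = 3
    basis: str = "natural-cubic"
    knot_rule: str = "weighted-quantile"

    def __post_init__(self):
        if self.degrees_of_freedom < 0:
            raise ValidationError("degrees_of_freedom must be >= 0")
        if self.basis != "natural-cubic":
            raise ValidationError(f"unknown basis: {self.basis!r}")
        if self.knot_rule != "weighted-quantile":
            raise ValidationError(f"unknown knot rule: {self.knot_rule!r}")

    def knots(self, ages: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """All knots (boundary + interior), ascending."""
        df = self.degrees_of_freedom
        if df <= 1:
            return np.array([float(AGE_START), float(AGE_END)])
        n_interior = df - 1
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = _weighted_quantile(ages, weights, probs)
        lo, hi = float(AGE_START), float(AGE_END)
        interior = np.clip(interior, lo + 1e-6, hi - 1e-6)
        return np.concatenate([[lo], np.sort(interior), [hi]])

    def build_matrix(self, ages: np.ndarray, knots: np.ndarray) -> np.ndarray:
        """Spline design columns (no intercept) at the given ages."""
        df = self.degrees_of_freedom
        if df == 0:
            return np.empty((len(ages), 0))
        if df == 1:
            return np.asarray(ages, dtype=float)[:, None]
        return _natural_cubic_basis(np.asarray(ages, dtype=float), knots)


def _weighted_quantile(
    values: np.ndarray, weights: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Quantiles of ``values`` under non-negative ``weights``."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        weights = np.ones_like(values)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(probs, cum, v)


def _natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    With K knots the space has dimension K including the constant; the
    returned matrix holds the K - 1 non-constant columns: x itself plus
    K - 2 truncated-power differences.
    """
    K = len(knots)
    cols = [x]
    kK, kK1 = knots[-1], knots[-2]

    def d(k: float) -> np.ndarray:
        num = np.clip(x - k, 0, None) ** 3 - np.clip(x - kK, 0, None) ** 3
        return num / (kK - k)

    dK1 = d(kK1)
    for k in knots[: K - 2]:
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


@dataclass
class RateCurve:
    """Modelled mortality rate per single year of age for one cause.

    ``coefficients`` are the fitted linear-predictor weights (intercept
    first).  ``zero_deaths`` flags a degenerate fit for a cause with no
    observed deaths, whose curve is identically zero.
    """

    cause: str
    ages: np.ndarray
    rates: np.ndarray
    coefficients: np.ndarray = field(default_factory=lambda: np.array([]))
    zero_deaths: bool = False

    def __post_init__(self):
        self.ages = np.asarray(self.ages)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.ages) != len(self.rates):
            raise ValidationError("ages and rates must have equal length")
        if not np.all(np.isfinite(self.rates)):
            raise ValidationError(f"non-finite rates in curve for {self.cause!r}")
        if self.zero_deaths:
            if (self.rates != 0).any():
                raise ValidationError("zero-deaths curve must be identically zero")
        elif (self.rates <= 0).any():
            raise ValidationError(f"non-positive rates in curve for {self.cause!r}")


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _irls_poisson(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, cause: str
) -> np.ndarray:
    """Maximum-likelihood fit of a Poisson log-linear model.

    Iteratively reweighted least squares with the log person-years offset;
    converges on the relative change in deviance.
    """
    mu = y + np.mean(y) + 0.1
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    beta = np.zeros(X.shape[1])
    for _ in range(IRLS_MAX_ITER):
        w = mu
        z = eta - offset + (y - mu) / mu
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(cause, f"singular weighted design: {exc}")
        eta = offset + X @ beta
        mu = np.exp(eta)
        if not np.all(np.isfinite(mu)):
            raise FitError(cause, "non-finite fitted means during IRLS")
        new_dev = _poisson_deviance(y, mu)
        if abs(new_dev - dev) <= IRLS_TOL * (abs(dev) + 0.1):
            return beta
        dev = new_dev
    raise FitError(cause, f"IRLS did not converge in {IRLS_MAX_ITER} iterations")


def fit_rate_model(
    table: AgeCauseTable, cause: str, spline: SplineSpec | None = None
) -> RateCurve:
    """Fit the Poisson spline model for one cause (or all causes).

    Ages with zero person-years are excluded from the likelihood but
    still receive predictions.  A cause with zero total deaths returns a
    flagged zero curve rather than a failed fit.
    """
    spline = spline or SplineSpec()
    ages = table.ages
    y = table.deaths(cause)
    T = table.person_years

    if y.sum() == 0:
        return RateCurve(
            cause=cause,
            ages=ages,
            rates=np.zeros(len(ages)),
            coefficients=np.array([]),
            zero_deaths=True,
        )
    if T.sum() <= 0:
        raise ValidationError("table has no person-years at risk")

    knots = spline.knots(ages, T)
    mask = T > 0
    B = spline.build_matrix(ages, knots)
    X = np.column_stack([np.ones(len(ages)), B])
    beta = _irls_poisson(y[mask], X[mask], np.log(T[mask]), cause)
    rates = np.exp(X @ beta)
    return RateCurve(cause=cause, ages=ages, rates=rates, coefficients=beta)


def fit_all(
    table: AgeCauseTable,
    spline: SplineSpec | None = None,
    causes: Sequence[str] | None = None,
) -> dict[str, RateCurve]:
    """Fit one curve per declared cause plus the all-cause curve.

    ``causes`` defaults to the table's declared categories; passing an
    explicit set enforces that the table covers every one of them.
    """
    spline = spline or SplineSpec()
    if causes is None:
        causes = table.causes
    else:
        missing = sorted(set(causes) - set(table.causes))
        if missing:
            raise ValidationError(f"table is missing declared categories: {missing}")
    curves = {c: fit_rate_model(table, c, spline) for c in causes}
    curves[ALL_CAUSE] = fit_rate_model(table, ALL_CAUSE, spline)
    return curves


def check_rate_consistency(curves: Mapping[str, RateCurve]) -> float:
    """Max over ages of |sum of cause rates - all-cause rate| / all-cause rate."""
    if ALL_CAUSE not in curves:
        raise ValidationError("curves must include the all-cause model")
    all_curve = curves[ALL_CAUSE]
    total = np.zeros(len(all_curve.ages))
    for label, curve in curves.items():
        if label == ALL_CAUSE:
            continue
        if not np.array_equal(curve.ages, all_curve.ages):
            raise ValidationError(f"age grid of {label!r} differs from all-cause grid")
        total = total + curve.rates
    return float(np.max(np.abs(total - all_curve.rates) / all_curve.rates))


def rates_frame(
    curves: Mapping[str, RateCurve], table: AgeCauseTable | None = None
) -> pd.DataFrame:
    """Tidy per-age observed and modelled rates (chart-ready export)."""
    records = []
    for label, curve in curves.items():
        for i, age in enumerate(curve.ages):
            rec = {"age": int(age), "cause": label, "modelled_rate": curve.rates[i]}
            if table is not None:
                T = table.person_years[i]
                d = table.deaths(label)[i] if label != ALL_CAUSE else table.deaths()[i]
                rec["deaths"] = d
                rec["person_years"] = T
                rec["observed_rate"] = d / T if T > 0 else np.nan
            records.append(rec)
    return pd.DataFrame.from_records(records)
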