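import numpy as np
import pandas as pd
import pytest

import lifeburden as lb
from lifeburden.errors import ValidationError
from lifeburden.rates import ALL_CAUSE, DEFAULT_AGES

from oracles import brute_force_poisson_fit, poisson_deviance


def _constant_rate_table(rate=0.02, py=1e6):
    df = pd.DataFrame(
        {
            "age": DEFAULT_AGES,
            "cause": "x",
            "deaths": np.round(rate * py).astype(int),
            "person_years": py,
        }
    )
    return lb.AgeCauseTable(df)


class TestAgeCauseTable:
    def test_negative_deaths_rejected_with_rows(self):
        df = _constant_rate_table().to_frame()
        df.loc[3, "deaths"] = -1
        with pytest.raises(ValidationError, match=r"\[3\]"):
            lb.AgeCauseTable(df)

    def test_duplicate_age_cause_rejected(self):
        df = _constant_rate_table().to_frame()
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicate"):
            lb.AgeCauseTable(df)

    def test_deaths_with_zero_person_years_rejected(self):
        df = _constant_rate_table().to_frame()
        df.loc[0, "person_years"] = 0.0
        with pytest.raises(ValidationError, match="zero person-years"):
            lb.AgeCauseTable(df)

    def test_out_of_range_age_rejected(self):
        df = _constant_rate_table().to_frame()
        df.loc[0, "age"] = 17
        with pytest.raises(ValidationError, match="outside"):
            lb.AgeCauseTable(df)

    def test_inconsistent_person_years_across_causes_rejected(self):
        df = _constant_rate_table().to_frame()
        other = df.copy()
        other["cause"] = "y"
        other.loc[5, "person_years"] *= 2
        with pytest.raises(ValidationError, match="disagree"):
            lb.AgeCauseTable(pd.concat([df, other], ignore_index=True))

    def test_declared_cause_superset_allowed(self):
        df = _constant_rate_table().to_frame()
        table = lb.AgeCauseTable(df, causes=["x", "y"])
        assert table.deaths("y").sum() == 0


class TestFitRateModel:
    def test_constant_data_yields_flat_curve(self):
        table = _constant_rate_table(rate=0.02, py=1e6)
        curve = lb.fit_rate_model(table, "x")
        assert np.max(np.abs(curve.rates - 0.02) / 0.02) < 0.01

    def test_intercept_only_matches_closed_form(self, default_table):
        # Poisson MLE with intercept only: total deaths / total person-years
        curve = lb.fit_rate_model(
            default_table, "other", lb.SplineSpec(degrees_of_freedom=0)
        )
        expected = default_table.deaths("other").sum() / default_table.person_years.sum()
        np.testing.assert_allclose(curve.rates, expected, rtol=1e-8)

    def test_matches_brute_force_optimizer(self, default_table):
        # 4-parameter fit: deviance within 1e-6 relative of a generic optimiser
        spline = lb.SplineSpec(degrees_of_freedom=3)
        table = default_table
        y = table.deaths("drug_poisoning")
        T = table.person_years
        mask = T > 0
        knots = spline.knots(table.ages, T)
        X = np.column_stack(
            [np.ones(len(table.ages)), spline.build_matrix(table.ages, knots)]
        )
        beta_oracle = brute_force_poisson_fit(y[mask], X[mask], np.log(T[mask]))
        mu_oracle = np.exp(np.log(T[mask]) + X[mask] @ beta_oracle)
        dev_oracle = poisson_deviance(y[mask], mu_oracle)

        curve = lb.fit_rate_model(table, "drug_poisoning", spline)
        mu_fit = curve.rates[mask] * T[mask]
        dev_fit = poisson_deviance(y[mask], mu_fit)
        assert abs(dev_fit - dev_oracle) <= 1e-6 * abs(dev_oracle)

    def test_row_order_invariance(self, default_table):
        shuffled = default_table.to_frame().sample(frac=1.0, random_state=0)
        curve_a = lb.fit_rate_model(default_table, "cardiovascular")
        curve_b = lb.fit_rate_model(lb.AgeCauseTable(shuffled), "cardiovascular")
        np.testing.assert_allclose(curve_a.rates, curve_b.rates, rtol=1e-12)

    def test_reproduces_total_expected_deaths(self, default_table, default_curves):
        # score equation of the intercept: sum(rate * T) == observed total
        T = default_table.person_years
        for cause in default_table.causes:
            expected = float((default_curves[cause].rates * T).sum())
            observed = float(default_table.deaths(cause).sum())
            assert expected == pytest.approx(observed, rel=1e-6)

    def test_zero_deaths_cause_flagged(self):
        df = _constant_rate_table().to_frame()
        df["deaths"] = 0
        table = lb.AgeCauseTable(df)
        curve = lb.fit_rate_model(table, "x")
        assert curve.zero_deaths
        assert (curve.rates == 0).all()

    def test_deterministic(self, default_table):
        a = lb.fit_rate_model(default_table, "other")
        b = lb.fit_rate_model(default_table, "other")
        np.testing.assert_array_equal(a.rates, b.rates)


class TestFitAll:
    def test_parameter_recovery_on_synthetic(self, true_hazards):
        # >= 1e5 person-years at every age: curves within 10% of the truth
        table = lb.generate_counts(
            lb.default_hazards(), lb.ExposureSchedule.uniform(1e6), seed=3
        )
        curves = lb.fit_all(table)
        for cause, h in true_hazards.items():
            assert np.max(np.abs(curves[cause].rates - h) / h) < 0.10

    def test_missing_categories_rejected(self):
        table = _constant_rate_table()
        with pytest.raises(ValidationError, match="missing declared categories"):
            lb.fit_all(table, causes=["x", "y", "z"])

    def test_returns_all_curves(self, default_curves, default_table):
        assert set(default_curves) == set(default_table.causes) | {ALL_CAUSE}


class TestRateConsistency:
    def test_exactly_additive_curves_give_zero(self):
        ages = DEFAULT_AGES
        a = lb.RateCurve("a", ages, np.full(52, 0.01))
        b = lb.RateCurve("b", ages, np.full(52, 0.02))
        total = lb.RateCurve(ALL_CAUSE, ages, np.full(52, 0.03))
        assert lb.check_rate_consistency({"a": a, "b": b, ALL_CAUSE: total}) == 0

    def test_large_sample_gap_below_5_percent(self, large_table):
        curves = lb.fit_all(large_table)
        assert lb.check_rate_consistency(curves) < 0.05

    def test_mismatched_grids_rejected(self):
        a = lb.RateCurve("a", DEFAULT_AGES, np.full(52, 0.01))
        bad = lb.RateCurve("b", DEFAULT_AGES[:-1], np.full(51, 0.01))
        total = lb.RateCurve(ALL_CAUSE, DEFAULT_AGES, np.full(52, 0.02))
        with pytest.raises(ValidationError):
            lb.check_rate_consistency({"a": a, "b": bad, ALL_CAUSE: total})


class TestSplineSpec:
    def test_basis_column_count_equals_df(self):
        for df_ in (1, 2, 3, 5):
            spline = lb.SplineSpec(degrees_of_freedom=df_)
            knots = spline.knots(DEFAULT_AGES, np.ones(52))
            B = spline.build_matrix(DEFAULT_AGES, knots)
            assert B.shape == (52, df_)

    def test_negative_df_rejected(self):
        with pytest.raises(ValidationError):
            lb.SplineSpec(degrees_of_freedom=-1)

    def test_weighted_knots_follow_person_years(self):
        spline = lb.SplineSpec(degrees_of_freedom=3)
        young_heavy = np.r_[np.full(26, 100.0), np.full(26, 1.0)]
        old_heavy = young_heavy[::-1].copy()
        k_young = spline.knots(DEFAULT_AGES, young_heavy)
        k_old = spline.knots(DEFAULT_AGES, old_heavy)
        assert (k_young[1:-1] < k_old[1:-1]).all()
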