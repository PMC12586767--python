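import numpy as np
import pytest

import lifeburden as lb
from lifeburden.attribution import OTHERS
from lifeburden.errors import ValidationError
from lifeburden.lifetable import build_from_hazards
from lifeburden.rates import ALL_CAUSE, DEFAULT_AGES
from lifeburden.scenarios import BASELINE_LABEL, scenario_from_hazards

N_AGES = len(DEFAULT_AGES)


@pytest.fixture(scope="module")
def hazards(default_curves):
    return lb.apportion_hazards(default_curves[ALL_CAUSE], default_curves)


@pytest.fixture(scope="module")
def summaries(default_table):
    return lb.evaluate_all(
        default_table, lb.SplineSpec(), lb.default_attribution(), lb.default_scenarios()
    )


class TestApplyElimination:
    def test_empty_set_is_identity(self, hazards, amap):
        spec = lb.ScenarioSpec("noop", ())
        out = lb.apply_elimination(hazards, amap, spec)
        for cause in hazards:
            np.testing.assert_array_equal(out[cause], hazards[cause])

    def test_eliminating_drugs_zeroes_fully_attributed_causes(self, hazards, amap):
        spec = lb.ScenarioSpec("drugs", ("illegal_drugs",))
        out = lb.apply_elimination(hazards, amap, spec)
        assert (out["drug_poisoning"] == 0).all()
        assert (out["viral_hepatitis"] == 0).all()
        np.testing.assert_array_equal(out["other"], hazards["other"])

    def test_eliminating_tobacco_scales_partial_causes(self, hazards, amap):
        spec = lb.ScenarioSpec("tobacco", ("tobacco",))
        out = lb.apply_elimination(hazards, amap, spec)
        np.testing.assert_allclose(out["cardiovascular"], 0.5 * hazards["cardiovascular"])
        np.testing.assert_allclose(out["other_cancers"], 0.7 * hazards["other_cancers"])
        assert (out["smoking_related"] == 0).all()
        np.testing.assert_array_equal(out["drug_poisoning"], hazards["drug_poisoning"])

    def test_unknown_exposure_rejected(self, hazards, amap):
        with pytest.raises(ValidationError, match="alcohol"):
            lb.apply_elimination(hazards, amap, lb.ScenarioSpec("x", ("alcohol",)))


class TestRunScenario:
    def test_competing_risks_ordering(self, summaries):
        r = {label: s.risk_total for label, s in summaries.items()}
        assert r["eliminate_both"] <= min(r["eliminate_drugs"], r["eliminate_tobacco"])
        assert max(r["eliminate_drugs"], r["eliminate_tobacco"]) <= r[BASELINE_LABEL]

    def test_eliminated_bucket_is_exactly_zero(self, summaries):
        assert summaries["eliminate_drugs"].risk_by_bucket["illegal_drugs"] == 0
        assert summaries["eliminate_tobacco"].risk_by_bucket["tobacco"] == 0
        both = summaries["eliminate_both"]
        assert both.risk_by_bucket["illegal_drugs"] == 0
        assert both.risk_by_bucket["tobacco"] == 0
        assert both.risk_by_bucket[OTHERS] == pytest.approx(both.risk_total, rel=1e-12)

    def test_offset_non_eliminated_buckets_never_shrink(self, summaries):
        base = summaries[BASELINE_LABEL]
        assert (
            summaries["eliminate_drugs"].risk_by_bucket["tobacco"]
            >= base.risk_by_bucket["tobacco"]
        )
        assert (
            summaries["eliminate_drugs"].risk_by_bucket[OTHERS]
            >= base.risk_by_bucket[OTHERS]
        )
        assert (
            summaries["eliminate_tobacco"].risk_by_bucket["illegal_drugs"]
            >= base.risk_by_bucket["illegal_drugs"]
        )

    def test_run_scenario_matches_evaluate_all(self, default_table, amap, summaries):
        single = lb.run_scenario(
            default_table,
            lb.SplineSpec(),
            amap,
            lb.ScenarioSpec("eliminate_drugs", ("illegal_drugs",)),
        )
        assert single.risk_total == pytest.approx(
            summaries["eliminate_drugs"].risk_total, rel=1e-12
        )

    def test_deterministic(self, default_table, amap):
        spec = lb.ScenarioSpec("eliminate_tobacco", ("tobacco",))
        a = lb.run_scenario(default_table, lb.SplineSpec(), amap, spec)
        b = lb.run_scenario(default_table, lb.SplineSpec(), amap, spec)
        assert a.risk_total == b.risk_total and a.yll_total == b.yll_total

    def test_yll_asymmetry_young_deaths_cost_more(self, amap):
        # same number of attributable deaths, concentrated young vs old:
        # young concentration raises the exposure's YLL bucket
        base = {"other": np.full(N_AGES, 0.01)}
        young = np.zeros(N_AGES)
        old = np.zeros(N_AGES)
        young[:10] = 0.005
        old[-10:] = 0.005
        s_young = lb.attribute_burden(
            build_from_hazards({**base, "drug_poisoning": young}),
            amap,
        )
        s_old = lb.attribute_burden(
            build_from_hazards({**base, "drug_poisoning": old}),
            amap,
        )
        assert s_young.yll_by_bucket["illegal_drugs"] > s_old.yll_by_bucket["illegal_drugs"]


class TestDecomposeChange:
    def test_identical_summaries_give_zero_changes(self, summaries):
        base = summaries[BASELINE_LABEL]
        cmp_ = lb.decompose_change(base, base)
        assert all(v == 0 for v in cmp_.risk_change_ppts.values())
        assert all(v == 0 for v in cmp_.yll_change_years.values())

    def test_bucket_changes_sum_to_total_change(self, summaries):
        base = summaries[BASELINE_LABEL]
        for label in ("eliminate_drugs", "eliminate_tobacco", "eliminate_both"):
            cmp_ = lb.decompose_change(base, summaries[label])
            parts = sum(
                v for k, v in cmp_.risk_change_ppts.items() if k != "total"
            )
            assert parts == pytest.approx(cmp_.risk_change_ppts["total"], abs=1e-9)
            parts_yll = sum(
                v for k, v in cmp_.yll_change_years.items() if k != "total"
            )
            assert parts_yll == pytest.approx(cmp_.yll_change_years["total"], abs=1e-9)

    def test_eliminated_bucket_change_equals_minus_baseline(self, summaries):
        base = summaries[BASELINE_LABEL]
        cmp_ = lb.decompose_change(base, summaries["eliminate_drugs"])
        assert cmp_.risk_change_ppts["illegal_drugs"] == pytest.approx(
            -100 * base.risk_by_bucket["illegal_drugs"], rel=1e-12
        )

    def test_bucket_mismatch_rejected(self, summaries):
        base = summaries[BASELINE_LABEL]
        other = lb.attribute_burden(
            build_from_hazards({"other": np.full(N_AGES, 0.01)}),
            lb.AttributionMap({"vaping": {"other": 0.1}}),
        )
        with pytest.raises(ValidationError, match="bucket mismatch"):
            lb.decompose_change(base, other)


class TestCounterfactualMapRescaling:
    def test_overlapping_map_rescales_remaining_exposure(self):
        # cause shared by two exposures: after eliminating one, the other's
        # share of the remaining hazard grows accordingly
        amap = lb.AttributionMap({"e1": {"c": 0.3}, "e2": {"c": 0.5}})
        hazards = {"c": np.full(N_AGES, 0.01)}
        spec = lb.ScenarioSpec("drop_e1", ("e1",))
        s = scenario_from_hazards(hazards, amap, spec)
        assert s.risk_by_bucket["e1"] == 0
        assert s.risk_by_bucket["e2"] == pytest.approx(
            s.risk_total * 0.5 / 0.7, rel=1e-12
        )
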