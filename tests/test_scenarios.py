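"""Scenario projection engine: closed forms, identities and monotonicity."""

import numpy as np
import pandas as pd
import pytest

from ferrodiet.adequacy import PriSchedule
from ferrodiet.errors import ConfigurationError
from ferrodiet.scenarios import (
    ComponentDensities,
    ScenarioSpec,
    apply_scenario,
    default_scenarios,
    run_all_scenarios,
    scenario_delta,
)

DENS = ComponentDensities(
    wheat_refined=0.010, wheat_whole=0.020, rice_white=0.004, rice_brown=0.012
)


def cohort_frame(rows):
    defaults = {
        "sex": "male",
        "age_class": "18-64",
        "age_years": 40.0,
        "iron_mg_day": None,
        "wheat_iron_mg_day": 0.0,
        "rice_iron_mg_day": 0.0,
        "other_iron_mg_day": 0.0,
        "wheat_g_day": 0.0,
        "rice_g_day": 0.0,
        "wholegrain_share": 0.0,
        "brown_share": 0.0,
    }
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    out["iron_mg_day"] = (
        out["wheat_iron_mg_day"] + out["rice_iron_mg_day"] + out["other_iron_mg_day"]
    )
    return out


@pytest.fixture
def one_person():
    # wheat iron 2.0, rice iron 0.2, other 8.0 mg/day
    return cohort_frame(
        [
            {
                "wheat_iron_mg_day": 2.0,
                "rice_iron_mg_day": 0.2,
                "other_iron_mg_day": 8.0,
                "wheat_g_day": 200.0,
                "rice_g_day": 50.0,
            }
        ]
    )


class TestClosedForms:
    def test_basic_depletes_grain_iron_by_20_percent(self, one_person):
        spec = ScenarioSpec("basic", depletion_factor=0.8)
        out = apply_scenario(one_person, spec, DENS)
        assert out["iron_mg_day"].iloc[0] == pytest.approx(8.0 + 0.8 * 2.2)  # 9.76

    def test_s1_depletion_then_30_percent_biofortification(self, one_person):
        spec = ScenarioSpec("s1", depletion_factor=0.8, biofort_factor=1.3)
        out = apply_scenario(one_person, spec, DENS)
        assert out["iron_mg_day"].iloc[0] == pytest.approx(8.0 + 0.8 * 1.3 * 2.2)  # 10.288

    def test_s1_minus_basic_delta(self, one_person):
        basic = ScenarioSpec("basic", depletion_factor=0.8)
        s1 = ScenarioSpec("s1", depletion_factor=0.8, biofort_factor=1.3)
        delta = scenario_delta(one_person, s1, basic, DENS)
        assert delta.iloc[0] == pytest.approx(10.288 - 9.76)  # 0.528

    def test_identity_spec_is_a_no_op(self, one_person):
        spec = ScenarioSpec("identity")
        out = apply_scenario(one_person, spec, DENS)
        assert out["iron_mg_day"].iloc[0] == pytest.approx(10.2, rel=1e-12)
        assert out["wheat_iron_mg_day"].iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_baseline_vs_itself_is_zero(self, one_person):
        basic = ScenarioSpec("basic", depletion_factor=0.8)
        assert scenario_delta(one_person, basic, basic, DENS).abs().max() == 0.0

    def test_wholegrain_shift_closed_form(self, one_person):
        # share 0 -> 0.5 on 200 g wheat: +200*0.5*(0.020-0.010) = +1.0 mg, then *0.8
        spec = ScenarioSpec("s2", depletion_factor=0.8, target_wholegrain_share=0.5)
        out = apply_scenario(one_person, spec, DENS)
        assert out["wheat_iron_mg_day"].iloc[0] == pytest.approx(0.8 * 3.0)

    def test_rice_nonconsumer_unaffected_by_brown_shift(self):
        frame = cohort_frame(
            [{"wheat_iron_mg_day": 1.5, "other_iron_mg_day": 7.0, "wheat_g_day": 120.0}]
        )
        basic = ScenarioSpec("basic", depletion_factor=0.8)
        s3 = ScenarioSpec("s3", depletion_factor=0.8, target_brown_share=1.0)
        assert scenario_delta(frame, s3, basic, DENS).abs().max() == 0.0


class TestSemantics:
    def test_share_already_above_target_left_unchanged(self):
        frame = cohort_frame(
            [
                {
                    "wheat_iron_mg_day": 2.0,
                    "wheat_g_day": 100.0,
                    "wholegrain_share": 0.8,
                    "other_iron_mg_day": 5.0,
                }
            ]
        )
        spec = ScenarioSpec("s2", target_wholegrain_share=0.5)
        out = apply_scenario(frame, spec, DENS)
        assert out["wheat_iron_mg_day"].iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_multipliers_commute_with_share_shift(self, one_person):
        # shift then multiply == multiply then shift-with-multiplied densities
        spec = ScenarioSpec(
            "s4", depletion_factor=0.8, biofort_factor=1.3,
            target_wholegrain_share=0.5, target_brown_share=1.0,
        )
        out = apply_scenario(one_person, spec, DENS)
        mult = 0.8 * 1.3
        wheat_shifted = 2.0 + 200.0 * 0.5 * (0.020 - 0.010)
        rice_shifted = 0.2 + 50.0 * 1.0 * (0.012 - 0.004)
        assert out["iron_mg_day"].iloc[0] == pytest.approx(
            8.0 + mult * (wheat_shifted + rice_shifted), rel=1e-12
        )
        # other order: multiply first, then add the shift at multiplied densities
        alt = 8.0 + (2.0 * mult + 200.0 * 0.5 * (0.020 - 0.010) * mult) + (
            0.2 * mult + 50.0 * (0.012 - 0.004) * mult
        )
        assert out["iron_mg_day"].iloc[0] == pytest.approx(alt, rel=1e-12)

    def test_biofortification_strictly_increases_consumer_iron(self, one_person):
        base = apply_scenario(
            one_person, ScenarioSpec("a", 0.8, biofort_factor=1.1), DENS
        )["iron_mg_day"].iloc[0]
        more = apply_scenario(
            one_person, ScenarioSpec("b", 0.8, biofort_factor=1.3), DENS
        )["iron_mg_day"].iloc[0]
        assert more > base

    def test_missing_densities_is_a_configuration_error(self, one_person):
        with pytest.raises(ConfigurationError):
            apply_scenario(one_person, ScenarioSpec("basic", 0.8), None)

    def test_invalid_spec_fields_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec("bad", depletion_factor=0.0)
        with pytest.raises(ConfigurationError):
            ScenarioSpec("bad", biofort_factor=0.9)
        with pytest.raises(ConfigurationError):
            ScenarioSpec("bad", target_wholegrain_share=1.5)


class TestRunAll:
    def make_cohort(self):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(40):
            wheat_g = rng.uniform(50, 250)
            rows.append(
                {
                    "sex": "male" if i % 2 else "female",
                    "age_class": "18-64" if i < 30 else "<1",
                    "age_years": 30.0 if i < 30 else 0.5,
                    "wheat_iron_mg_day": wheat_g * 0.010,
                    "wheat_g_day": wheat_g,
                    "other_iron_mg_day": rng.uniform(5, 10),
                }
            )
        return cohort_frame(rows)

    def test_infants_are_excluded(self):
        results, _ = run_all_scenarios(
            self.make_cohort(), default_scenarios(), PriSchedule.default(), DENS
        )
        assert "<1" not in set(results["age_class"])

    def test_s4_delta_dominates_single_action_deltas(self):
        results, _ = run_all_scenarios(
            self.make_cohort(), default_scenarios(), PriSchedule.default(), DENS
        )
        wide = results.pivot_table(
            index=["sex", "age_class"], columns="scenario",
            values="mean_delta_vs_baseline",
        )
        assert (wide["s4"] >= wide[["s1", "s2", "s3"]].max(axis=1) - 1e-12).all()
        assert (wide["basic"].abs() < 1e-12).all()

    def test_degenerate_identical_cohort_matches_single_person_closed_form(self):
        rows = [
            {
                "sex": "male",
                "age_class": "18-64",
                "age_years": 40.0,
                "wheat_iron_mg_day": 2.0,
                "rice_iron_mg_day": 0.2,
                "other_iron_mg_day": 8.0,
                "wheat_g_day": 200.0,
                "rice_g_day": 50.0,
            }
        ] * 25
        results, _ = run_all_scenarios(
            cohort_frame(rows), default_scenarios(), PriSchedule.default(), DENS
        )
        s1 = results[results["scenario"] == "s1"].iloc[0]
        assert s1["mean_delta_vs_baseline"] == pytest.approx(0.528, rel=1e-12)
        assert s1["mean_iron_mg_day"] == pytest.approx(10.288, rel=1e-12)

    def test_grams_and_energy_never_altered(self, one_person):
        before = one_person[["wheat_g_day", "rice_g_day"]].copy()
        for spec in default_scenarios():
            out = apply_scenario(one_person, spec, DENS)
            assert set(out.columns) == {
                "wheat_iron_mg_day", "rice_iron_mg_day", "iron_mg_day",
            }
        pd.testing.assert_frame_equal(one_person[["wheat_g_day", "rice_g_day"]], before)
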