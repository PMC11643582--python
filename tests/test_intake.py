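"""Two-day-mean intakes, group summaries and age-class assignment."""

import numpy as np
import pandas as pd
import pytest

from ferrodiet.composition import decompose_item, records_from_frame
from ferrodiet.errors import StructuralError, UnknownFoodError
from ferrodiet.intake import (
    assign_age_class,
    compute_intakes,
    group_summary,
    individual_intake,
    summarize_by_group,
)

from conftest import comp_frame, comp_row


def diary(*entries):
    return pd.DataFrame(
        entries, columns=["individual_id", "day_index", "food_code", "grams"]
    )


class TestIndividualIntake:
    def test_two_day_arithmetic_mean(self, bread_table):
        # day 1: 1000 g bread -> 9 mg iron + 500 g rice_dish -> 1.5 mg;
        # day 2: 600 g bread -> 5.4 mg + 600 g apple -> 0.6 mg.
        d = diary(
            ("p1", 1, "bread", 1000.0),
            ("p1", 1, "rice_dish", 500.0),
            ("p1", 2, "bread", 600.0),
            ("p1", 2, "apple", 600.0),
        )
        ii = individual_intake(d, bread_table, "p1")
        assert ii.iron_mg_day == pytest.approx((10.5 + 6.0) / 2)
        assert ii.wheat_g_day == pytest.approx((700 + 420) / 2)
        assert ii.rice_g_day == pytest.approx(250 / 2)
        assert ii.total_g_day == pytest.approx((1500 + 1200) / 2)

    def test_constant_single_item_diet_density(self):
        table = comp_frame(comp_row("item", energy_density=2.0, iron_density=0.02))
        d = diary(("p1", 1, "item", 100.0), ("p1", 2, "item", 100.0))
        ii = individual_intake(d, table, "p1")
        assert ii.iron_mg_day == pytest.approx(2.0)
        assert ii.energy_kcal_day == pytest.approx(200.0)
        assert ii.iron_density_per_1000kcal == pytest.approx(1000 * 2.0 / 200.0)

    def test_empty_diary_gives_zero_intake_and_missing_density(self, bread_table):
        ii = individual_intake(diary(), bread_table, "ghost")
        assert ii.iron_mg_day == 0.0
        assert ii.total_g_day == 0.0
        assert np.isnan(ii.iron_density_per_1000kcal)

    def test_unknown_food_code_named_in_error(self, bread_table):
        d = diary(("p1", 1, "mystery_meat", 10.0))
        with pytest.raises(UnknownFoodError, match="mystery_meat"):
            individual_intake(d, bread_table, "p1")

    def test_day_index_outside_two_days_rejected(self, bread_table):
        d = diary(("p1", 3, "bread", 10.0))
        with pytest.raises(StructuralError, match="day_index"):
            individual_intake(d, bread_table, "p1")


class TestVectorizedAgreement:
    def test_matches_per_entry_brute_force_on_random_diaries(self, bread_table):
        """Cohort path vs naive per-entry summation, 1e-12 relative."""
        rng = np.random.default_rng(42)
        records = {r.food_code: r for r in records_from_frame(bread_table)}
        codes = list(records)
        for _ in range(200):
            n_rows = rng.integers(1, 11)
            rows = [
                (
                    "p",
                    int(rng.integers(1, 3)),
                    codes[rng.integers(len(codes))],
                    float(rng.uniform(0, 800)),
                )
                for _ in range(n_rows)
            ]
            d = diary(*rows)
            ii = individual_intake(d, bread_table, "p")
            # oracle: decompose every entry independently, sum, halve
            iron = sum(
                decompose_item(records[c], g).wheat_iron_mg
                + decompose_item(records[c], g).rice_iron_mg
                + decompose_item(records[c], g).other_iron_mg
                for _, _, c, g in rows
            )
            assert ii.iron_mg_day == pytest.approx(iron / 2, rel=1e-12)
            individuals = pd.DataFrame(
                {"individual_id": ["p"], "sex": ["male"], "age_years": [30.0]}
            )
            frame = compute_intakes(individuals, d, bread_table)
            for col in (
                "iron_mg_day", "energy_kcal_day", "wheat_g_day", "rice_g_day",
                "wheat_iron_mg_day", "rice_iron_mg_day", "total_g_day",
            ):
                assert frame[col].iloc[0] == pytest.approx(
                    getattr(ii, col), rel=1e-12, abs=1e-12
                )

    def test_record_order_never_changes_output(self, bread_table):
        rng = np.random.default_rng(7)
        rows = [
            ("p", int(rng.integers(1, 3)), c, float(rng.uniform(1, 500)))
            for c in ["bread", "rice_dish", "apple", "wholegrain_bread"] * 3
        ]
        base = individual_intake(diary(*rows), bread_table, "p")
        perm = [rows[i] for i in rng.permutation(len(rows))]
        shuffled = individual_intake(diary(*perm), bread_table, "p")
        for field in vars(base):
            if field == "individual_id":
                continue
            assert getattr(base, field) == pytest.approx(
                getattr(shuffled, field), rel=1e-12, nan_ok=True
            )

    def test_component_irons_sum_to_total(self, bread_table):
        rng = np.random.default_rng(3)
        rows = [
            (f"p{i}", d, c, float(rng.uniform(0, 500)))
            for i in range(20)
            for d in (1, 2)
            for c in ("bread", "rice_dish", "apple")
        ]
        individuals = pd.DataFrame(
            {
                "individual_id": [f"p{i}" for i in range(20)],
                "sex": ["female"] * 20,
                "age_years": rng.uniform(1, 74, 20),
            }
        )
        frame = compute_intakes(individuals, diary(*rows), bread_table)
        total = (
            frame["wheat_iron_mg_day"]
            + frame["rice_iron_mg_day"]
            + frame["other_iron_mg_day"]
        )
        np.testing.assert_allclose(total, frame["iron_mg_day"], rtol=1e-12)
        assert frame["iron_mg_day"].mean() == pytest.approx(total.mean(), rel=1e-12)


class TestGroupSummary:
    def test_closed_form_five_values(self):
        s = group_summary([1, 2, 3, 4, 5])
        assert (s.mean, s.median) == (3.0, 3.0)
        assert s.sd == pytest.approx(np.sqrt(2.5))

    def test_degenerate_all_equal(self):
        s = group_summary([7.0] * 10)
        assert s.sd == 0.0
        assert s.p5 == s.median == s.p95 == 7.0

    def test_matches_sort_based_percentile_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(1.0, 0.6, 1000)
        s = group_summary(values)
        # independent oracle: manual linear interpolation on sorted values
        v = np.sort(values)
        for stat, q in ((s.p5, 0.05), (s.median, 0.5), (s.p95, 0.95)):
            h = q * (len(v) - 1)
            lo = int(np.floor(h))
            expected = v[lo] + (h - lo) * (v[lo + 1] - v[lo])
            assert stat == pytest.approx(expected, rel=0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no values"):
            group_summary([])

    def test_summarize_by_group_shapes(self, bread_table):
        intakes = pd.DataFrame(
            {
                "sex": ["male"] * 3 + ["female"] * 2,
                "age_class": ["18-64", "18-64", "65-74", "18-64", "18-64"],
                "iron_mg_day": [10, 12, 14, 8, 9],
            }
        )
        out = summarize_by_group(intakes, ["iron_mg_day"])
        keys = set(zip(out["sex"], out["age_class"]))
        assert ("male", "18-64") in keys and ("all", "all") in keys
        overall = out[(out["sex"] == "all")].iloc[0]
        assert overall["n"] == 5 and overall["mean"] == pytest.approx(10.6)


class TestAgeClasses:
    @pytest.mark.parametrize(
        "age, expected",
        [
            (0.5, "<1"),
            (1.0, "1-2"),
            (2.9, "1-2"),
            (3.0, "3-9"),
            (9.99, "3-9"),
            (10.0, "10-17"),
            (17.9, "10-17"),  # completed years = 17
            (18.0, "18-64"),
            (64.9, "18-64"),
            (65.0, "65-74"),
            (74.5, "65-74"),
        ],
    )
    def test_boundaries_use_completed_years(self, age, expected):
        assert assign_age_class(age) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_age_class(75.0)
        with pytest.raises(ValueError):
            assign_age_class(-0.1)
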