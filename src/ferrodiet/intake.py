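"""Per-individual two-day mean intakes and group summary statistics.

Each survey individual contributes two non-consecutive diary days.  Every
diary entry is decomposed into wheat-, rice- and other-derived mass, energy
and iron via the composition table; the per-day sums are then averaged
arithmetically over the two days.  Iron density is intake per 1000 kcal.

Group summaries follow the survey-report conventions: arithmetic mean,
sample SD (n - 1 denominator), and median / 5th / 95th percentiles with
linear interpolation between order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import ComponentAmounts, decompose_item, records_from_frame
from .errors import StructuralError, UnknownFoodError

#: Age classes used for reporting: label, [min, max) in completed years.
AGE_CLASSES = [
    ("<1", 0.0, 1.0),
    ("1-2", 1.0, 3.0),
    ("3-9", 3.0, 10.0),
    ("10-17", 10.0, 18.0),
    ("18-64", 18.0, 65.0),
    ("65-74", 65.0, 75.0),
]
AGE_CLASS_LABELS = [label for label, _, _ in AGE_CLASSES]

#: Composition category whose foods count towards total cereal grams.
CEREAL_CATEGORY = "cereals"

#: Intake columns produced per individual (all per day).
INTAKE_COLUMNS = [
    "total_g_day",
    "energy_kcal_day",
    "iron_mg_day",
    "wheat_g_day",
    "rice_g_day",
    "cereal_g_day",
    "wheat_kcal_day",
    "rice_kcal_day",
    "wheat_iron_mg_day",
    "rice_iron_mg_day",
    "other_iron_mg_day",
    "wholegrain_wheat_g_day",
    "brown_rice_g_day",
]


@dataclass
class IndividualIntake:
    """Two-day-mean intake totals with wheat/rice attribution for one person."""

    individual_id: str
    total_g_day: float
    energy_kcal_day: float
    iron_mg_day: float
    wheat_g_day: float
    rice_g_day: float
    cereal_g_day: float
    wheat_kcal_day: float
    rice_kcal_day: float
    wheat_iron_mg_day: float
    rice_iron_mg_day: float
    other_iron_mg_day: float
    wholegrain_share: float
    brown_share: float
    iron_density_per_1000kcal: float  # NaN when both days have zero energy


@dataclass
class GroupSummary:
    """Distributional summary of one variable within one population group."""

    group: tuple
    n: int
    mean: float
    sd: float
    median: float
    p5: float
    p95: float


def assign_age_class(age_years: float, classes=AGE_CLASSES) -> str:
    """Label for the age class containing ``age_years`` (completed years)."""
    if age_years < 0:
        raise ValueError(f"age must be >= 0, got {age_years}")
    completed = math.floor(age_years) if age_years >= 1 else age_years
    for label, lo, hi in classes:
        if lo <= completed < hi:
            return label
    raise ValueError(f"age {age_years} y is outside the covered range (0-74 completed years)")


def _check_days(day_index: pd.Series) -> None:
    bad = set(day_index.unique()) - {1, 2}
    if bad:
        raise StructuralError(
            f"diary day_index values must be 1 or 2; found {sorted(bad)}"
        )


def individual_intake(
    diaries: pd.DataFrame, composition: pd.DataFrame, individual_id: str
) -> IndividualIntake:
    """Two-day-mean intake of one individual, entry by entry.

    Reference implementation over :func:`ferrodiet.composition.decompose_item`;
    the cohort-level path (:func:`compute_intakes`) is vectorized but must
    agree with this one.
    """
    rows = diaries[diaries["individual_id"] == individual_id]
    _check_days(rows["day_index"]) if len(rows) else None
    records = {r.food_code: r for r in records_from_frame(composition)}
    unknown = set(rows["food_code"]) - set(records)
    if unknown:
        raise UnknownFoodError(f"unknown food codes in diary: {sorted(unknown)}")

    day_totals = {1: ComponentAmounts(), 2: ComponentAmounts()}
    day_grams = {1: 0.0, 2: 0.0}
    day_cereal = {1: 0.0, 2: 0.0}
    day_wg = {1: 0.0, 2: 0.0}
    day_brown = {1: 0.0, 2: 0.0}
    for _, row in rows.iterrows():
        rec = records[row["food_code"]]
        parts = decompose_item(rec, row["grams"])
        day = int(row["day_index"])
        day_totals[day] = day_totals[day] + parts
        day_grams[day] += row["grams"]
        if rec.category == CEREAL_CATEGORY:
            day_cereal[day] += row["grams"]
        day_wg[day] += parts.wheat_g * rec.wholegrain_share
        day_brown[day] += parts.rice_g * rec.brown_share

    mean2 = lambda d: (d[1] + d[2]) / 2.0
    comp = day_totals[1] + day_totals[2]
    wheat_g = (comp.wheat_g) / 2.0
    rice_g = (comp.rice_g) / 2.0
    energy = (comp.wheat_kcal + comp.rice_kcal + comp.other_kcal) / 2.0
    iron = (comp.wheat_iron_mg + comp.rice_iron_mg + comp.other_iron_mg) / 2.0
    wg = mean2(day_wg)
    brown = mean2(day_brown)
    return IndividualIntake(
        individual_id=individual_id,
        total_g_day=mean2(day_grams),
        energy_kcal_day=energy,
        iron_mg_day=iron,
        wheat_g_day=wheat_g,
        rice_g_day=rice_g,
        cereal_g_day=mean2(day_cereal),
        wheat_kcal_day=comp.wheat_kcal / 2.0,
        rice_kcal_day=comp.rice_kcal / 2.0,
        wheat_iron_mg_day=comp.wheat_iron_mg / 2.0,
        rice_iron_mg_day=comp.rice_iron_mg / 2.0,
        other_iron_mg_day=comp.other_iron_mg / 2.0,
        wholegrain_share=wg / wheat_g if wheat_g > 0 else 0.0,
        brown_share=brown / rice_g if rice_g > 0 else 0.0,
        iron_density_per_1000kcal=1000.0 * iron / energy if energy > 0 else float("nan"),
    )


def compute_intakes(
    individuals: pd.DataFrame, diaries: pd.DataFrame, composition: pd.DataFrame
) -> pd.DataFrame:
    """Two-day-mean intakes for a whole cohort (vectorized).

    ``individuals`` needs ``individual_id``, ``sex`` and ``age_years``
    columns; every diary food code must exist in the composition table.
    Individuals without diary entries on a day contribute zeros for that
    day (an empty diary day is a valid observation of no intake).
    """
    _check_days(diaries["day_index"])
    unknown = set(diaries["food_code"]) - set(composition["food_code"])
    if unknown:
        raise UnknownFoodError(f"unknown food codes in diaries: {sorted(unknown)}")

    d = diaries.merge(composition, on="food_code", how="left", validate="many_to_one")
    wheat_blend = (
        d["wholegrain_share"] * d["iron_density_wheat_whole"]
        + (1.0 - d["wholegrain_share"]) * d["iron_density_wheat_refined"]
    )
    rice_blend = (
        d["brown_share"] * d["iron_density_rice_brown"]
        + (1.0 - d["brown_share"]) * d["iron_density_rice_white"]
    )
    d["wheat_g"] = d["grams"] * d["wheat_fraction"]
    d["rice_g"] = d["grams"] * d["rice_fraction"]
    d["kcal"] = d["grams"] * d["energy_density"]
    d["iron_mg"] = d["grams"] * d["iron_density"]
    d["wheat_kcal"] = d["wheat_g"] * d["energy_density"]
    d["rice_kcal"] = d["rice_g"] * d["energy_density"]
    d["wheat_iron_mg"] = d["wheat_g"] * wheat_blend
    d["rice_iron_mg"] = d["rice_g"] * rice_blend
    d["other_iron_mg"] = (d["iron_mg"] - d["wheat_iron_mg"] - d["rice_iron_mg"]).clip(lower=0.0)
    d["cereal_g"] = np.where(d["category"] == CEREAL_CATEGORY, d["grams"], 0.0)
    d["wholegrain_wheat_g"] = d["wheat_g"] * d["wholegrain_share"]
    d["brown_rice_g"] = d["rice_g"] * d["brown_share"]

    sums = {
        "total_g_day": "grams",
        "energy_kcal_day": "kcal",
        "iron_mg_day": "iron_mg",
        "wheat_g_day": "wheat_g",
        "rice_g_day": "rice_g",
        "cereal_g_day": "cereal_g",
        "wheat_kcal_day": "wheat_kcal",
        "rice_kcal_day": "rice_kcal",
        "wheat_iron_mg_day": "wheat_iron_mg",
        "rice_iron_mg_day": "rice_iron_mg",
        "other_iron_mg_day": "other_iron_mg",
        "wholegrain_wheat_g_day": "wholegrain_wheat_g",
        "brown_rice_g_day": "brown_rice_g",
    }
    per_day = (
        d.groupby(["individual_id", "day_index"], sort=False)[list(sums.values())]
        .sum()
        .rename(columns={v: k for k, v in sums.items()})
    )
    # Average the two days; missing (individual, day) cells are zero intake.
    full_index = pd.MultiIndex.from_product(
        [individuals["individual_id"], [1, 2]], names=["individual_id", "day_index"]
    )
    per_day = per_day.reindex(full_index, fill_value=0.0)
    intakes = per_day.groupby(level="individual_id", sort=False).mean()

    out = individuals.merge(intakes, left_on="individual_id", right_index=True)
    if "age_class" not in out.columns:
        out["age_class"] = [assign_age_class(a) for a in out["age_years"]]
    wheat = out["wheat_g_day"]
    rice = out["rice_g_day"]
    out["wholegrain_share"] = np.where(wheat > 0, out["wholegrain_wheat_g_day"] / wheat.replace(0, np.nan), 0.0)
    out["brown_share"] = np.where(rice > 0, out["brown_rice_g_day"] / rice.replace(0, np.nan), 0.0)
    out["iron_density_per_1000kcal"] = np.where(
        out["energy_kcal_day"] > 0,
        1000.0 * out["iron_mg_day"] / out["energy_kcal_day"].replace(0, np.nan),
        np.nan,
    )
    return out


def group_summary(values, group: tuple = ()) -> GroupSummary:
    """Mean, sample SD, median and P5/P95 of one variable in one group."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError(f"group {group!r} has no values to summarize")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return GroupSummary(
        group=group,
        n=int(values.size),
        mean=float(np.mean(values)),
        sd=sd,
        median=float(np.median(values)),
        p5=float(np.percentile(values, 5)),
        p95=float(np.percentile(values, 95)),
    )


def summarize_by_group(
    intakes: pd.DataFrame,
    variables: list[str],
    by: list[str] = ("sex", "age_class"),
    include_overall: bool = True,
) -> pd.DataFrame:
    """Tidy long-format summaries: one row per group x variable."""
    by = list(by)
    rows = []

    def emit(frame: pd.DataFrame, key: tuple) -> None:
        for var in variables:
            s = group_summary(frame[var].dropna().to_numpy(), group=key + (var,))
            rows.append(
                dict(zip(by, key))
                | {
                    "variable": var,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "median": s.median,
                    "p5": s.p5,
                    "p95": s.p95,
                }
            )

    for key, frame in intakes.groupby(by, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        emit(frame, key)
    if include_overall and "sex" in by:
        for sex, frame in intakes.groupby("sex", sort=False):
            emit(frame, (sex,) + ("all",) * (len(by) - 1))
        emit(intakes, ("all",) * len(by))
    return pd.DataFrame(rows)
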