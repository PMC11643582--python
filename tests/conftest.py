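import pandas as pd
import pytest
from hypothesis import settings

from ferrodiet.composition import SCHEMA_COLUMNS

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def comp_row(food_code, **overrides):
    """One composition row with sane defaults, overridable per test."""
    row = {
        "food_code": food_code,
        "category": "cereals",
        "energy_density": 2.0,
        "iron_density": 0.01,
        "wheat_fraction": 0.0,
        "rice_fraction": 0.0,
        "wholegrain_share": 0.0,
        "brown_share": 0.0,
        "iron_density_wheat_refined": 0.010,
        "iron_density_wheat_whole": 0.020,
        "iron_density_rice_white": 0.004,
        "iron_density_rice_brown": 0.012,
    }
    row.update(overrides)
    return row


def comp_frame(*rows):
    return pd.DataFrame(list(rows), columns=SCHEMA_COLUMNS)


@pytest.fixture
def bread_table():
    """A small but decomposition-exercising composition table.

    ``bread``: 70% refined wheat, component iron 0.7 mg/100 g, item iron
    0.9 mg/100 g (so 0.2 mg is non-wheat) — the hand-arithmetic fixture.
    """
    return comp_frame(
        comp_row(
            "bread",
            energy_density=2.8,
            iron_density=0.009,
            wheat_fraction=0.7,
            iron_density_wheat_refined=0.010,
            iron_density_wheat_whole=0.020,
        ),
        comp_row(
            "wholegrain_bread",
            energy_density=2.6,
            iron_density=0.0145,
            wheat_fraction=0.7,
            wholegrain_share=1.0,
        ),
        comp_row(
            "rice_dish",
            category="composite_dishes",
            energy_density=1.5,
            iron_density=0.0030,
            rice_fraction=0.5,
        ),
        comp_row("apple", category="fruit", energy_density=0.5, iron_density=0.001),
    )


@pytest.fixture
def single_adult():
    """One 40-year-old male with a constant 13.1 mg iron/day diet."""
    individuals = pd.DataFrame(
        {"individual_id": ["p1"], "sex": ["male"], "age_years": [40.0]}
    )
    composition = comp_frame(
        comp_row("staple", energy_density=2.0, iron_density=0.0131)
    )
    diaries = pd.DataFrame(
        {
            "individual_id": ["p1", "p1"],
            "day_index": [1, 2],
            "food_code": ["staple", "staple"],
            "grams": [1000.0, 1000.0],
        }
    )
    return individuals, diaries, composition
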