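"""Food composition tables and wheat/rice recipe decomposition.

A composition record describes one coded food: its energy and iron density
per gram as consumed, the recipe fractions of wheat and rice it contains
(grams of grain per gram of food), and how those grain components split into
refined/wholegrain wheat and white/brown rice, each with its own iron
density.  Decomposition attributes the mass, energy and iron of a consumed
item to a wheat part, a rice part and a residual "other" part; the three
parts always sum back to the item totals.

Energy is attributed mass-proportionally: the grain component inherits the
energy density of the food that carries it.  Iron is attributed through the
component iron densities, with the residual iron assigned to "other".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import pandas as pd

from .errors import TableValidationError

logger = logging.getLogger(__name__)

#: Columns a composition CSV must provide, in canonical order.
SCHEMA_COLUMNS = [
    "food_code",
    "category",
    "energy_density",
    "iron_density",
    "wheat_fraction",
    "rice_fraction",
    "wholegrain_share",
    "brown_share",
    "iron_density_wheat_refined",
    "iron_density_wheat_whole",
    "iron_density_rice_white",
    "iron_density_rice_brown",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class FoodCompositionRecord:
    """Per-food densities and recipe fractions.

    Densities are per gram of food as consumed (kcal/g, mg/g); fractions are
    grams of grain per gram of food; shares split the grain component into
    its wholegrain/brown versus refined/white variants.
    """

    food_code: str
    category: str
    energy_density: float
    iron_density: float
    wheat_fraction: float = 0.0
    rice_fraction: float = 0.0
    wholegrain_share: float = 0.0
    brown_share: float = 0.0
    iron_density_wheat_refined: float = 0.0
    iron_density_wheat_whole: float = 0.0
    iron_density_rice_white: float = 0.0
    iron_density_rice_brown: float = 0.0

    @property
    def wheat_iron_density(self) -> float:
        """Share-weighted iron density of the wheat component (mg/g wheat)."""
        s = self.wholegrain_share
        return s * self.iron_density_wheat_whole + (1.0 - s) * self.iron_density_wheat_refined

    @property
    def rice_iron_density(self) -> float:
        """Share-weighted iron density of the rice component (mg/g rice)."""
        s = self.brown_share
        return s * self.iron_density_rice_brown + (1.0 - s) * self.iron_density_rice_white


@dataclass
class ComponentAmounts:
    """Mass, energy and iron of one consumed item split by origin."""

    wheat_g: float = 0.0
    rice_g: float = 0.0
    other_g: float = 0.0
    wheat_kcal: float = 0.0
    rice_kcal: float = 0.0
    other_kcal: float = 0.0
    wheat_iron_mg: float = 0.0
    rice_iron_mg: float = 0.0
    other_iron_mg: float = 0.0

    def __add__(self, other: "ComponentAmounts") -> "ComponentAmounts":
        return ComponentAmounts(
            **{
                f.name: getattr(self, f.name) + getattr(other, f.name)
                for f in fields(self)
            }
        )


def validate_record(record: FoodCompositionRecord, row: int | str = "?") -> None:
    """Raise :class:`TableValidationError` if the record violates an invariant."""

    def fail(field: str, msg: str) -> None:
        raise TableValidationError(
            f"composition row {row} (food_code={record.food_code!r}), field {field!r}: {msg}"
        )

    for field in ("energy_density", "iron_density"):
        if not getattr(record, field) >= 0:
            fail(field, "density must be >= 0")
    for field in ("wheat_fraction", "rice_fraction", "wholegrain_share", "brown_share"):
        value = getattr(record, field)
        if not 0.0 <= value <= 1.0:
            fail(field, f"must lie in [0, 1], got {value}")
    if record.wheat_fraction + record.rice_fraction > 1.0 + _REL_TOL:
        fail("wheat_fraction", "wheat_fraction + rice_fraction must not exceed 1")
    for field in (
        "iron_density_wheat_refined",
        "iron_density_wheat_whole",
        "iron_density_rice_white",
        "iron_density_rice_brown",
    ):
        if not getattr(record, field) >= 0:
            fail(field, "component iron density must be >= 0")
    if record.iron_density_wheat_whole < record.iron_density_wheat_refined:
        fail(
            "iron_density_wheat_whole",
            "wholegrain wheat iron density must be >= refined wheat iron density",
        )
    if record.iron_density_rice_brown < record.iron_density_rice_white:
        fail(
            "iron_density_rice_brown",
            "brown rice iron density must be >= white rice iron density",
        )
    implied = (
        record.wheat_fraction * record.wheat_iron_density
        + record.rice_fraction * record.rice_iron_density
    )
    if implied > record.iron_density * (1.0 + _REL_TOL) + _REL_TOL:
        fail(
            "iron_density",
            f"component-implied iron {implied:.6g} mg/g exceeds item iron density "
            f"{record.iron_density:.6g} mg/g",
        )


def records_from_frame(table: pd.DataFrame) -> list[FoodCompositionRecord]:
    """Convert a validated composition frame into records, keyed by row order."""
    return [
        FoodCompositionRecord(**{c: row[c] for c in SCHEMA_COLUMNS})
        for _, row in table.iterrows()
    ]


def validate_composition_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, types and per-row invariants of a composition frame."""
    missing = [c for c in SCHEMA_COLUMNS if c not in table.columns]
    if missing:
        raise TableValidationError(f"composition table is missing columns: {missing}")
    duplicated = table["food_code"][table["food_code"].duplicated()]
    if len(duplicated):
        raise TableValidationError(
            f"duplicate food_code values: {sorted(set(duplicated))}"
        )
    table = table[SCHEMA_COLUMNS].copy()
    numeric = SCHEMA_COLUMNS[2:]
    table[numeric] = table[numeric].astype(float)
    if table[numeric].isna().any().any():
        bad = table[numeric].isna().any()
        raise TableValidationError(
            f"non-numeric or missing values in columns: {list(bad[bad].index)}"
        )
    for i, record in enumerate(records_from_frame(table)):
        validate_record(record, row=i)
    return table


def load_composition_table(path) -> pd.DataFrame:
    """Load a composition CSV and validate every record.

    Returns the validated frame in canonical column order.  Raises
    :class:`TableValidationError` naming the offending row and field on any
    schema or invariant violation (missing column, fraction out of range,
    wholegrain iron density below refined, duplicate food code, ...).
    """
    return validate_composition_frame(pd.read_csv(path))


def decompose_item(record: FoodCompositionRecord, grams: float) -> ComponentAmounts:
    """Split ``grams`` of a food into wheat-, rice- and other-derived amounts.

    Wheat mass is ``grams * wheat_fraction``; wheat iron is wheat mass times
    the share-weighted component iron density; wheat energy is the wheat
    mass times the food's energy density (mass-proportional attribution).
    The rice component is analogous and "other" is the remainder, so the
    three components conserve the item totals.  Residual iron that would be
    negative beyond rounding noise is clamped to zero with a warning.
    """
    if grams < 0:
        raise ValueError(f"grams must be >= 0, got {grams}")
    total_kcal = grams * record.energy_density
    total_iron = grams * record.iron_density

    wheat_g = grams * record.wheat_fraction
    rice_g = grams * record.rice_fraction
    wheat_iron = wheat_g * record.wheat_iron_density
    rice_iron = rice_g * record.rice_iron_density
    other_iron = total_iron - wheat_iron - rice_iron
    if other_iron < 0:
        if other_iron < -_REL_TOL * max(total_iron, 1.0):
            logger.warning(
                "food %s: component iron exceeds item iron by %.3g mg; clamping to 0",
                record.food_code,
                -other_iron,
            )
        other_iron = 0.0
    return ComponentAmounts(
        wheat_g=wheat_g,
        rice_g=rice_g,
        other_g=grams - wheat_g - rice_g,
        wheat_kcal=wheat_g * record.energy_density,
        rice_kcal=rice_g * record.energy_density,
        other_kcal=total_kcal
        - wheat_g * record.energy_density
        - rice_g * record.energy_density,
        wheat_iron_mg=wheat_iron,
        rice_iron_mg=rice_iron,
        other_iron_mg=other_iron,
    )
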