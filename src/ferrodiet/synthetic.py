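"""Synthetic two-day dietary survey generator.

The national survey micro-data this pipeline was designed around are not
redistributable, so this module generates cohorts with the same statistical
structure: sex x age-class stratification with the published group sizes,
two non-consecutive diary days (>= 15 days apart) per person, right-skewed
(lognormal) intake distributions calibrated to published group means and
SDs for total food mass, energy, iron, wheat and rice amounts, zero-inflated
rice consumption, and wheat/rice embedded in composite recipes so that the
recipe decomposition downstream is non-trivial.

Construction is additive and exact in expectation: each person draws latent
two-day-mean totals (iron, energy, mass, wheat grams, rice grams); wheat
and rice grams are laid out across cereal and composite foods with fixed
allocation weights; the iron and energy not supplied by those foods are
filled by two aggregate non-grain foods solved to match the person's
targets, and water tops up total mass.  Day totals are the latent mean
times (1 +- delta) with a truncated-normal day effect, so the two-day mean
is preserved exactly.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .adequacy import FEMALE, MALE
from .composition import SCHEMA_COLUMNS, validate_composition_frame
from .errors import ConfigurationError
from .intake import AGE_CLASSES
from .scenarios import ComponentDensities

AREAS = ("northwest", "northeast", "centre", "south_islands")


@dataclass(frozen=True)
class GroupTargets:
    """Calibration targets for one sex x age-class cell (per-day units)."""

    n: int
    iron_mean: float
    iron_sd: float
    energy_mean: float
    energy_sd: float
    wheat_mean: float
    wheat_sd: float
    rice_mean: float
    rice_sd: float
    total_g_mean: float
    total_g_sd: float


# Published group summaries of the Italian national dietary survey
# (IV SCAI 2017-2020): sample size, total iron (mg/day), energy (kcal/day),
# wheat amount (g/day), rice amount (g/day), total food+beverage mass
# (g/day), each as mean and SD.  These are the generator's default study
# conditions.
DEFAULT_GROUP_TARGETS: dict[tuple[str, str], GroupTargets] = {
    (MALE, "<1"): GroupTargets(75, 6.4, 3.3, 892, 243, 29.3, 28.9, 4.7, 7.2, 1208, 291),
    (MALE, "1-2"): GroupTargets(162, 6.3, 2.6, 1133, 273, 66.7, 33.0, 12.9, 25.0, 1500, 443),
    (MALE, "3-9"): GroupTargets(168, 7.8, 2.7, 1545, 410, 102.5, 51.8, 18.3, 30.8, 2011, 582),
    (MALE, "10-17"): GroupTargets(138, 11.4, 3.7, 2218, 573, 163.1, 78.1, 30.5, 52.8, 2971, 780),
    (MALE, "18-64"): GroupTargets(346, 13.1, 4.1, 2270, 563, 149.8, 80.9, 33.3, 43.3, 3150, 820),
    (MALE, "65-74"): GroupTargets(65, 14.2, 4.6, 2135, 619, 156.7, 76.1, 18.2, 25.2, 3010, 715),
    (FEMALE, "<1"): GroupTargets(75, 5.0, 3.5, 838, 235, 29.5, 29.5, 2.7, 5.2, 1131, 341),
    (FEMALE, "1-2"): GroupTargets(160, 6.1, 2.7, 1084, 241, 63.8, 29.2, 15.9, 54.0, 1509, 396),
    (FEMALE, "3-9"): GroupTargets(171, 7.1, 2.2, 1411, 327, 86.0, 41.8, 22.6, 28.7, 1828, 488),
    (FEMALE, "10-17"): GroupTargets(138, 9.8, 3.2, 1779, 463, 121.1, 58.3, 21.3, 26.5, 2701, 805),
    (FEMALE, "18-64"): GroupTargets(380, 10.3, 3.5, 1718, 402, 107.8, 60.6, 25.7, 37.0, 2744, 745),
    (FEMALE, "65-74"): GroupTargets(91, 10.3, 3.1, 1630, 429, 121.1, 61.0, 15.1, 20.8, 2668, 553),
}


@dataclass(frozen=True)
class FoodDef:
    code: str
    category: str
    energy_density: float  # kcal/g as consumed
    wheat_fraction: float = 0.0
    rice_fraction: float = 0.0
    wholegrain_share: float = 0.0
    brown_share: float = 0.0
    other_iron: float = 0.0  # non-grain iron margin, mg/g


# The synthetic food list: pure grain foods, composite recipes with grain
# fractions strictly inside (0, 1), and non-grain aggregates used to fill
# the rest of the diet.  Energy densities are typical as-consumed values;
# grain fractions are flour/raw-grain equivalents per gram of food.
FOOD_DEFS: tuple[FoodDef, ...] = (
    FoodDef("wheat_flour_refined", "cereals", 3.40, wheat_fraction=1.0),
    FoodDef("wheat_flour_whole", "cereals", 3.30, wheat_fraction=1.0, wholegrain_share=1.0),
    FoodDef("white_bread", "cereals", 2.80, wheat_fraction=0.65, other_iron=0.0003),
    FoodDef("wholegrain_bread", "cereals", 2.60, wheat_fraction=0.65, wholegrain_share=1.0, other_iron=0.0003),
    FoodDef("pasta_cooked", "cereals", 1.55, wheat_fraction=0.40, other_iron=0.0005),
    FoodDef("biscuits", "cereals", 4.40, wheat_fraction=0.70, other_iron=0.0004),
    FoodDef("pizza_margherita", "composite_dishes", 2.60, wheat_fraction=0.45, other_iron=0.0030),
    FoodDef("white_rice_raw", "cereals", 3.60, rice_fraction=1.0),
    FoodDef("white_rice_cooked", "cereals", 1.30, rice_fraction=0.35, other_iron=0.0001),
    FoodDef("brown_rice_raw", "cereals", 3.50, rice_fraction=1.0, brown_share=1.0),
    FoodDef("brown_rice_cooked", "cereals", 1.25, rice_fraction=0.35, brown_share=1.0, other_iron=0.0001),
    FoodDef("rice_salad", "composite_dishes", 1.80, rice_fraction=0.30, other_iron=0.0020),
    FoodDef("meat_fish_legumes", "meat_fish_eggs_legumes", 1.80, other_iron=0.0250),
    FoodDef("mixed_plant_foods", "vegetables_fruit_dairy", 1.00, other_iron=0.0005),
    FoodDef("water_beverages", "beverages", 0.0001, other_iron=0.000001),
)

# How each person's refined/wholegrain wheat and white/brown rice grams are
# spread across the foods above (fraction of the grain component).
REFINED_WHEAT_ALLOCATION = {
    "wheat_flour_refined": 0.10,
    "white_bread": 0.35,
    "pasta_cooked": 0.30,
    "biscuits": 0.10,
    "pizza_margherita": 0.15,
}
WHOLE_WHEAT_ALLOCATION = {"wholegrain_bread": 0.80, "wheat_flour_whole": 0.20}
WHITE_RICE_ALLOCATION = {
    "white_rice_cooked": 0.65,
    "rice_salad": 0.25,
    "white_rice_raw": 0.10,
}
BROWN_RICE_ALLOCATION = {"brown_rice_cooked": 0.80, "brown_rice_raw": 0.20}

_FILLER_RICH = "meat_fish_legumes"
_FILLER_LEAN = "mixed_plant_foods"
_WATER = "water_beverages"

#: Minimum gap between the two survey days, in days.
MIN_DAY_GAP = 15


@dataclass(frozen=True)
class PopulationConfig:
    """Study conditions for one synthetic cohort.

    Group sizes and intake targets default to the published survey values;
    a subset of (sex, age-class) cells may be supplied to simulate a single
    stratum.  ``rice_zero_prob`` is the probability that a person consumes
    no rice at all; ``wholegrain_share0`` / ``brown_share0`` are the
    baseline population shares of wholegrain wheat and brown rice;
    ``within_person_cv`` controls day-to-day variation around each
    person's latent mean.
    """

    seed: int
    intake_targets: dict[tuple[str, str], GroupTargets] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_TARGETS)
    )
    group_sizes: dict[tuple[str, str], int] | None = None
    rice_zero_prob: float = 0.25
    wholegrain_share0: float = 0.08
    brown_share0: float = 0.05
    within_person_cv: float = 0.3
    densities: ComponentDensities = field(default_factory=ComponentDensities)
    age_class_bounds: tuple = tuple(AGE_CLASSES)

    def sizes(self) -> dict[tuple[str, str], int]:
        if self.group_sizes is not None:
            return dict(self.group_sizes)
        return {k: t.n for k, t in self.intake_targets.items()}

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed: an integer seed is mandatory")
        for name in ("rice_zero_prob", "wholegrain_share0", "brown_share0"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}: must lie in [0, 1], got {value}")
        if not 0.0 <= self.within_person_cv < 1.0:
            raise ConfigurationError(
                f"within_person_cv: must lie in [0, 1), got {self.within_person_cv}"
            )
        labels = [label for label, _, _ in self.age_class_bounds]
        cursor = 0.0
        for label, lo, hi in self.age_class_bounds:
            if lo != cursor:
                raise ConfigurationError(
                    f"age_class_bounds: classes must be disjoint and cover 0-74 y "
                    f"(gap/overlap at {lo})"
                )
            cursor = hi
        if cursor < 75.0:
            raise ConfigurationError("age_class_bounds: classes must cover ages up to 74 y")
        for key, n in self.sizes().items():
            sex, cls = key
            if sex not in (MALE, FEMALE):
                raise ConfigurationError(f"group_sizes: unknown sex {sex!r}")
            if cls not in labels:
                raise ConfigurationError(f"group_sizes: unknown age class {cls!r}")
            if n < 1:
                raise ConfigurationError(f"group_sizes: size for {key} must be >= 1, got {n}")
            if key not in self.intake_targets:
                raise ConfigurationError(f"intake_targets: no targets for group {key}")
        for key, t in self.intake_targets.items():
            for name in ("iron_mean", "energy_mean", "wheat_mean", "total_g_mean"):
                if not getattr(t, name) > 0:
                    raise ConfigurationError(
                        f"intake_targets[{key}].{name}: target mean must be > 0"
                    )
            if not t.rice_mean >= 0:
                raise ConfigurationError(f"intake_targets[{key}].rice_mean: must be >= 0")
            for name in ("iron_sd", "energy_sd", "wheat_sd", "rice_sd", "total_g_sd"):
                if getattr(t, name) < 0:
                    raise ConfigurationError(
                        f"intake_targets[{key}].{name}: SD must be >= 0"
                    )


def _lognormal_from_z(mean: float, sd: float, z: np.ndarray) -> np.ndarray:
    """Lognormal values moment-matched to (mean, sd), driven by N(0,1) scores."""
    if mean <= 0:
        return np.zeros(z.shape)
    if sd <= 0:
        return np.full(z.shape, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.exp(np.log(mean) - sigma2 / 2.0 + np.sqrt(sigma2) * z)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Independent lognormal draws moment-matched to the given mean and SD."""
    return _lognormal_from_z(mean, sd, rng.standard_normal(n))


# One-factor loadings tying a person's latent totals together: people who
# eat more overall eat more of everything, which is what keeps the residual
# (non-grain) iron/energy mix within a plausible nutrient-density range.
_FACTOR_LOADINGS = {"energy": 0.85, "iron": 0.80, "mass": 0.70, "wheat": 0.50}


def _correlated_scores(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    factor = rng.standard_normal(n)
    return {
        name: lam * factor + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        for name, lam in _FACTOR_LOADINGS.items()
    }


def generate_composition_table(config: PopulationConfig) -> pd.DataFrame:
    """Composition table for the synthetic food list.

    Item iron density is the grain-component iron implied by the config's
    component densities plus each food's non-grain margin, so component
    iron never exceeds item iron by construction.
    """
    config.validate()
    d = config.densities
    rows = []
    for f in FOOD_DEFS:
        wheat_blend = (
            f.wholegrain_share * d.wheat_whole + (1 - f.wholegrain_share) * d.wheat_refined
        )
        rice_blend = f.brown_share * d.rice_brown + (1 - f.brown_share) * d.rice_white
        rows.append(
            {
                "food_code": f.code,
                "category": f.category,
                "energy_density": f.energy_density,
                "iron_density": f.wheat_fraction * wheat_blend
                + f.rice_fraction * rice_blend
                + f.other_iron,
                "wheat_fraction": f.wheat_fraction,
                "rice_fraction": f.rice_fraction,
                "wholegrain_share": f.wholegrain_share,
                "brown_share": f.brown_share,
                "iron_density_wheat_refined": d.wheat_refined,
                "iron_density_wheat_whole": d.wheat_whole,
                "iron_density_rice_white": d.rice_white,
                "iron_density_rice_brown": d.rice_brown,
            }
        )
    return validate_composition_frame(pd.DataFrame(rows, columns=SCHEMA_COLUMNS))


def _cell_ages(rng, cls: str, bounds, n: int) -> np.ndarray:
    for label, lo, hi in bounds:
        if label == cls:
            if hi <= 1.0:  # infants: survey covers 3-11 months
                return rng.uniform(0.25, 0.999, n)
            return rng.uniform(max(lo, 1.0), hi, n)
    raise ConfigurationError(f"unknown age class {cls!r}")


def _survey_days(rng, n: int) -> tuple[np.ndarray, np.ndarray]:
    start = datetime.date(2018, 1, 1).toordinal()
    d1 = start + rng.integers(0, 700, n)
    d2 = d1 + MIN_DAY_GAP + rng.integers(0, 46, n)
    iso = np.vectorize(lambda o: datetime.date.fromordinal(int(o)).isoformat())
    return iso(d1), iso(d2)


def _day_split(rng, n: int, cv: float) -> np.ndarray:
    """Day-1 multiplier 1 + delta with delta ~ N(0, cv) truncated to (-0.95, 0.95)."""
    return 1.0 + np.clip(rng.normal(0.0, cv, n), -0.95, 0.95)


def generate_population(
    config: PopulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate individuals and two-day diaries for every configured cell.

    Returns ``(individuals, diaries)``.  Individuals carry sex, age,
    geographic area and the two survey-day dates (>= 15 days apart);
    diaries are one row per (individual, day, food) with grams consumed.
    Identical config and seed give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.densities
    food_by_code = {f.code: f for f in FOOD_DEFS}
    wheat_blend0 = (
        config.wholegrain_share0 * d.wheat_whole
        + (1 - config.wholegrain_share0) * d.wheat_refined
    )
    rice_blend0 = (
        config.brown_share0 * d.rice_brown + (1 - config.brown_share0) * d.rice_white
    )

    individuals = []
    diary_frames = []
    for (sex, cls) in sorted(config.sizes(), key=lambda k: (k[0], _class_order(config, k[1]))):
        n = config.sizes()[(sex, cls)]
        t = config.intake_targets[(sex, cls)]
        ids = np.array([f"{sex[0]}{cls}-{i:04d}" for i in range(n)])
        ages = _cell_ages(rng, cls, config.age_class_bounds, n)
        areas = np.array(AREAS)[rng.integers(0, len(AREAS), n)]
        day1, day2 = _survey_days(rng, n)
        holidays = rng.random((n, 2)) < 0.29

        scores = _correlated_scores(rng, n)
        iron_total = _lognormal_from_z(t.iron_mean, t.iron_sd, scores["iron"])
        energy_total = _lognormal_from_z(t.energy_mean, t.energy_sd, scores["energy"])
        mass_total = _lognormal_from_z(t.total_g_mean, t.total_g_sd, scores["mass"])
        wheat_g = _lognormal_from_z(t.wheat_mean, t.wheat_sd, scores["wheat"])

        eats_rice = rng.random(n) >= config.rice_zero_prob
        rice_g = np.zeros(n)
        if t.rice_mean > 0 and eats_rice.any():
            p_eat = max(1.0 - config.rice_zero_prob, 1e-9)
            cond_mean = t.rice_mean / p_eat
            cond_var = (t.rice_sd**2 + t.rice_mean**2) / p_eat - cond_mean**2
            cond_sd = np.sqrt(max(cond_var, (0.2 * cond_mean) ** 2))
            rice_g[eats_rice] = _lognormal(rng, cond_mean, cond_sd, int(eats_rice.sum()))

        # Lay grain components out over foods (two-day-mean grams per food).
        grams = {f.code: np.zeros(n) for f in FOOD_DEFS}
        for code, share in REFINED_WHEAT_ALLOCATION.items():
            grams[code] = (
                (1 - config.wholegrain_share0) * wheat_g * share
            ) / food_by_code[code].wheat_fraction
        for code, share in WHOLE_WHEAT_ALLOCATION.items():
            grams[code] = (
                config.wholegrain_share0 * wheat_g * share
            ) / food_by_code[code].wheat_fraction
        for code, share in WHITE_RICE_ALLOCATION.items():
            grams[code] = (
                (1 - config.brown_share0) * rice_g * share
            ) / food_by_code[code].rice_fraction
        for code, share in BROWN_RICE_ALLOCATION.items():
            grams[code] = (
                config.brown_share0 * rice_g * share
            ) / food_by_code[code].rice_fraction

        # Iron and energy already supplied by the grain-bearing foods.
        supplied_iron = np.zeros(n)
        supplied_kcal = np.zeros(n)
        for f in FOOD_DEFS:
            if grams[f.code].any():
                wheat_bl = (
                    f.wholegrain_share * d.wheat_whole
                    + (1 - f.wholegrain_share) * d.wheat_refined
                )
                rice_bl = f.brown_share * d.rice_brown + (1 - f.brown_share) * d.rice_white
                iron_density = (
                    f.wheat_fraction * wheat_bl + f.rice_fraction * rice_bl + f.other_iron
                )
                supplied_iron += grams[f.code] * iron_density
                supplied_kcal += grams[f.code] * f.energy_density

        # Fill residual iron and energy with the two non-grain aggregates.
        iron_res = np.maximum(iron_total - supplied_iron, 0.0)
        kcal_res = np.maximum(energy_total - supplied_kcal, 0.0)
        i_rich, e_rich = food_by_code[_FILLER_RICH].other_iron, food_by_code[_FILLER_RICH].energy_density
        i_lean, e_lean = food_by_code[_FILLER_LEAN].other_iron, food_by_code[_FILLER_LEAN].energy_density
        det = i_rich * e_lean - i_lean * e_rich
        g_rich = (iron_res * e_lean - i_lean * kcal_res) / det
        g_lean = (i_rich * kcal_res - e_rich * iron_res) / det
        # Degenerate residual mixes: keep the iron target exact, let energy drift.
        low_iron = g_rich < 0
        g_rich[low_iron] = 0.0
        g_lean[low_iron] = iron_res[low_iron] / i_lean
        high_iron = g_lean < 0
        g_lean[high_iron] = 0.0
        g_rich[high_iron] = iron_res[high_iron] / i_rich
        grams[_FILLER_RICH] = g_rich
        grams[_FILLER_LEAN] = g_lean

        solid = sum(grams[f.code] for f in FOOD_DEFS if f.code != _WATER)
        grams[_WATER] = np.maximum(mass_total - solid, 0.0)

        individuals.append(
            pd.DataFrame(
                {
                    "individual_id": ids,
                    "sex": sex,
                    "age_class": cls,
                    "age_years": ages,
                    "area": areas,
                    "day1_date": day1,
                    "day2_date": day2,
                    "day1_holiday": holidays[:, 0],
                    "day2_holiday": holidays[:, 1],
                }
            )
        )

        # Split every person's foods over the two days, preserving the mean.
        split_wheat = _day_split(rng, n, config.within_person_cv)
        split_rice = _day_split(rng, n, config.within_person_cv)
        one_day_rice = rng.random(n) < 0.35  # rice often eaten on one day only
        split_rice[one_day_rice] = np.where(rng.random(one_day_rice.sum()) < 0.5, 0.0, 2.0)
        split_other = _day_split(rng, n, config.within_person_cv)
        wheat_codes = set(REFINED_WHEAT_ALLOCATION) | set(WHOLE_WHEAT_ALLOCATION)
        rice_codes = set(WHITE_RICE_ALLOCATION) | set(BROWN_RICE_ALLOCATION)

        for f in FOOD_DEFS:
            g = grams[f.code]
            if not g.any():
                continue
            if f.code in wheat_codes:
                s = split_wheat
            elif f.code in rice_codes:
                s = split_rice
            else:
                s = split_other
            for day, factor in ((1, s), (2, 2.0 - s)):
                keep = g * factor > 1e-9
                if keep.any():
                    diary_frames.append(
                        pd.DataFrame(
                            {
                                "individual_id": ids[keep],
                                "day_index": day,
                                "food_code": f.code,
                                "grams": g[keep] * factor[keep],
                            }
                        )
                    )

    individuals_df = pd.concat(individuals, ignore_index=True)
    diaries_df = (
        pd.concat(diary_frames, ignore_index=True)
        .sort_values(["individual_id", "day_index", "food_code"], kind="stable")
        .reset_index(drop=True)
    )
    return individuals_df, diaries_df


def _class_order(config: PopulationConfig, cls: str) -> int:
    return [label for label, _, _ in config.age_class_bounds].index(cls)


@dataclass
class SurveyBundle:
    """A generated cohort: individuals, diaries and the composition table."""

    individuals: pd.DataFrame
    diaries: pd.DataFrame
    composition: pd.DataFrame
    config: PopulationConfig


def generate_survey(config: PopulationConfig) -> SurveyBundle:
    """Generate a full synthetic survey bundle from one config and seed."""
    individuals, diaries = generate_population(config)
    return SurveyBundle(
        individuals=individuals,
        diaries=diaries,
        composition=generate_composition_table(config),
        config=config,
    )


def config_from_yaml(path) -> PopulationConfig:
    """Build a :class:`PopulationConfig` from a flat YAML file.

    Recognized keys: ``seed`` (mandatory), ``rice_zero_prob``,
    ``wholegrain_share0``, ``brown_share0``, ``within_person_cv``,
    ``densities`` (mapping with the four component iron densities) and
    ``groups`` (list of mappings with sex, age_class, n and the ten target
    fields; omitted groups fall back to the published defaults).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ConfigurationError("seed: a seed is mandatory in the survey config")
    kwargs: dict = {"seed": int(raw["seed"])}
    for key in ("rice_zero_prob", "wholegrain_share0", "brown_share0", "within_person_cv"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "densities" in raw:
        kwargs["densities"] = ComponentDensities(**{k: float(v) for k, v in raw["densities"].items()})
    if "groups" in raw:
        targets = {}
        sizes = {}
        for g in raw["groups"]:
            key = (g["sex"], str(g["age_class"]))
            base = DEFAULT_GROUP_TARGETS.get(key)
            fields = {
                name: float(g[name]) if name in g else getattr(base, name)
                for name in (
                    "iron_mean", "iron_sd", "energy_mean", "energy_sd",
                    "wheat_mean", "wheat_sd", "rice_mean", "rice_sd",
                    "total_g_mean", "total_g_sd",
                )
            }
            n = int(g.get("n", base.n if base else 0))
            targets[key] = GroupTargets(n=n, **fields)
            sizes[key] = n
        kwargs["intake_targets"] = targets
        kwargs["group_sizes"] = sizes
    config = PopulationConfig(**kwargs)
    config.validate()
    return config


def single_group_config(
    sex: str, age_class: str, seed: int, n: int | None = None, **overrides
) -> PopulationConfig:
    """Config for one stratum only (handy for calibration experiments)."""
    key = (sex, age_class)
    targets = {key: DEFAULT_GROUP_TARGETS[key]}
    if n is not None:
        targets[key] = replace(targets[key], n=n)
    return PopulationConfig(seed=seed, intake_targets=targets, **overrides)
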