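"""Projection engine for climate-change and biofortification scenarios.

All scenarios hold consumed grams and energy fixed and act only on the iron
content of the wheat and rice components of the diet:

* ``basic``  - climate-change baseline: grain iron depleted by 20%
  (multiplier 0.8 on wheat and rice iron).
* ``s1``     - 30% biofortification of wheat and rice on top of the baseline
  (multiplier 0.8 * 1.3).
* ``s2``     - shift of wholegrain wheat consumption up to 50% of all wheat,
  on top of the baseline.
* ``s3``     - shift of brown rice consumption up to 100% of all rice, on
  top of the baseline.
* ``s4``     - cumulative: biofortification plus both consumption shifts.

A share shift replaces an individual's current wholegrain (brown) share s
with max(s, target): people already above the target are left unchanged.
The shifted component iron is wheat_g * blend(share) where blend(s) =
s * rho_whole + (1 - s) * rho_refined, then the depletion and
biofortification multipliers apply; the two steps commute.  Other-source
iron is untouched.

Significance of a scenario's mean increase over the baseline uses the
least-significant-delta rule on the current-diet iron distribution of each
group (see :mod:`ferrodiet.stats`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .adequacy import PriSchedule
from .errors import ConfigurationError, StructuralError

#: Age-class label excluded from every projection (reference data for
#: infants is weaning-driven and the projections are not defined for them).
INFANT_CLASS = "<1"


@dataclass(frozen=True)
class ComponentDensities:
    """Iron densities (mg per g of grain) of the four grain variants."""

    wheat_refined: float = 0.012
    wheat_whole: float = 0.024
    rice_white: float = 0.006
    rice_brown: float = 0.012

    def __post_init__(self):
        for name in ("wheat_refined", "wheat_whole", "rice_white", "rice_brown"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} iron density must be > 0")
        if self.wheat_whole < self.wheat_refined:
            raise ConfigurationError("wheat_whole must be >= wheat_refined")
        if self.rice_brown < self.rice_white:
            raise ConfigurationError("rice_brown must be >= rice_white")


@dataclass(frozen=True)
class ScenarioSpec:
    """One projection: multipliers on grain iron plus optional share targets.

    ``target_wholegrain_share`` / ``target_brown_share`` of ``None`` mean
    "unchanged" (keep each individual's current share).
    """

    name: str
    depletion_factor: float = 1.0
    biofort_factor: float = 1.0
    target_wholegrain_share: float | None = None
    target_brown_share: float | None = None

    def __post_init__(self):
        if not 0.0 < self.depletion_factor <= 1.0:
            raise ConfigurationError("depletion_factor must lie in (0, 1]")
        if self.biofort_factor < 1.0:
            raise ConfigurationError("biofort_factor must be >= 1")
        for field in ("target_wholegrain_share", "target_brown_share"):
            value = getattr(self, field)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{field} must lie in [0, 1] or be None")


def default_scenarios(
    depletion: float = 0.8,
    biofort: float = 1.3,
    wholegrain_target: float = 0.5,
    brown_target: float = 1.0,
) -> list[ScenarioSpec]:
    """The five study scenarios: baseline plus four corrective actions."""
    return [
        ScenarioSpec("basic", depletion_factor=depletion),
        ScenarioSpec("s1", depletion_factor=depletion, biofort_factor=biofort),
        ScenarioSpec("s2", depletion_factor=depletion, target_wholegrain_share=wholegrain_target),
        ScenarioSpec("s3", depletion_factor=depletion, target_brown_share=brown_target),
        ScenarioSpec(
            "s4",
            depletion_factor=depletion,
            biofort_factor=biofort,
            target_wholegrain_share=wholegrain_target,
            target_brown_share=brown_target,
        ),
    ]


def _shifted_component(iron, grams, share, target, rho_low, rho_high):
    """Component iron after an upward share shift, before multipliers.

    Uses the observed component iron directly so that an "unchanged" target
    is an exact identity; the shift adds grams * (share' - share) times the
    density difference between the high- and low-iron variants.
    """
    if target is None:
        return iron
    share = np.asarray(share, dtype=float)
    new_share = np.maximum(share, target)
    return iron + np.asarray(grams, dtype=float) * (new_share - share) * (rho_high - rho_low)


def apply_scenario(
    intakes: pd.DataFrame,
    spec: ScenarioSpec,
    densities: ComponentDensities,
) -> pd.DataFrame:
    """Adjusted iron intake per individual under ``spec``.

    ``intakes`` must carry per-day wheat/rice grams, component iron and
    current wholegrain/brown shares.  Returns a frame indexed like the
    input with adjusted ``wheat_iron_mg_day``, ``rice_iron_mg_day`` and
    total ``iron_mg_day``; grams and energy are never altered.
    """
    if densities is None:
        raise ConfigurationError("component densities are required to apply a scenario")
    required = [
        "wheat_iron_mg_day",
        "rice_iron_mg_day",
        "other_iron_mg_day",
        "wheat_g_day",
        "rice_g_day",
        "wholegrain_share",
        "brown_share",
    ]
    missing = [c for c in required if c not in intakes.columns]
    if missing:
        raise StructuralError(f"intake frame lacks columns required for scenarios: {missing}")

    mult = spec.depletion_factor * spec.biofort_factor
    wheat = (
        _shifted_component(
            intakes["wheat_iron_mg_day"],
            intakes["wheat_g_day"],
            intakes["wholegrain_share"],
            spec.target_wholegrain_share,
            densities.wheat_refined,
            densities.wheat_whole,
        )
        * mult
    )
    rice = (
        _shifted_component(
            intakes["rice_iron_mg_day"],
            intakes["rice_g_day"],
            intakes["brown_share"],
            spec.target_brown_share,
            densities.rice_white,
            densities.rice_brown,
        )
        * mult
    )
    out = pd.DataFrame(index=intakes.index)
    out["wheat_iron_mg_day"] = wheat
    out["rice_iron_mg_day"] = rice
    out["iron_mg_day"] = wheat + rice + intakes["other_iron_mg_day"]
    return out


def apply_scenario_individual(
    intake, spec: ScenarioSpec, densities: ComponentDensities
) -> float:
    """Adjusted total iron (mg/day) for a single :class:`IndividualIntake`."""
    frame = pd.DataFrame(
        [
            {
                "wheat_iron_mg_day": intake.wheat_iron_mg_day,
                "rice_iron_mg_day": intake.rice_iron_mg_day,
                "other_iron_mg_day": intake.other_iron_mg_day,
                "wheat_g_day": intake.wheat_g_day,
                "rice_g_day": intake.rice_g_day,
                "wholegrain_share": intake.wholegrain_share,
                "brown_share": intake.brown_share,
            }
        ]
    )
    return float(apply_scenario(frame, spec, densities)["iron_mg_day"].iloc[0])


def scenario_delta(
    intakes: pd.DataFrame,
    spec: ScenarioSpec,
    baseline_spec: ScenarioSpec,
    densities: ComponentDensities,
) -> pd.Series:
    """Per-individual iron difference between ``spec`` and ``baseline_spec``."""
    a = apply_scenario(intakes, spec, densities)["iron_mg_day"]
    b = apply_scenario(intakes, baseline_spec, densities)["iron_mg_day"]
    return a - b


def run_all_scenarios(
    intakes: pd.DataFrame,
    specs: list[ScenarioSpec],
    schedule: PriSchedule,
    densities: ComponentDensities,
    z: float = stats.DEFAULT_Z,
    baseline_name: str = "basic",
    exclude_infants: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level projection table and figure-ready adequacy series.

    Returns ``(results, series)``: one result row per (sex, age class,
    scenario) with mean iron, mean delta versus the named baseline
    scenario, the mean adequacy gap under the scenario, the group's least
    significant delta, and the significance flag; and a long-format frame
    of mean adequacy gaps (current diet, baseline, each scenario) for the
    per-sex adequacy figures.
    """
    names = [s.name for s in specs]
    if baseline_name not in names:
        raise ConfigurationError(f"baseline scenario {baseline_name!r} not among specs {names}")
    cohort = intakes[intakes["age_class"] != INFANT_CLASS] if exclude_infants else intakes
    if cohort.empty:
        raise StructuralError("no individuals left after excluding infants")

    pri = schedule.pri_series(cohort["sex"], cohort["age_years"])
    adjusted = {s.name: apply_scenario(cohort, s, densities)["iron_mg_day"] for s in specs}
    baseline = adjusted[baseline_name]

    results = []
    series = []
    for (sex, age_class), idx in cohort.groupby(["sex", "age_class"], sort=False).groups.items():
        current = cohort.loc[idx, "iron_mg_day"]
        n = len(idx)
        half_width = (
            stats.least_significant_delta(float(np.std(current, ddof=1)), n, z=z)
            if n >= 2
            else float("nan")
        )
        series.append(
            {
                "sex": sex,
                "age_class": age_class,
                "series": "current",
                "mean_gap_mg_day": float((current - pri.loc[idx]).mean()),
            }
        )
        for spec in specs:
            iron = adjusted[spec.name].loc[idx]
            delta = float((iron - baseline.loc[idx]).mean())
            gap = float((iron - pri.loc[idx]).mean())
            results.append(
                {
                    "sex": sex,
                    "age_class": age_class,
                    "scenario": spec.name,
                    "n": n,
                    "mean_iron_mg_day": float(iron.mean()),
                    "mean_delta_vs_baseline": delta,
                    "mean_gap_mg_day": gap,
                    "half_width_mg_day": half_width,
                    "significant": stats.flag_significant(delta, half_width)
                    if spec.name != baseline_name and np.isfinite(half_width)
                    else False,
                }
            )
            series.append(
                {
                    "sex": sex,
                    "age_class": age_class,
                    "series": spec.name,
                    "mean_gap_mg_day": gap,
                }
            )
    return pd.DataFrame(results), pd.DataFrame(series)
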