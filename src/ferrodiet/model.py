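"""Model-and-results interface over the intake/adequacy/scenario pipeline.

:class:`DietaryIronModel` is built from the three survey tables (individuals,
two-day diaries, food composition) plus a reference-intake schedule;
``fit()`` computes every individual's two-day-mean intake with wheat/rice
attribution and returns a :class:`DietaryIronResults` carrying the estimates.
Group summaries, adequacy gaps, confidence half-widths, rank tests, scenario
projections and plots all hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .adequacy import PriSchedule, add_gaps, group_adequacy
from .composition import load_composition_table, validate_composition_frame
from .intake import compute_intakes, summarize_by_group
from .scenarios import (
    INFANT_CLASS,
    ComponentDensities,
    ScenarioSpec,
    default_scenarios,
    run_all_scenarios,
)
from .synthetic import PopulationConfig, generate_survey


class DietaryIronModel:
    """Iron-intake analysis of a two-day dietary survey cohort."""

    def __init__(
        self,
        individuals: pd.DataFrame,
        diaries: pd.DataFrame,
        composition: pd.DataFrame,
        schedule: PriSchedule | None = None,
        densities: ComponentDensities | None = None,
    ):
        self.individuals = individuals
        self.diaries = diaries
        self.composition = validate_composition_frame(composition)
        self.schedule = schedule or PriSchedule.default()
        self.densities = densities or ComponentDensities()

    @classmethod
    def from_csv(
        cls,
        individuals_path,
        diaries_path,
        composition_path,
        schedule_path=None,
        densities: ComponentDensities | None = None,
    ) -> "DietaryIronModel":
        """Build the model from plain-CSV survey tables."""
        schedule = PriSchedule.from_csv(schedule_path) if schedule_path else None
        return cls(
            individuals=pd.read_csv(individuals_path),
            diaries=pd.read_csv(diaries_path),
            composition=load_composition_table(composition_path),
            schedule=schedule,
            densities=densities,
        )

    @classmethod
    def from_simulation(
        cls, config: PopulationConfig, schedule: PriSchedule | None = None
    ) -> "DietaryIronModel":
        """Build the model from a synthetic survey generated under ``config``."""
        bundle = generate_survey(config)
        return cls(
            individuals=bundle.individuals,
            diaries=bundle.diaries,
            composition=bundle.composition,
            schedule=schedule,
            densities=config.densities,
        )

    def fit(self) -> "DietaryIronResults":
        """Compute per-individual intakes and adequacy gaps."""
        intakes = compute_intakes(self.individuals, self.diaries, self.composition)
        intakes = add_gaps(intakes, self.schedule)
        return DietaryIronResults(self, intakes)


@dataclass
class DietaryIronResults:
    """Fitted intakes plus everything derived from them."""

    model: DietaryIronModel
    intakes: pd.DataFrame

    # -- group estimates ---------------------------------------------------
    def group_summaries(
        self, variables=("iron_mg_day",), include_overall: bool = True
    ) -> pd.DataFrame:
        return summarize_by_group(
            self.intakes, list(variables), include_overall=include_overall
        )

    def adequacy(self) -> pd.DataFrame:
        """Per-group adequacy-gap summaries (gaps computed per individual)."""
        rows = []
        for (sex, age_class), frame in self.intakes.groupby(["sex", "age_class"], sort=False):
            r = group_adequacy(frame["gap_mg_day"].to_numpy(), group=(sex, age_class))
            rows.append(
                {
                    "sex": sex,
                    "age_class": age_class,
                    "n": r.n,
                    "mean_gap_mg_day": r.mean_gap,
                    "median_gap_mg_day": r.median_gap,
                    "p5_gap_mg_day": r.p5_gap,
                    "p95_gap_mg_day": r.p95_gap,
                    "share_below_pri": r.share_below_pri,
                }
            )
        return pd.DataFrame(rows)

    def half_widths(self, z: float = stats.DEFAULT_Z) -> pd.DataFrame:
        """Least significant delta z*sd/sqrt(n) of mean iron intake per group."""
        rows = []
        for (sex, age_class), frame in self.intakes.groupby(["sex", "age_class"], sort=False):
            iron = frame["iron_mg_day"].to_numpy()
            if iron.size < 2:
                continue
            rows.append(
                {
                    "sex": sex,
                    "age_class": age_class,
                    "n": iron.size,
                    "sd": float(np.std(iron, ddof=1)),
                    "half_width_mg_day": stats.least_significant_delta(
                        float(np.std(iron, ddof=1)), iron.size, z=z
                    ),
                }
            )
        return pd.DataFrame(rows)

    # -- rank tests --------------------------------------------------------
    def compare_age_groups(self, variable: str, sex: str | None = None):
        """Kruskal-Wallis test of ``variable`` across age classes."""
        frame = self.intakes if sex is None else self.intakes[self.intakes["sex"] == sex]
        groups = [g[variable].dropna().to_numpy() for _, g in frame.groupby("age_class", sort=False)]
        return stats.kruskal_wallis([g for g in groups if g.size])

    def compare_sexes(self, variable: str):
        """Kruskal-Wallis (two-group) test of ``variable`` between sexes."""
        groups = [
            g[variable].dropna().to_numpy()
            for _, g in self.intakes.groupby("sex", sort=False)
        ]
        return stats.kruskal_wallis(groups)

    # -- projections -------------------------------------------------------
    def project(
        self,
        specs: list[ScenarioSpec] | None = None,
        z: float = stats.DEFAULT_Z,
        exclude_infants: bool = True,
    ) -> "ScenarioProjection":
        specs = specs if specs is not None else default_scenarios()
        results, series = run_all_scenarios(
            self.intakes,
            specs,
            self.model.schedule,
            self.model.densities,
            z=z,
            exclude_infants=exclude_infants,
        )
        return ScenarioProjection(results=results, series=series)

    # -- presentation ------------------------------------------------------
    def summary(self, variables=("iron_mg_day",)) -> str:
        """Plain-text survey-style summary table."""
        lines = ["Dietary iron intake summary (two-day means)", "=" * 66]
        table = self.group_summaries(variables)
        with pd.option_context("display.float_format", "{:0.2f}".format):
            lines.append(table.to_string(index=False))
        adequacy = self.adequacy()
        lines += ["", "Adequacy gaps vs PRI (mg/day; negative = inadequate)", "-" * 66]
        with pd.option_context("display.float_format", "{:0.2f}".format):
            lines.append(adequacy.to_string(index=False))
        return "\n".join(lines)

    def plot_adequacy(self, projection: "ScenarioProjection | None" = None, ax=None):
        """Bar chart of mean adequacy gaps per group, optionally by scenario."""
        from .plotting import plot_adequacy_gaps

        series = projection.series if projection is not None else None
        return plot_adequacy_gaps(self, series=series, ax=ax)


@dataclass
class ScenarioProjection:
    """Scenario results table plus figure-ready adequacy series."""

    results: pd.DataFrame
    series: pd.DataFrame

    def delta_table(self, scenario: str = "s4") -> pd.DataFrame:
        """Half-widths, deltas and significance flags for one scenario."""
        rows = self.results[self.results["scenario"] == scenario]
        return rows[
            [
                "sex",
                "age_class",
                "n",
                "half_width_mg_day",
                "mean_delta_vs_baseline",
                "significant",
            ]
        ].reset_index(drop=True)

    def summary(self) -> str:
        lines = ["Scenario projections (infants excluded)", "=" * 66]
        with pd.option_context("display.float_format", "{:0.3f}".format):
            lines.append(self.results.to_string(index=False))
        return "\n".join(lines)
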