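"""End-to-end orchestration: survey -> intakes -> adequacy -> scenarios.

``run_pipeline`` drives the whole analysis from a single run configuration
(synthetic generation or external CSV tables) and writes the report bundle:

* ``table1_intake_adequacy.csv``   - intake and adequacy summaries by group
* ``table2_wheat.csv`` / ``table2_rice.csv`` - grain quantity/energy/iron
* ``table3_cereal_contribution.csv`` - wheat/rice share of cereal intake
* ``table4_scenario_significance.csv`` - half-widths, s4 deltas, flags
* ``scenario_results.csv`` / ``figure_adequacy_series.csv`` - all scenarios
* ``group_comparisons.csv``        - Kruskal-Wallis tests per variable
* ``manifest.json``                - seed, config hash, package version

All tabular output is UTF-8 CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adequacy import PriSchedule
from .errors import ConfigurationError
from .model import DietaryIronModel, DietaryIronResults
from .scenarios import ScenarioSpec, default_scenarios
from .synthetic import PopulationConfig, config_from_yaml

logger = logging.getLogger(__name__)

GRAIN_VARIABLES = {
    "wheat": ["wheat_g_day", "wheat_kcal_day", "wheat_iron_mg_day"],
    "rice": ["rice_g_day", "rice_kcal_day", "rice_iron_mg_day"],
}


@dataclass
class RunConfig:
    """One pipeline run: data source, schedule, scenarios, output folder."""

    mode: str  # "synthetic" or "external-csv"
    outdir: Path
    population: PopulationConfig | None = None
    individuals_path: Path | None = None
    diaries_path: Path | None = None
    composition_path: Path | None = None
    schedule_path: Path | None = None
    scenarios: list[ScenarioSpec] | None = None
    z_value: float = 1.96

    def validate(self) -> None:
        if self.mode not in ("synthetic", "external-csv"):
            raise ConfigurationError(f"mode: must be 'synthetic' or 'external-csv', got {self.mode!r}")
        if self.mode == "synthetic" and self.population is None:
            raise ConfigurationError("population: a population config (with seed) is mandatory in synthetic mode")
        if self.mode == "external-csv":
            for name in ("individuals_path", "diaries_path", "composition_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(f"{name}: path missing or not resolvable: {path}")
        if self.schedule_path is not None and not Path(self.schedule_path).exists():
            raise ConfigurationError(f"schedule_path: not resolvable: {self.schedule_path}")


def load_run_config(path, outdir) -> RunConfig:
    """Read a YAML run config (see the repo schema docs for keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mode = raw.get("mode", "synthetic")
    population = config_from_yaml(path) if mode == "synthetic" else None
    scenarios = None
    if "scenarios" in raw:
        scenarios = [
            ScenarioSpec(
                name=s["name"],
                depletion_factor=float(s.get("depletion_factor", 1.0)),
                biofort_factor=float(s.get("biofort_factor", 1.0)),
                target_wholegrain_share=s.get("target_wholegrain_share"),
                target_brown_share=s.get("target_brown_share"),
            )
            for s in raw["scenarios"]
        ]
    return RunConfig(
        mode=mode,
        outdir=Path(outdir),
        population=population,
        individuals_path=raw.get("individuals_path"),
        diaries_path=raw.get("diaries_path"),
        composition_path=raw.get("composition_path"),
        schedule_path=raw.get("schedule_path"),
        scenarios=scenarios,
        z_value=float(raw.get("z_value", 1.96)),
    )


def build_model(config: RunConfig) -> DietaryIronModel:
    config.validate()
    schedule = PriSchedule.from_csv(config.schedule_path) if config.schedule_path else None
    if config.mode == "synthetic":
        logger.info("generating synthetic survey (seed=%s)", config.population.seed)
        return DietaryIronModel.from_simulation(config.population, schedule=schedule)
    return DietaryIronModel.from_csv(
        config.individuals_path,
        config.diaries_path,
        config.composition_path,
        schedule_path=config.schedule_path,
    )


def _table1(results: DietaryIronResults) -> pd.DataFrame:
    summaries = results.group_summaries(
        ["total_g_day", "energy_kcal_day", "iron_mg_day"], include_overall=True
    )
    adequacy = results.adequacy()
    return summaries.merge(adequacy, on=["sex", "age_class"], how="left", suffixes=("", "_gap"))


def _table3(results: DietaryIronResults) -> pd.DataFrame:
    """Cereal intake and the wheat/rice percentage of it, per group.

    The headline percentage is the ratio of group mean grain grams to group
    mean cereal grams (ratio of means); the mean of per-individual ratios
    is emitted alongside for comparison.
    """
    rows = []
    for (sex, age_class), frame in results.intakes.groupby(["sex", "age_class"], sort=False):
        cereal = frame["cereal_g_day"]
        consumers = cereal > 0
        rows.append(
            {
                "sex": sex,
                "age_class": age_class,
                "n": len(frame),
                "cereal_g_day_mean": cereal.mean(),
                "wheat_pct_of_cereal": 100.0 * frame["wheat_g_day"].mean() / cereal.mean(),
                "rice_pct_of_cereal": 100.0 * frame["rice_g_day"].mean() / cereal.mean(),
                "wheat_pct_of_cereal_mean_of_ratios": 100.0
                * (frame.loc[consumers, "wheat_g_day"] / cereal[consumers]).mean(),
                "rice_pct_of_cereal_mean_of_ratios": 100.0
                * (frame.loc[consumers, "rice_g_day"] / cereal[consumers]).mean(),
            }
        )
    return pd.DataFrame(rows)


def _group_comparisons(results: DietaryIronResults) -> pd.DataFrame:
    rows = []
    for grain, variables in GRAIN_VARIABLES.items():
        for variable in variables:
            comparisons = []
            for label, compare in (
                ("age_classes", results.compare_age_groups),
                ("sexes", results.compare_sexes),
            ):
                try:
                    comparisons.append((label, compare(variable)))
                except ValueError:
                    logger.info("skipping %s comparison of %s: <2 groups", label, variable)
            for label, test in comparisons:
                rows.append(
                    {
                        "grain": grain,
                        "variable": variable,
                        "comparison": label,
                        "h": test.h_statistic,
                        "df": test.df,
                        "p_value": test.p_value,
                        "tie_correction": test.tie_correction,
                    }
                )
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    def canonical(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            obj = dataclasses.asdict(obj)
        if isinstance(obj, dict):
            return {str(k): canonical(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [canonical(v) for v in obj]
        if isinstance(obj, (str, int, float, bool)) or obj is None:
            return obj
        return str(obj)

    fields = {k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"}
    payload = json.dumps(canonical(fields), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``config.outdir``.

    Returns the manifest dict.  Identical config and seed produce
    byte-identical CSV outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_model(config)
    results = model.fit()
    logger.info("fitted intakes for %d individuals", len(results.intakes))

    specs = config.scenarios if config.scenarios is not None else default_scenarios()
    projection = results.project(specs, z=config.z_value)

    outputs = {
        "table1_intake_adequacy.csv": _table1(results),
        "table2_wheat.csv": results.group_summaries(GRAIN_VARIABLES["wheat"]),
        "table2_rice.csv": results.group_summaries(GRAIN_VARIABLES["rice"]),
        "table3_cereal_contribution.csv": _table3(results),
        "table4_scenario_significance.csv": projection.delta_table("s4"),
        "scenario_results.csv": projection.results,
        "figure_adequacy_series.csv": projection.series,
        "group_comparisons.csv": _group_comparisons(results),
        "intakes_individual.csv": results.intakes,
    }
    if config.mode == "synthetic":
        outputs["individuals.csv"] = model.individuals
        outputs["diaries.csv"] = model.diaries
        outputs["composition.csv"] = model.composition
    for name, frame in outputs.items():
        frame.to_csv(outdir / name, index=False)
        logger.info("wrote %s (%d rows)", name, len(frame))

    manifest = {
        "package": "ferrodiet",
        "version": __version__,
        "mode": config.mode,
        "seed": config.population.seed if config.population else None,
        "config_sha256": _config_hash(config),
        "n_individuals": int(len(results.intakes)),
        "n_diary_records": int(len(model.diaries)),
        "scenarios": [s.name for s in specs],
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
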