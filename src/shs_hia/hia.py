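"""Model/Results front end for the dynamic health impact assessment.

:class:`HIAModel` bundles the four input tables (population pyramid,
disease inputs, SHS exposure prevalence, relative risks) with a simulation
configuration; :meth:`HIAModel.run` executes every configured scenario and
returns an :class:`HIAResults` carrying the full result grid together with
aggregation, summary and plotting helpers.

Example
-------
>>> from shs_hia import HIAModel, synthetic_data
>>> fixture = synthetic_data.generate_full_study_fixture(seed=7)
>>> model = HIAModel(fixture.population, fixture.disease_inputs,
...                  fixture.exposure, fixture.rr, fixture.config)
>>> res = model.run()
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import scenario_reporting as rep
from .epi_core import build_exposure_specific_rates
from .model_io import (DiseaseInputSet, ExposureGroupTable, PopulationPyramid,
                       RelativeRiskTable, RunInputs, SimulationConfig,
                       load_config)
from .riskfactor_dynamics import build_schedule

__all__ = ["HIAModel", "HIAResults"]


class HIAModel:
    """Dynamic multistate model of SHS-attributable chronic-disease burden.

    Parameters
    ----------
    population
        Baseline pyramid with all-cause mortality and newborn inflow.
    disease_inputs
        Population-level prevalence, incidence and excess mortality per
        sex, single-year age and disease.
    exposure
        SHS exposure prevalence by sex and age group.
    rr
        Relative risk of each disease given exposure, per sex.
    config
        Horizon, scenario list, engine mode, sample size and seed.
    """

    def __init__(self, population: PopulationPyramid,
                 disease_inputs: DiseaseInputSet,
                 exposure: ExposureGroupTable,
                 rr: RelativeRiskTable,
                 config: SimulationConfig | None = None):
        self.population = population
        self.disease_inputs = disease_inputs
        self.exposure = exposure
        self.rr = rr
        self.config = config or SimulationConfig()
        self.schedule = build_schedule(exposure)
        self.rates = build_exposure_specific_rates(
            disease_inputs, self.schedule.p_exposed, rr)

    @classmethod
    def from_config(cls, path: str | Path) -> "HIAModel":
        """Build a model from a YAML run-configuration file."""
        inputs = load_config(path)
        return cls.from_inputs(inputs)

    @classmethod
    def from_inputs(cls, inputs: RunInputs) -> "HIAModel":
        return cls(inputs.population, inputs.disease_inputs, inputs.exposure,
                   inputs.rr, inputs.config)

    def run(self, *, seed: int | None = None,
            engine_mode: str | None = None) -> "HIAResults":
        """Execute all scenarios; optional seed / engine-mode overrides."""
        config = self.config
        if seed is not None or engine_mode is not None:
            config = dataclasses.replace(
                config,
                rng_seed=config.rng_seed if seed is None else seed,
                engine_mode=engine_mode or config.engine_mode)
        frame = rep.run_hia(self.population, self.disease_inputs,
                            self.exposure, self.rr, config)
        return HIAResults(self, config, frame)


class HIAResults:
    """Scenario projections produced by :meth:`HIAModel.run`.

    ``frame`` is the long result grid (year, scenario, sex, age, disease)
    with total, counterfactual and attributable prevalent cases, the
    population denominator and the attributable population prevalence in
    percent.
    """

    def __init__(self, model: HIAModel, config: SimulationConfig,
                 frame: pd.DataFrame):
        self.model = model
        self.config = config
        self.frame = frame

    # -- aggregation ------------------------------------------------------
    def aggregate(self, **kwargs) -> tuple[float, float]:
        """(cases, prevalence_pct) summed over the requested strata."""
        return rep.aggregate(self.frame, **kwargs)

    def percent_change(self, *, scenario: str, disease, year0: int,
                       year1: int, **kwargs) -> float:
        """Percent change in attributable cases between two years."""
        c0, _ = self.aggregate(scenario=scenario, disease=disease,
                               year=year0, **kwargs)
        c1, _ = self.aggregate(scenario=scenario, disease=disease,
                               year=year1, **kwargs)
        return rep.percent_change(c0, c1)

    def scenario_reduction(self, *, scenario: str, year: int,
                           reference: str = "reference", **kwargs) -> float:
        """Percent reduction of a scenario vs the reference in one year."""
        ref, _ = self.aggregate(scenario=reference, year=year, **kwargs)
        scen, _ = self.aggregate(scenario=scenario, year=year, **kwargs)
        return rep.scenario_reduction(ref, scen)

    def report_tables(self) -> dict[str, pd.DataFrame]:
        return rep.build_report_tables(self.frame)

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        """Report-style text table of attributable burden per scenario.

        Shows, for the first and last simulated year, attributable case
        counts and attributable population prevalence (percent of the
        same-sex population) per disease and sex.
        """
        tables = self.report_tables()["summary"]
        years = [self.config.start_year, self.config.end_year]
        sel = tables[tables["year"].isin(years)].copy()
        for col in sel.columns:
            if col.endswith("_n"):
                sel[col] = sel[col].round(0).astype("int64")
        lines = [
            "Dynamic HIA of second-hand smoke exposure",
            f"horizon {self.config.start_year}-{self.config.end_year}, "
            f"engine={self.config.engine_mode}, "
            f"n_individuals={self.config.n_individuals}, "
            f"seed={self.config.rng_seed}",
            "attributable prevalent cases (n) and attributable population "
            "prevalence (% of same-sex population):",
            sel.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        """Write results.csv plus the summary / by-age report tables."""
        return rep.write_report(self.frame, out_dir)

    def plot_age_profile(self, **kwargs):
        return rep.plot_age_profile(self.frame, **kwargs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        scen = [s.name for s in self.config.scenarios]
        return (f"<HIAResults scenarios={scen} "
                f"years={self.config.start_year}-{self.config.end_year} "
                f"rows={len(self.frame)}>")
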