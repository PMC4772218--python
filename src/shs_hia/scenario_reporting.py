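"""Scenario execution, attribution and summary reporting.

Attributable cases in year t are defined as the difference between the
scenario world and a counterfactual world in which nobody was ever exposed
(the engine run on the back-calculated unexposed rates with a zero exposure
schedule).  At the baseline year this reduces, stratum by stratum, to the
classical population attributable fraction p(RR-1)/(1+p(RR-1)).

The headline counts are prevalent cases (disease-state occupancy), reported
alongside the attributable population prevalence in percent.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .disease_engine import (background_mortality, run_engine,
                             zero_exposure_schedule)
from .epi_core import build_exposure_specific_rates
from .model_io import (AGES, DISEASES, DiseaseInputSet, DomainError,
                       ExposureGroupTable, PopulationPyramid,
                       RelativeRiskTable, SEXES, SimulationConfig,
                       write_results_csv)
from .riskfactor_dynamics import build_schedule

__all__ = ["run_hia", "aggregate", "percent_change", "scenario_reduction",
           "build_report_tables", "round_half_away", "plot_age_profile"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def run_hia(population: PopulationPyramid, disease_inputs: DiseaseInputSet,
            exposure: ExposureGroupTable, rr: RelativeRiskTable,
            config: SimulationConfig) -> pd.DataFrame:
    """Run every configured scenario plus the never-exposed counterfactual.

    Returns the long-format result grid with one row per
    (year, scenario, sex, age, disease) carrying total, counterfactual and
    attributable cases, the population denominator and the attributable
    population prevalence in percent.  The counterfactual world is shared
    by all scenarios and computed deterministically (it contains no
    randomness to sample).
    """
    schedule = build_schedule(exposure)
    rates = build_exposure_specific_rates(disease_inputs, schedule.p_exposed, rr)
    qb = background_mortality(population, disease_inputs)

    counterfactual = run_engine(config, zero_exposure_schedule(), rates,
                                population, background=qb,
                                mode="deterministic")
    frames = []
    pop = counterfactual.population  # identical across worlds
    pop_grid = np.broadcast_to(pop[..., None], counterfactual.cases.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        for scen in config.scenarios:
            # common random numbers across scenarios: every scenario replays
            # the same stream, so baseline draws coincide and scenario
            # contrasts are comonotonically coupled
            out = run_engine(config, schedule, rates, population,
                             scenario=scen, background=qb,
                             mode=config.engine_mode,
                             rng=np.random.default_rng(config.rng_seed))
            attributable = out.cases - counterfactual.cases
            prev_pct = np.where(pop_grid > 0,
                                100.0 * attributable / np.where(pop_grid > 0,
                                                                pop_grid, 1.0),
                                0.0)
            idx = pd.MultiIndex.from_product(
                [out.years, SEXES, AGES, DISEASES],
                names=["year", "sex", "age", "disease"])
            df = pd.DataFrame({
                "total_cases": out.cases.ravel(),
                "counterfactual_cases": counterfactual.cases.ravel(),
                "attributable_cases": attributable.ravel(),
                "population": pop_grid.ravel(),
                "population_prevalence_pct": prev_pct.ravel(),
            }, index=idx).reset_index()
            df.insert(1, "scenario", scen.name)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _select(result: pd.DataFrame, *, scenario=None, year=None, disease=None,
            sex=None, age_range=None) -> pd.DataFrame:
    sel = result
    if scenario is not None:
        sel = sel[sel["scenario"] == scenario]
    if year is not None:
        sel = sel[sel["year"] == year]
    if disease is not None:
        diseases = [disease] if isinstance(disease, str) else list(disease)
        sel = sel[sel["disease"].isin(diseases)]
    if sex is not None:
        sexes = [sex] if isinstance(sex, str) else list(sex)
        sel = sel[sel["sex"].isin(sexes)]
    if age_range is not None:
        lo, hi = age_range
        sel = sel[(sel["age"] >= lo) & (sel["age"] <= hi)]
    return sel


def aggregate(result: pd.DataFrame, *, scenario=None, year=None, disease=None,
              sex=None, age_range=None,
              value: str = "attributable_cases") -> tuple[float, float]:
    """Sum cases over the requested strata and their population prevalence.

    ``value`` selects the case column (attributable by default).  The
    prevalence denominator counts each (year, scenario, sex, age) stratum's
    population once even when several diseases are summed.  Raises on an
    empty selection.
    """
    sel = _select(result, scenario=scenario, year=year, disease=disease,
                  sex=sex, age_range=age_range)
    if sel.empty:
        raise DomainError("aggregate: selection matched no result cells")
    cases = float(sel[value].sum())
    pop = float(sel.drop_duplicates(["year", "scenario", "sex", "age"])
                ["population"].sum())
    prevalence_pct = 100.0 * cases / pop if pop > 0 else 0.0
    return cases, prevalence_pct


def percent_change(cases_t0: float, cases_t1: float) -> float:
    """Percent change between two case counts, one decimal, half away from 0."""
    if cases_t0 <= 0:
        raise DomainError("percent change undefined for a zero or negative base")
    return round_half_away(100.0 * (cases_t1 - cases_t0) / cases_t0, 1)


def scenario_reduction(reference_cases: float, scenario_cases: float) -> float:
    """Percent reduction of a scenario relative to the reference world."""
    if reference_cases <= 0:
        raise DomainError("reduction undefined for zero reference cases")
    return 100.0 * (1.0 - scenario_cases / reference_cases)


def build_report_tables(result: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary (wide, per scenario x year) and per-age tables for plotting.

    ``summary`` has one row per (scenario, year) with attributable case
    counts and attributable population prevalence (percent of the same-sex
    population) per disease and sex, percentages rounded to two decimals
    half away from zero; ``by_age`` is the long per-age grid feeding the
    count and prevalence curves.
    """
    rows = []
    for (scen, year), grp in result.groupby(["scenario", "year"], sort=True):
        row: dict[str, object] = {"scenario": scen, "year": year}
        for d in DISEASES:
            for s in SEXES:
                cases, pct = aggregate(grp, disease=d, sex=s)
                row[f"{d}_{s}_n"] = cases
                row[f"{d}_{s}_pct"] = round_half_away(pct, 2)
        rows.append(row)
    summary = pd.DataFrame(rows)
    by_age = result[["scenario", "year", "sex", "age", "disease",
                     "attributable_cases", "population",
                     "population_prevalence_pct"]].copy()
    return {"summary": summary, "by_age": by_age}


def write_report(result: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write the long results grid and both report tables as CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"results": out_dir / "results.csv"}
    write_results_csv(result, paths["results"])
    tables = build_report_tables(result)
    for name, df in tables.items():
        paths[name] = out_dir / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    return paths


def plot_age_profile(result: pd.DataFrame, *, year: int, disease: str,
                     scenario: str = "reference", kind: str = "cases", ax=None):
    """Per-age attributable burden curves by sex for one year and disease.

    ``kind`` selects absolute case counts or population prevalence (percent)
    on the y axis.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    column = {"cases": "attributable_cases",
              "prevalence": "population_prevalence_pct"}[kind]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for s in SEXES:
        sel = _select(result, scenario=scenario, year=year, disease=disease,
                      sex=s).sort_values("age")
        ax.plot(sel["age"], sel[column], label=s)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("attributable cases" if kind == "cases"
                  else "attributable population prevalence (%)")
    ax.set_title(f"{disease.upper()} attributable to SHS, {scenario}, {year}")
    ax.legend()
    return ax
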