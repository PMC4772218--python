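"""Internally consistent synthetic study inputs.

The national disease and population files behind the published projection
are not public, so every run and test works on a synthetic substitute that
reproduces the *structure* the analysis relies on:

* an ageing pyramid with Gompertz all-cause mortality, more elderly women
  than men, and a constant newborn inflow at sex ratio 1.05;
* chronic-disease prevalence rising logistically with age from a
  disease-specific onset age (no cases before the mid-30s), higher in men,
  with COPD declining again after a late-age peak;
* incidence back-solved so that propagating a cohort through the engine's
  one-year update reproduces the prevalence profile exactly (a stationary
  population), and excess mortality rising with age;
* the published exposure prevalences and relative risks as defaults.

Magnitudes are scaled to a configurable total population rather than the
~81 million inhabitants of Germany; only structure, not magnitude, is
needed for verification.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import germany
from .model_io import (AGES, DISEASES, DomainError, DiseaseInputSet,
                       ExposureGroupTable, N_AGES, PopulationPyramid,
                       RelativeRiskTable, Scenario, SEXES, SimulationConfig,
                       write_config)

__all__ = ["FixtureSpec", "DiseaseCurve", "StudyFixture",
           "generate_population", "generate_disease_inputs",
           "generate_full_study_fixture"]


@dataclasses.dataclass(frozen=True)
class DiseaseCurve:
    """Logistic-in-age prevalence curve with optional post-peak decline.

    ``prev(a) = level * sigmoid(steepness * (a - midpoint))`` for ages at or
    above ``onset_age`` (zero below), multiplied by
    ``exp(-decline * (a - peak_age))`` beyond ``peak_age`` when a decline
    is configured.  ``female_factor`` scales the whole curve for women.
    Excess mortality ramps linearly from ``excess_lo`` at onset to
    ``excess_hi`` at the top age.
    """

    onset_age: int
    level: float
    steepness: float
    midpoint: float
    female_factor: float
    excess_lo: float
    excess_hi: float
    peak_age: int | None = None
    decline: float = 0.0


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study population and disease inputs."""

    seed: int = 0
    total_population: float = 1_000_000.0
    # Gompertz all-cause mortality: hazard = base + coeff * exp(rate * age)
    mortality_coeff: tuple[float, float] = (4.0e-5, 2.2e-5)   # (male, female)
    mortality_rate: float = 0.095
    mortality_base: float = 2.0e-4
    count_jitter_sd: float = 0.02
    newborn_sex_ratio: float = 1.05
    curves: dict[str, DiseaseCurve] = dataclasses.field(default_factory=lambda: {
        "ihd": DiseaseCurve(onset_age=36, level=0.28, steepness=0.11,
                            midpoint=78.0, female_factor=0.55,
                            excess_lo=0.01, excess_hi=0.06),
        "copd": DiseaseCurve(onset_age=40, level=0.10, steepness=0.13,
                             midpoint=70.0, female_factor=0.65,
                             excess_lo=0.02, excess_hi=0.12,
                             peak_age=79, decline=0.025),
        "stroke": DiseaseCurve(onset_age=36, level=0.12, steepness=0.10,
                               midpoint=80.0, female_factor=0.85,
                               excess_lo=0.02, excess_hi=0.10),
    })

    def __post_init__(self) -> None:
        if self.total_population <= 0:
            raise DomainError("total_population must be > 0")
        for name, curve in self.curves.items():
            if curve.onset_age < 30:
                raise DomainError(f"{name}: onset age must be >= 30 so first "
                                  "cases appear in the mid-30s or later")
            if not (0.0 < curve.level <= 1.0):
                raise DomainError(f"{name}: prevalence level outside (0, 1]")


def _all_cause_mortality(spec: FixtureSpec) -> np.ndarray:
    coeff = np.asarray(spec.mortality_coeff)[:, None]
    hazard = spec.mortality_base + coeff * np.exp(spec.mortality_rate * AGES)
    return 1.0 - np.exp(-hazard)


def generate_population(spec: FixtureSpec) -> PopulationPyramid:
    """Quasi-stationary pyramid from the sex-specific survival curves.

    Counts are the survival curve of a constant birth inflow (sex ratio
    male:female from the spec), perturbed by a small seeded lognormal
    jitter and normalised to ``total_population``.  Lower female mortality
    produces the female surplus at the oldest ages.  Deterministic under
    the seed.
    """
    rng = np.random.default_rng(spec.seed)
    q = _all_cause_mortality(spec)
    survival = np.cumprod(np.hstack([np.ones((2, 1)), 1.0 - q[:, :-1]]), axis=1)
    r = spec.newborn_sex_ratio
    births = np.array([r / (1.0 + r), 1.0 / (1.0 + r)])[:, None]
    counts = births * survival
    counts = counts * np.exp(rng.normal(0.0, spec.count_jitter_sd, counts.shape))
    counts = counts / counts.sum() * spec.total_population
    return PopulationPyramid(
        counts=counts, all_cause_mortality=q,
        newborns_per_year=float(counts[:, 0].sum()),
        newborn_sex_ratio=spec.newborn_sex_ratio)


def _prevalence_curve(curve: DiseaseCurve, factor: float) -> np.ndarray:
    prev = factor * curve.level / (1.0 + np.exp(-curve.steepness
                                                * (AGES - curve.midpoint)))
    if curve.peak_age is not None:
        prev = prev * np.exp(-curve.decline
                             * np.maximum(0, AGES - curve.peak_age))
    prev[AGES < curve.onset_age] = 0.0
    return prev


def _excess_curve(curve: DiseaseCurve) -> np.ndarray:
    span = max(1, (N_AGES - 1) - curve.onset_age)
    ramp = np.clip((AGES - curve.onset_age) / span, 0.0, 1.0)
    qx = curve.excess_lo + (curve.excess_hi - curve.excess_lo) * ramp
    qx[AGES < curve.onset_age] = 0.0
    return qx


def _stationary_incidence(prev: np.ndarray, qx: np.ndarray) -> np.ndarray:
    """Back-solve the annual incidence that keeps the profile stationary.

    Inverts the engine's one-year prevalence update: a cohort with
    prevalence ``prev[a]`` that lives the year at age a under excess
    mortality ``qx[a]`` and incidence ``inc[a]`` must arrive at
    ``prev[a+1]``.  Background mortality cancels in the update and plays
    no role.  Raises if the requested profile would need negative
    incidence (decline steeper than excess mortality can explain).
    """
    # i[a] is the incidence experienced while living the year at age a;
    # the top bucket gets the rate that keeps its own prevalence stationary
    p0 = prev
    p1 = np.append(prev[1:], prev[-1])
    surv_sick = p0 * (1.0 - qx)
    with np.errstate(invalid="ignore", divide="ignore"):
        i = np.where(p0 < 1.0,
                     (p1 * (surv_sick + 1.0 - p0) - surv_sick)
                     / np.where(p0 < 1.0, 1.0 - p0, 1.0),
                     0.0)
    i[np.abs(i) < 1e-15] = 0.0
    if np.any(i < 0.0):
        age = int(np.nonzero(i < 0.0)[0][0])
        raise DomainError(
            f"prevalence decline after age {age} is steeper than the excess "
            "mortality can produce; raise excess_hi or soften the decline")
    if np.any(i > 1.0):
        raise DomainError("back-solved incidence exceeds 1; flatten the "
                          "prevalence curve")
    return i


def generate_disease_inputs(spec: FixtureSpec) -> DiseaseInputSet:
    """Prevalence, stationary incidence and excess mortality per stratum.

    Male prevalence dominates female prevalence at every age by
    construction (``female_factor <= 1``); propagating the returned
    incidence through the engine's update reproduces the returned
    prevalence exactly.
    """
    prevalence = np.zeros((len(SEXES), N_AGES, len(DISEASES)))
    incidence = np.zeros_like(prevalence)
    excess = np.zeros_like(prevalence)
    for d, disease in enumerate(DISEASES):
        curve = spec.curves[disease]
        qx = _excess_curve(curve)
        for s, sex in enumerate(SEXES):
            factor = 1.0 if sex == "male" else curve.female_factor
            prev = _prevalence_curve(curve, factor)
            prevalence[s, :, d] = prev
            incidence[s, :, d] = _stationary_incidence(prev, qx)
            excess[s, :, d] = qx
    return DiseaseInputSet(prevalence=prevalence, incidence=incidence,
                           excess_mortality=excess)


@dataclasses.dataclass(frozen=True)
class StudyFixture:
    """A complete, ready-to-run set of study inputs."""

    spec: FixtureSpec
    population: PopulationPyramid
    disease_inputs: DiseaseInputSet
    exposure: ExposureGroupTable
    rr: RelativeRiskTable
    config: SimulationConfig


def default_scenarios(start_year: int = 2014) -> tuple[Scenario, ...]:
    return (Scenario("reference", 0.0, start_year),
            Scenario("success_20", 0.2, start_year),
            Scenario("success_100", 1.0, start_year))


def generate_full_study_fixture(seed: int = 0, *,
                                out_dir: str | Path | None = None,
                                spec: FixtureSpec | None = None,
                                config: SimulationConfig | None = None
                                ) -> StudyFixture:
    """Generate the full study setup; optionally write it as CSVs + config.

    Defaults follow the study design: 2014-2040 horizon, 10,000 simulated
    individuals, the published exposure and relative-risk tables, and the
    reference / 20%-success / 100%-success scenario triple.
    """
    spec = spec or FixtureSpec(seed=seed)
    if spec.seed != seed:
        spec = dataclasses.replace(spec, seed=seed)
    config = config or SimulationConfig(
        start_year=2014, end_year=2040, n_individuals=10_000, rng_seed=seed,
        scenarios=default_scenarios(2014), engine_mode="micro")
    fixture = StudyFixture(
        spec=spec,
        population=generate_population(spec),
        disease_inputs=generate_disease_inputs(spec),
        exposure=germany.exposure_group_table(),
        rr=germany.relative_risk_table(),
        config=config,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fixture.population.to_csv(out / "population.csv")
        fixture.disease_inputs.to_csv(out / "disease_inputs.csv")
        fixture.exposure.to_csv(out / "exposure.csv")
        fixture.rr.to_csv(out / "rr.csv")
        write_config(out / "config.yaml", {
            "population": "population.csv",
            "disease_inputs": "disease_inputs.csv",
            "exposure": "exposure.csv",
            "rr": "rr.csv",
            "start_year": config.start_year,
            "end_year": config.end_year,
            "n_individuals": config.n_individuals,
            "seed": config.rng_seed,
            "engine_mode": config.engine_mode,
            "newborns_per_year": fixture.population.newborns_per_year,
            "newborn_sex_ratio": fixture.population.newborn_sex_ratio,
            "scenarios": [
                {"name": s.name, "success_rate": s.success_rate,
                 "start_year": s.start_year} for s in config.scenarios],
            "output_dir": "results",
        })
    return fixture
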