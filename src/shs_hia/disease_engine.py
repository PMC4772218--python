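"""Disease occupancy, mortality and demographic ageing.

The engine is a "partial micro-simulation": exposure states are hard,
individually sampled labels (see :mod:`shs_hia.riskfactor_dynamics`), while
disease occupancy is carried as probabilities — each simulated individual
holds, per disease, a pair of person-masses (healthy, diseased) conditional
on their exposure path.  Diseases are chronic (no remission), mutually
conditionally independent given age, sex and the exposure history, and kill
through an excess annual risk on top of background (other-cause) mortality.

Two engine modes produce the same expectations:

``deterministic``
    propagates, per (sex, cohort, disease), the exact joint distribution
    over {unexposed, exposed} x {healthy, diseased} as a 4-state Markov
    chain.  Because per-individual disease masses evolve linearly given the
    exposure path, this equals the expectation of the micro mode cell for
    cell; it serves as the noise-free oracle.

``micro``
    samples exposure paths for a weighted sample of individuals and
    averages their disease masses — the approach of the original tool.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .epi_core import ExposureSpecificRates
from .model_io import (DISEASES, DomainError, DiseaseInputSet, MAX_AGE, N_AGES,
                       PopulationPyramid, Scenario, SEXES, SimulationConfig)
from .riskfactor_dynamics import ExposureSchedule, apply_scenario

__all__ = ["update_disease_probability", "joint_distribution",
           "advance_population", "project_population", "background_mortality",
           "zero_exposure_schedule", "run_engine", "EngineOutput",
           "IndividualState"]

# state indices of the per-disease exposure x disease chain
_UH, _US, _EH, _ES = 0, 1, 2, 3


@dataclasses.dataclass
class IndividualState:
    """Probabilistic state of one simulated individual.

    ``disease_prob`` maps each of the three diseases to the probability of
    being a prevalent case conditional on being alive; ``alive_prob`` is
    the survival mass given the individual's exposure history.
    """

    age: int
    sex: str
    exposed: bool
    disease_prob: dict[str, float]
    alive_prob: float

    def __post_init__(self) -> None:
        if set(self.disease_prob) != set(DISEASES):
            raise DomainError(f"disease_prob must cover exactly {DISEASES}")
        probs = list(self.disease_prob.values()) + [self.alive_prob]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise DomainError("probabilities must lie in [0, 1]")


def update_disease_probability(prob, incidence_for_state, excess_mortality,
                               all_cause_mortality):
    """One-year update of a chronic-disease occupancy probability.

    Prevalent cases survive the year with probability
    ``(1 - all_cause)(1 - excess)``; the disease-free survive with
    ``(1 - all_cause)`` and then become incident cases with probability
    ``incidence_for_state`` (chosen upstream from the exposed or unexposed
    back-calculated rate).  The result is the diseased share of survivors;
    the all-cause term cancels in this ratio but is kept in the signature
    because the unnormalised masses feed the case counts.  Accepts scalars
    or arrays.
    """
    p = np.asarray(prob, dtype=float)
    i = np.asarray(incidence_for_state, dtype=float)
    qx = np.asarray(excess_mortality, dtype=float)
    q = np.asarray(all_cause_mortality, dtype=float)
    for name, arr in (("prob", p), ("incidence", i),
                      ("excess_mortality", qx), ("all_cause_mortality", q)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise DomainError(f"{name} must be an annual probability in [0, 1]")
    sick = p * (1.0 - q) * (1.0 - qx)
    healthy = (1.0 - p) * (1.0 - q)
    denom = sick + healthy
    out = np.where(denom > 0.0, (sick + healthy * i) / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any(out < -1e-15) or np.any(out > 1.0 + 1e-15):
        raise DomainError("updated disease probability left [0, 1]")
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def joint_distribution(marginals) -> np.ndarray:
    """Product-form joint over the 2**3 disease-state combinations.

    ``marginals`` holds the three per-disease probabilities in the order of
    :data:`~shs_hia.model_io.DISEASES` (trailing axis).  Cell ``c`` of the
    returned trailing axis of length 8 is the combination in which disease
    ``d`` is present iff bit ``d`` of ``c`` is set (IHD is the least
    significant bit).  Cells are non-negative, sum to 1, and marginalise
    back to the inputs.
    """
    m = np.asarray(marginals, dtype=float)
    if m.shape[-1] != len(DISEASES):
        raise DomainError(f"need {len(DISEASES)} marginals, got shape {m.shape}")
    if np.any(m < 0) or np.any(m > 1):
        raise DomainError("marginal probabilities must lie in [0, 1]")
    out = np.ones(m.shape[:-1] + (8,))
    for d in range(len(DISEASES)):
        present = (np.arange(8) >> d) & 1
        out = out * np.where(present, m[..., d:d + 1], 1.0 - m[..., d:d + 1])
    return out


def advance_population(pyramid: PopulationPyramid) -> PopulationPyramid:
    """Age the pyramid by one year: survival, top-bucket accumulation, births.

    Each cohort is scaled by ``1 - all_cause_mortality`` and shifted up one
    age; survivors from 94 and from the open-ended 95 bucket accumulate at
    95; newborns enter age 0 split male:female by the sex ratio.  No
    migration.
    """
    surv = pyramid.counts * (1.0 - pyramid.all_cause_mortality)
    new = np.zeros_like(pyramid.counts)
    new[:, 1:] = surv[:, :-1]
    new[:, MAX_AGE] += surv[:, MAX_AGE]
    new[:, 0] = pyramid.newborns_by_sex
    return dataclasses.replace(pyramid, counts=new)


def project_population(pyramid: PopulationPyramid, n_years: int) -> np.ndarray:
    """Counts for n_years consecutive years, shape (n_years, n_sexes, n_ages)."""
    out = np.empty((n_years, len(SEXES), N_AGES))
    current = pyramid
    for t in range(n_years):
        out[t] = current.counts
        if t + 1 < n_years:
            current = advance_population(current)
    return out


def background_mortality(pyramid: PopulationPyramid,
                         inputs: DiseaseInputSet) -> np.ndarray:
    """Other-cause mortality: all-cause minus the prevalence-weighted excess.

    The all-cause input already contains the deaths of prevalent cases, so
    the engine must not charge the excess risks twice; the remainder
    ``q_all - sum_d prev_d * excess_d`` (clamped at 0) is what healthy
    individuals face.  Shape (n_sexes, n_ages).
    """
    attributable = (inputs.prevalence * inputs.excess_mortality).sum(axis=2)
    return np.clip(pyramid.all_cause_mortality - attributable, 0.0, 1.0)


def zero_exposure_schedule() -> ExposureSchedule:
    """A schedule in which nobody is ever exposed (counterfactual world)."""
    z = np.zeros((len(SEXES), N_AGES))
    return ExposureSchedule(p_exposed=z, transition_in=z.copy(),
                            transition_out=z.copy())


@dataclasses.dataclass(frozen=True)
class EngineOutput:
    """Expected case counts and population denominators per simulated year."""

    years: np.ndarray                 # (n_years,)
    cases: np.ndarray                 # persons, (n_years, n_sexes, n_ages, n_diseases)
    population: np.ndarray            # persons, (n_years, n_sexes, n_ages)


def _exposure_flip(masses: np.ndarray, success_rate: float) -> None:
    """Move the scenario fraction of exposed mass to unexposed, in place."""
    moved_h = success_rate * masses[..., _EH]
    moved_s = success_rate * masses[..., _ES]
    masses[..., _UH] += moved_h
    masses[..., _US] += moved_s
    masses[..., _EH] -= moved_h
    masses[..., _ES] -= moved_s


def _disease_step(masses: np.ndarray, qb: np.ndarray, rates: ExposureSpecificRates
                  ) -> None:
    """One-year incidence / mortality update on (sex, age, disease, 4) masses."""
    qb3 = qb[:, :, None]
    qx = rates.excess_mortality
    i_u = rates.incidence_unexposed
    i_e = rates.incidence_exposed
    uh, us = masses[..., _UH], masses[..., _US]
    eh, es = masses[..., _EH], masses[..., _ES]
    masses[..., _US] = us * (1.0 - qb3) * (1.0 - qx) + uh * (1.0 - qb3) * i_u
    masses[..., _UH] = uh * (1.0 - qb3) * (1.0 - i_u)
    masses[..., _ES] = es * (1.0 - qb3) * (1.0 - qx) + eh * (1.0 - qb3) * i_e
    masses[..., _EH] = eh * (1.0 - qb3) * (1.0 - i_e)


def run_engine(config: SimulationConfig, schedule: ExposureSchedule,
               rates: ExposureSpecificRates, pyramid: PopulationPyramid, *,
               scenario: Scenario | None = None,
               background: np.ndarray | None = None,
               mode: str | None = None,
               rng: np.random.Generator | None = None) -> EngineOutput:
    """Run the dynamic model over the configured horizon for one scenario.

    ``schedule`` is the pre-intervention (reference) exposure regime;
    ``scenario``, if given, scales the exposure targets by its success rate
    from its start year on, moving the required share of exposed
    individuals to the unexposed state at that instant.  ``background`` is
    the other-cause mortality grid (defaults to
    :func:`background_mortality` reconstructed from the rates and
    schedule).  ``mode`` overrides ``config.engine_mode``.
    """
    mode = mode or config.engine_mode
    if mode not in ("micro", "deterministic"):
        raise DomainError(f"unknown engine mode {mode!r}")
    shape = (len(SEXES), N_AGES, len(DISEASES))
    for name in ("prevalence_unexposed", "prevalence_exposed",
                 "incidence_unexposed", "incidence_exposed", "excess_mortality"):
        if getattr(rates, name).shape != shape:
            raise DomainError(f"rates.{name} not on the (sex, age, disease) grid "
                              f"{shape}")
    if background is None:
        p = schedule.p_exposed[:, :, None]
        prev_pop = (1.0 - p) * rates.prevalence_unexposed + p * rates.prevalence_exposed
        attributable = (prev_pop * rates.excess_mortality).sum(axis=2)
        background = np.clip(pyramid.all_cause_mortality - attributable, 0.0, 1.0)

    population = project_population(pyramid, config.n_years)
    scen = scenario or Scenario("reference", 0.0, config.start_year)
    post = apply_scenario(schedule, scen) if scen.success_rate > 0 else schedule

    def active(year: int) -> ExposureSchedule:
        return post if year >= scen.start_year else schedule

    if mode == "deterministic":
        cases = _run_deterministic(config, schedule, post, scen, active, rates,
                                   pyramid, background)
    else:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        cases = _run_micro(config, schedule, post, scen, active, rates,
                           pyramid, background, rng)
    return EngineOutput(years=config.years, cases=cases, population=population)


def _initial_masses(schedule: ExposureSchedule, rates: ExposureSpecificRates,
                    counts: np.ndarray) -> np.ndarray:
    """Baseline-year masses: exposure from the reference profile, disease
    occupancy from the back-calculated stratum prevalences."""
    p = schedule.p_exposed[:, :, None]
    n = counts[:, :, None]
    masses = np.empty((len(SEXES), N_AGES, len(DISEASES), 4))
    masses[..., _UH] = n * (1.0 - p) * (1.0 - rates.prevalence_unexposed)
    masses[..., _US] = n * (1.0 - p) * rates.prevalence_unexposed
    masses[..., _EH] = n * p * (1.0 - rates.prevalence_exposed)
    masses[..., _ES] = n * p * rates.prevalence_exposed
    return masses


def _run_deterministic(config, schedule, post, scen, active, rates, pyramid,
                       background) -> np.ndarray:
    cases = np.empty((config.n_years, len(SEXES), N_AGES, len(DISEASES)))
    masses = _initial_masses(schedule, rates, pyramid.counts)
    if scen.start_year == config.start_year:
        _exposure_flip(masses, scen.success_rate)
    cases[0] = masses[..., _US] + masses[..., _ES]
    newborns = pyramid.newborns_by_sex
    for t in range(1, config.n_years):
        year = config.start_year + t
        # incidence and mortality experienced during the year just lived,
        # at the source age and under the pre-transition exposure state —
        # the same convention advance_population uses for survival
        _disease_step(masses, background, rates)
        sched = active(year - 1)   # regime governing the year being left
        t_in = sched.transition_in[:, :, None]
        t_out = sched.transition_out[:, :, None]
        uh, us = masses[..., _UH].copy(), masses[..., _US].copy()
        eh, es = masses[..., _EH].copy(), masses[..., _ES].copy()
        masses[..., _UH] = uh * (1.0 - t_in) + eh * t_out
        masses[..., _EH] = eh * (1.0 - t_out) + uh * t_in
        masses[..., _US] = us * (1.0 - t_in) + es * t_out
        masses[..., _ES] = es * (1.0 - t_out) + us * t_in
        # ageing with top-bucket accumulation, newborn inflow at age 0
        shifted = np.zeros_like(masses)
        shifted[:, 1:] = masses[:, :-1]
        shifted[:, MAX_AGE] += masses[:, MAX_AGE]
        p0 = active(year).p_exposed[:, 0]
        shifted[:, 0, :, _UH] = (newborns * (1.0 - p0))[:, None]
        shifted[:, 0, :, _EH] = (newborns * p0)[:, None]
        masses = shifted
        if year == scen.start_year:
            _exposure_flip(masses, scen.success_rate)
        cases[t] = masses[..., _US] + masses[..., _ES]
    return cases


def _run_micro(config, schedule, post, scen, active, rates, pyramid,
               background, rng) -> np.ndarray:
    n_sexes, n_dis = len(SEXES), len(DISEASES)
    # n_individuals is the target total across populated baseline cohorts;
    # each populated (sex, age) cell gets an equal share of m individuals,
    # weighted by cohort size / m.  Empty cells are not simulated.
    populated = np.argwhere(pyramid.counts > 0)
    m = max(1, round(config.n_individuals / max(1, len(populated))))
    nb = pyramid.newborns_by_sex
    cohorts: list[tuple[int, int, int, float]] = [
        (int(i), int(a), 0, pyramid.counts[i, a] / m) for i, a in populated]
    for t in range(1, config.n_years):
        cohorts.extend((i, 0, t, nb[i] / m)
                       for i in range(n_sexes) if nb[i] > 0)
    if not cohorts:
        return np.zeros((config.n_years, n_sexes, N_AGES, n_dis))
    sex_idx = np.repeat([c[0] for c in cohorts], m)
    age = np.repeat([c[1] for c in cohorts], m)
    entry = np.repeat([c[2] for c in cohorts], m)
    weight = np.repeat([c[3] for c in cohorts], m)
    total = len(sex_idx)

    exposed = np.zeros(total, dtype=bool)
    healthy = np.ones((total, n_dis))
    sick = np.zeros((total, n_dis))

    baseline = entry == 0
    p_init = schedule.p_exposed[sex_idx, age]
    exposed[baseline] = rng.random(baseline.sum()) < p_init[baseline]
    # disease occupancy reflects the historical (pre-intervention) state
    prev = np.where(exposed[:, None],
                    rates.prevalence_exposed[sex_idx, age],
                    rates.prevalence_unexposed[sex_idx, age])
    sick[baseline] = prev[baseline]
    healthy[baseline] = 1.0 - prev[baseline]
    if scen.start_year == config.start_year:
        # drawn for every scenario (incl. success 0) so that runs with the
        # same seed share a common random-number stream across scenarios
        flip = baseline & exposed & (rng.random(total) < scen.success_rate)
        exposed[flip] = False

    cases = np.zeros((config.n_years, n_sexes, N_AGES, n_dis))
    flat = sex_idx * N_AGES + age

    def record(t: int, live: np.ndarray) -> None:
        for d in range(n_dis):
            cases[t].reshape(-1, n_dis)[:, d] += np.bincount(
                flat[live], weights=(weight * sick[:, d])[live],
                minlength=n_sexes * N_AGES)

    record(0, baseline)
    for t in range(1, config.n_years):
        year = config.start_year + t
        live = entry <= t
        old = entry < t
        # disease masses absorb the year just lived: source-age rates and
        # the pre-transition exposure state (mirrors the deterministic mode)
        inc = np.where(exposed[:, None],
                       rates.incidence_exposed[sex_idx, age],
                       rates.incidence_unexposed[sex_idx, age])
        qx = rates.excess_mortality[sex_idx, age]
        qb = background[sex_idx, age][:, None]
        mask = old[:, None]
        new_sick = np.where(mask,
                            sick * (1.0 - qb) * (1.0 - qx)
                            + healthy * (1.0 - qb) * inc, sick)
        new_healthy = np.where(mask, healthy * (1.0 - qb) * (1.0 - inc), healthy)
        sick, healthy = new_sick, new_healthy
        sched = active(year - 1)
        u = rng.random(total)
        gain = old & ~exposed & (u < sched.transition_in[sex_idx, age])
        lose = old & exposed & (u < sched.transition_out[sex_idx, age])
        exposed = (exposed | gain) & ~lose
        age[old] = np.minimum(age[old] + 1, MAX_AGE)
        entering = entry == t
        if entering.any():
            p0 = active(year).p_exposed[sex_idx, 0]
            exposed[entering] = rng.random(entering.sum()) < p0[entering]
        if year == scen.start_year:
            flip = live & exposed & (rng.random(total) < scen.success_rate)
            exposed[flip] = False
        flat = sex_idx * N_AGES + age
        record(t, live)
    return cases
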