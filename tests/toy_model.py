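"""A tiny one-disease, one-cohort world with an independent oracle.

A single cohort of 10,000 men aged 60 is followed for three years under a
falling exposure profile (50% -> 40% -> 30%).  The oracle enumerates all
eight exposure paths explicitly with plain Python loops — it shares no
code with the engine — and returns the exact expected diseased mass per
year together with its per-individual variance (for Monte-Carlo error
bounds on the micro engine).
"""

import dataclasses
import itertools

import numpy as np

from shs_hia.epi_core import build_exposure_specific_rates
from shs_hia.model_io import (DISEASES, DiseaseInputSet, N_AGES,
                              PopulationPyramid, RelativeRiskTable,
                              SimulationConfig, SEXES)
from shs_hia.riskfactor_dynamics import ExposureSchedule, derive_net_transitions

COHORT_AGE = 60
COHORT_SIZE = 10_000.0
PREV, INC, EXCESS, ALL_CAUSE, RR = 0.2, 0.1, 0.05, 0.03, 1.8
P_BY_AGE = {60: 0.5, 61: 0.4, 62: 0.3}


@dataclasses.dataclass
class Toy:
    config: SimulationConfig
    schedule: ExposureSchedule
    rates: object
    pyramid: PopulationPyramid
    background: np.ndarray


def build_toy(n_individuals: int = 20_000) -> Toy:
    p = np.zeros((2, N_AGES))
    p[0, :61] = P_BY_AGE[60]
    p[0, 61] = P_BY_AGE[61]
    p[0, 62:] = P_BY_AGE[62]
    t_in = np.zeros_like(p)
    t_out = np.zeros_like(p)
    t_in[0], t_out[0] = derive_net_transitions(p[0])
    schedule = ExposureSchedule(p_exposed=p, transition_in=t_in,
                                transition_out=t_out)

    shape = (2, N_AGES, len(DISEASES))
    prev = np.zeros(shape)
    inc = np.zeros(shape)
    qx = np.zeros(shape)
    prev[..., 0], inc[..., 0], qx[..., 0] = PREV, INC, EXCESS
    inputs = DiseaseInputSet(prevalence=prev, incidence=inc,
                             excess_mortality=qx)
    rr = RelativeRiskTable({(s, d): (RR if d == "ihd" else 1.0)
                            for s in SEXES for d in DISEASES})
    rates = build_exposure_specific_rates(inputs, p, rr)

    counts = np.zeros((2, N_AGES))
    counts[0, COHORT_AGE] = COHORT_SIZE
    pyramid = PopulationPyramid(counts=counts,
                                all_cause_mortality=np.full((2, N_AGES), ALL_CAUSE),
                                newborns_per_year=0.0)
    background = np.full((2, N_AGES), ALL_CAUSE - PREV * EXCESS)
    config = SimulationConfig(start_year=2014, end_year=2016,
                              n_individuals=n_individuals, rng_seed=99)
    return Toy(config=config, schedule=schedule, rates=rates,
               pyramid=pyramid, background=background)


def enumerate_exposure_paths(toy: Toy):
    """Exact per-year E[diseased mass] and Var[diseased mass] per individual."""
    sched = toy.schedule
    qb = float(toy.background[0, 0])
    prev_u = toy.rates.prevalence_unexposed[0, COHORT_AGE, 0]
    prev_e = toy.rates.prevalence_exposed[0, COHORT_AGE, 0]
    n_years = toy.config.n_years
    moments = np.zeros((2, n_years))          # E[s], E[s^2]
    for path in itertools.product([0, 1], repeat=n_years):
        prob = P_BY_AGE[COHORT_AGE] if path[0] else 1.0 - P_BY_AGE[COHORT_AGE]
        sick = prev_e if path[0] else prev_u
        healthy = 1.0 - sick
        sick_by_year = [sick]
        for t in range(1, n_years):
            src = COHORT_AGE + t - 1
            if path[t - 1]:
                p_next = (1.0 - sched.transition_out[0, src] if path[t]
                          else sched.transition_out[0, src])
            else:
                p_next = (sched.transition_in[0, src] if path[t]
                          else 1.0 - sched.transition_in[0, src])
            prob *= p_next
            # the year just lived: source age, pre-transition state
            i = (toy.rates.incidence_exposed[0, src, 0] if path[t - 1]
                 else toy.rates.incidence_unexposed[0, src, 0])
            qx = toy.rates.excess_mortality[0, src, 0]
            sick, healthy = (sick * (1 - qb) * (1 - qx)
                             + healthy * (1 - qb) * i,
                             healthy * (1 - qb) * (1 - i))
            sick_by_year.append(sick)
        if prob == 0.0:
            continue
        for t, s in enumerate(sick_by_year):
            moments[0, t] += prob * s
            moments[1, t] += prob * s * s
    expected = moments[0]
    variance = moments[1] - expected ** 2
    return expected, variance
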