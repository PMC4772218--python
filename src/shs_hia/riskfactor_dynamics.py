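"""Exposure-state dynamics: the two-state risk-factor part of the model.

The risk factor is categorical with states {unexposed, exposed}.  A
cross-sectional age profile of exposure prevalence is expanded to single
years of age, converted into annual net transition probabilities that
reproduce the profile exactly when a cohort is propagated through it, and
optionally transformed by a policy scenario.  Individual exposure
histories are then sampled from those transitions (the "micro" half of the
partial micro-simulation); disease states never feed back into them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model_io import (DomainError, ExposureGroupTable, MAX_AGE, N_AGES,
                       Scenario, SEXES)

__all__ = ["ExposureSchedule", "expand_age_groups", "derive_net_transitions",
           "propagate_cohort", "build_schedule", "apply_scenario",
           "simulate_exposure_histories"]


@dataclasses.dataclass(frozen=True)
class ExposureSchedule:
    """Target exposure prevalence and the transitions that sustain it.

    ``p_exposed`` has shape (n_sexes, n_ages).  ``transition_in`` /
    ``transition_out`` give, indexed by the *source* age a, the annual
    probability of switching state while ageing from a to a+1; index 95
    (the self-looping top bucket) is always zero.
    """

    p_exposed: np.ndarray
    transition_in: np.ndarray
    transition_out: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p_exposed", "transition_in", "transition_out"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(SEXES), N_AGES):
                raise DomainError(f"{name} must have shape {(len(SEXES), N_AGES)}")
            if (arr < 0).any() or (arr > 1).any():
                raise DomainError(f"{name} must lie in [0, 1]")


def expand_age_groups(table: ExposureGroupTable) -> np.ndarray:
    """Expand grouped exposure prevalence to single years of age.

    Piecewise-constant within each printed group; ages below 18 carry zero
    exposure (no data exist for minors); the open-ended top group applies
    through age 95.  Returns shape (n_sexes, n_ages).
    """
    p = np.zeros((len(SEXES), N_AGES))
    for i, sex in enumerate(SEXES):
        for age in range(18, N_AGES):
            p[i, age] = table.fraction(sex, age)
    return p


def derive_net_transitions(p_by_age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Annual one-sided net transitions reproducing a 1-D age profile.

    For each source age a: a falling profile requires only outflow,
    ``out = (p(a) - p(a+1)) / p(a)``; a rising one only inflow,
    ``in = (p(a+1) - p(a)) / (1 - p(a))``.  Deterministic forward
    propagation of a cohort through these probabilities reproduces the
    profile exactly.
    """
    p = np.asarray(p_by_age, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise DomainError("exposure prevalence must lie in [0, 1]")
    t_in = np.zeros_like(p)
    t_out = np.zeros_like(p)
    dp = np.diff(p)
    falling = dp < 0
    if np.any(falling & (p[:-1] <= 0)):
        raise DomainError("profile falls from an age with zero exposed fraction; "
                          "no outflow can produce it")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_out[:-1] = np.where(falling, -dp / np.where(p[:-1] > 0, p[:-1], 1.0), 0.0)
        t_in[:-1] = np.where(dp > 0, dp / (1.0 - p[:-1]), 0.0)
    return t_in, t_out


def propagate_cohort(p0: float, t_in: np.ndarray, t_out: np.ndarray) -> np.ndarray:
    """Expected exposed fraction of a cohort propagated from age 0."""
    out = np.empty(len(t_in))
    x = float(p0)
    out[0] = x
    for a in range(len(t_in) - 1):
        x = x * (1.0 - t_out[a]) + (1.0 - x) * t_in[a]
        out[a + 1] = x
    return out


def build_schedule(table: ExposureGroupTable) -> ExposureSchedule:
    """Expand an age-group table and derive the sustaining transitions."""
    p = expand_age_groups(table)
    t_in = np.zeros_like(p)
    t_out = np.zeros_like(p)
    for i in range(len(SEXES)):
        t_in[i], t_out[i] = derive_net_transitions(p[i])
    return ExposureSchedule(p_exposed=p, transition_in=t_in, transition_out=t_out)


def apply_scenario(schedule: ExposureSchedule, scenario: Scenario) -> ExposureSchedule:
    """Scale the target profile by (1 - success_rate) and re-derive transitions.

    The returned schedule describes the post-intervention regime; the
    engine switches to it at ``scenario.start_year``, moving the required
    fraction of currently exposed individuals to unexposed so the new
    target holds immediately.  success_rate 0 is the identity, 1 zeroes
    exposure.
    """
    p = schedule.p_exposed * (1.0 - scenario.success_rate)
    t_in = np.zeros_like(p)
    t_out = np.zeros_like(p)
    for i in range(len(SEXES)):
        t_in[i], t_out[i] = derive_net_transitions(p[i])
    return ExposureSchedule(p_exposed=p, transition_in=t_in, transition_out=t_out)


def simulate_exposure_histories(schedule: ExposureSchedule, sex: str,
                                entry_age: int, n_years: int, n: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Sample exposure histories for a cohort entering at ``entry_age``.

    Returns a boolean array of shape (n, n_years): True = exposed.  Initial
    states are Bernoulli draws from the target prevalence at the entry age;
    each subsequent year applies the transition probabilities of the source
    age (capped at the top bucket).  Histories are independent of disease.
    """
    i = SEXES.index(sex)
    hist = np.zeros((n, n_years), dtype=bool)
    age0 = min(int(entry_age), MAX_AGE)
    state = rng.random(n) < schedule.p_exposed[i, age0]
    hist[:, 0] = state
    for t in range(1, n_years):
        src = min(entry_age + t - 1, MAX_AGE)
        u = rng.random(n)
        gain = ~state & (u < schedule.transition_in[i, src])
        lose = state & (u < schedule.transition_out[i, src])
        state = (state | gain) & ~lose
        hist[:, t] = state
    return hist
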