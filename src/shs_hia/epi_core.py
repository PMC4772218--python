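"""Exposure-stratum back-calculation and attributable-fraction arithmetic.

Disease inputs arrive at the population level only.  Given the exposed
fraction p and the relative risk RR, the unique stratum-specific rates
satisfying both the mixture constraint

    (1 - p) * rate_unexposed + p * rate_exposed = rate_total

and the risk ratio ``rate_exposed = RR * rate_unexposed`` are

    rate_unexposed = rate_total / ((1 - p) + p * RR).

The population attributable fraction follows as
``PAF = p (RR - 1) / (1 + p (RR - 1)) = 1 - rate_unexposed / rate_total``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model_io import (DISEASES, DomainError, DiseaseInputSet,
                       RelativeRiskTable, SEXES)

__all__ = ["split_rate_by_exposure", "attributable_fraction",
           "ExposureSpecificRates", "build_exposure_specific_rates",
           "counterfactual_rates"]


def _validate(p_exposed, rr) -> None:
    p = np.asarray(p_exposed, dtype=float)
    r = np.asarray(rr, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError(f"exposed fraction outside [0, 1]: {p_exposed}")
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise DomainError(f"relative risk must be finite and > 0: {rr}")


def split_rate_by_exposure(rate_total, p_exposed, rr):
    """Back-calculate (rate_unexposed, rate_exposed) from a population rate.

    Accepts scalars or broadcastable arrays.  The recombined mixture
    reproduces ``rate_total`` to machine precision by construction.
    """
    _validate(p_exposed, rr)
    rate_total = np.asarray(rate_total, dtype=float)
    if np.any(rate_total < 0):
        raise DomainError("rates must be >= 0")
    denom = (1.0 - np.asarray(p_exposed, dtype=float)) \
        + np.asarray(p_exposed, dtype=float) * np.asarray(rr, dtype=float)
    unexposed = rate_total / denom
    exposed = np.asarray(rr, dtype=float) * unexposed
    if unexposed.ndim == 0:
        return float(unexposed), float(exposed)
    return unexposed, exposed


def attributable_fraction(p_exposed, rr):
    """Population attributable fraction p(RR-1) / (1 + p(RR-1)).

    Zero whenever nobody is exposed or RR = 1; negative for protective
    exposures (RR < 1); always in (-1, 1).
    """
    _validate(p_exposed, rr)
    excess = np.asarray(p_exposed, dtype=float) * (np.asarray(rr, dtype=float) - 1.0)
    out = excess / (1.0 + excess)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class ExposureSpecificRates:
    """Stratum-specific disease rates on the (sex, age, disease) grid.

    Prevalence and incidence are split by exposure with the same RR (one RR
    per sex and disease is all the evidence provides); excess mortality is
    not exposure-specific.
    """

    prevalence_unexposed: np.ndarray
    prevalence_exposed: np.ndarray
    incidence_unexposed: np.ndarray
    incidence_exposed: np.ndarray
    excess_mortality: np.ndarray


def build_exposure_specific_rates(inputs: DiseaseInputSet,
                                  p_exposed_by_age: np.ndarray,
                                  rr: RelativeRiskTable) -> ExposureSpecificRates:
    """Split every prevalence and incidence on the grid by exposure stratum.

    ``p_exposed_by_age`` has shape (n_sexes, n_ages).  Raises
    :class:`DomainError`, naming the stratum, if a split probability would
    exceed 1.
    """
    rr_arr = rr.as_array()[:, None, :]                      # (sex, 1, disease)
    p = np.asarray(p_exposed_by_age, dtype=float)[:, :, None]  # (sex, age, 1)
    prev_u, prev_e = split_rate_by_exposure(inputs.prevalence, p, rr_arr)
    inc_u, inc_e = split_rate_by_exposure(inputs.incidence, p, rr_arr)
    for name, arr in (("prevalence", prev_e), ("prevalence", prev_u),
                      ("incidence", inc_e), ("incidence", inc_u)):
        if np.any(arr > 1.0):
            i, a, d = np.unravel_index(int(np.argmax(arr)), arr.shape)
            raise DomainError(
                f"back-calculated {name} exceeds 1 at "
                f"(sex={SEXES[i]}, age={a}, disease={DISEASES[d]}): {arr[i, a, d]:.4f}")
    return ExposureSpecificRates(
        prevalence_unexposed=prev_u, prevalence_exposed=prev_e,
        incidence_unexposed=inc_u, incidence_exposed=inc_e,
        excess_mortality=inputs.excess_mortality.copy(),
    )


def counterfactual_rates(inputs: DiseaseInputSet,
                         p_exposed_by_age: np.ndarray,
                         rr: RelativeRiskTable) -> DiseaseInputSet:
    """Disease inputs for a world in which SHS exposure never existed.

    Every prevalence and incidence is replaced by its back-calculated
    unexposed-stratum value; excess mortality is unchanged.  With zero
    exposure or all RR = 1 the inputs come back unchanged, and the
    operation is idempotent (the unexposed stratum of an unexposed world
    is itself).
    """
    rates = build_exposure_specific_rates(inputs, p_exposed_by_age, rr)
    return DiseaseInputSet(
        prevalence=rates.prevalence_unexposed,
        incidence=rates.incidence_unexposed,
        excess_mortality=inputs.excess_mortality.copy(),
    )
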