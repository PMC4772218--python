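"""Published German estimates used as worked-example inputs.

Three published national tables travel with the package:

* meta-analytic relative risks of IHD, COPD and stroke given regular SHS
  exposure, by sex;
* SHS exposure prevalence by sex and age group (national health survey,
  2009);
* the published national projection of SHS-attributable prevalent cases
  for 2014 and 2040 under the reference, 20%-success and 100%-success
  scenarios, plus the stroke and COPD context totals reported with it.

The first two are the default risk inputs of the synthetic study fixture.
The third is input data for the worked example: every derived statistic in
:func:`derived_statistics` is recomputed from these printed counts by the
package's aggregation and reporting operations, exercising exactly the
arithmetic a reader would do on the published table.
"""

from __future__ import annotations

import pandas as pd

from .model_io import ExposureGroupTable, RelativeRiskTable
from .scenario_reporting import (percent_change, round_half_away,
                                 scenario_reduction)

__all__ = ["relative_risk_table", "exposure_group_table",
           "attributable_cases_table", "stroke_total_cases_2014",
           "copd_cases_age_60_75_2014", "derived_statistics"]

#: point-estimate relative risks (95% CIs stored for completeness only)
RELATIVE_RISKS: dict[tuple[str, str], float] = {
    ("male", "ihd"): 1.06, ("female", "ihd"): 1.50,
    ("male", "copd"): 1.50, ("female", "copd"): 2.17,
    ("male", "stroke"): 1.40, ("female", "stroke"): 1.43,
}

RELATIVE_RISK_CIS: dict[tuple[str, str], tuple[float, float]] = {
    ("male", "ihd"): (0.96, 1.19), ("female", "ihd"): (1.31, 1.72),
    ("male", "copd"): (0.96, 2.28), ("female", "copd"): (1.48, 3.18),
    ("male", "stroke"): (1.09, 1.81), ("female", "stroke"): (1.28, 1.61),
}

#: percent of the population exposed to SHS, by sex and age group
EXPOSURE_PCT: list[tuple[str, int, int | None, float]] = [
    ("male", 18, 29, 72.0), ("female", 18, 29, 61.6),
    ("male", 30, 39, 49.0), ("female", 30, 39, 27.0),
    ("male", 40, 49, 46.4), ("female", 40, 49, 28.1),
    ("male", 50, 59, 42.5), ("female", 50, 59, 24.8),
    ("male", 60, 69, 27.0), ("female", 60, 69, 17.0),
    ("male", 70, None, 16.2), ("female", 70, None, 8.9),
]

#: published SHS-attributable prevalent cases (n) and attributable
#: population prevalence (%) for Germany, by scenario, year, sex, disease
_ATTRIBUTABLE_CASES = [
    # scenario, year, sex, disease, cases, prevalence_pct
    ("reference", 2014, "male", "ihd", 441_137, 1.09),
    ("reference", 2014, "female", "ihd", 246_117, 0.58),
    ("reference", 2014, "male", "copd", 139_103, 0.35),
    ("reference", 2014, "female", "copd", 92_870, 0.22),
    ("reference", 2014, "male", "stroke", 186_281, 0.46),
    ("reference", 2014, "female", "stroke", 101_734, 0.24),
    ("reference", 2040, "male", "ihd", 525_921, 1.46),
    ("reference", 2040, "female", "ihd", 269_788, 0.72),
    ("reference", 2040, "male", "copd", 170_525, 0.47),
    ("reference", 2040, "female", "copd", 99_863, 0.27),
    ("reference", 2040, "male", "stroke", 248_792, 0.69),
    ("reference", 2040, "female", "stroke", 112_438, 0.30),
    ("success_20", 2040, "male", "ihd", 420_737, 1.16),
    ("success_20", 2040, "female", "ihd", 215_831, 0.58),
    ("success_20", 2040, "male", "copd", 136_420, 0.38),
    ("success_20", 2040, "female", "copd", 97_914, 0.21),
    ("success_20", 2040, "male", "stroke", 199_033, 0.55),
    ("success_20", 2040, "female", "stroke", 89_950, 0.24),
    ("success_100", 2040, "male", "ihd", 262_960, 0.73),
    ("success_100", 2040, "female", "ihd", 134_894, 0.36),
    ("success_100", 2040, "male", "copd", 85_262, 0.24),
    ("success_100", 2040, "female", "copd", 49_946, 0.13),
    ("success_100", 2040, "male", "stroke", 124_396, 0.34),
    ("success_100", 2040, "female", "stroke", 56_219, 0.15),
]

#: published total prevalent stroke cases (all causes), Germany 2014
STROKE_TOTAL_CASES_2014 = {"male": 664_653, "female": 685_230}

#: published SHS-attributable COPD cases in the 60-75 age range, 2014
COPD_CASES_AGE_60_75_2014 = {"male": 78_525, "female": 48_335}


def relative_risk_table() -> RelativeRiskTable:
    """The published sex-specific relative risks as a validated table."""
    return RelativeRiskTable(entries=dict(RELATIVE_RISKS),
                             ci=dict(RELATIVE_RISK_CIS))


def exposure_group_table() -> ExposureGroupTable:
    """The published SHS exposure prevalences as a validated table."""
    return ExposureGroupTable(rows=tuple(
        (sex, lo, hi, pct / 100.0) for sex, lo, hi, pct in EXPOSURE_PCT))


def attributable_cases_table() -> pd.DataFrame:
    """Published attributable-case projection as a tidy DataFrame."""
    return pd.DataFrame(_ATTRIBUTABLE_CASES,
                        columns=["scenario", "year", "sex", "disease",
                                 "cases", "prevalence_pct"])


def stroke_total_cases_2014() -> dict[str, int]:
    return dict(STROKE_TOTAL_CASES_2014)


def copd_cases_age_60_75_2014() -> dict[str, int]:
    return dict(COPD_CASES_AGE_60_75_2014)


def derived_statistics() -> dict[str, float]:
    """Recompute every derived headline statistic from the printed counts.

    All values are produced by the package's aggregation operations applied
    to the published table — sums over sexes, attributable shares, percent
    changes 2014 to 2040, the eradication-scenario reduction, and the
    male/female burden ratios — at the precision the published report uses.
    """
    tab = attributable_cases_table()

    def cases(scenario: str, year: int, disease: str, sex: str | None = None) -> float:
        sel = tab[(tab.scenario == scenario) & (tab.year == year)
                  & (tab.disease == disease)]
        if sex is not None:
            sel = sel[sel.sex == sex]
        return float(sel["cases"].sum())

    stats: dict[str, float] = {}
    for d in ("ihd", "copd", "stroke"):
        stats[f"{d}_attributable_cases_2014"] = cases("reference", 2014, d)
        stats[f"{d}_case_change_2014_2040_pct"] = percent_change(
            cases("reference", 2014, d), cases("reference", 2040, d))

    for sex in ("male", "female"):
        share = 100.0 * cases("reference", 2014, "stroke", sex) \
            / STROKE_TOTAL_CASES_2014[sex]
        stats[f"{sex}_stroke_attributable_share_pct"] = round_half_away(share, 2)

    ref_2040 = sum(cases("reference", 2040, d) for d in ("ihd", "copd", "stroke"))
    erad_2040 = sum(cases("success_100", 2040, d) for d in ("ihd", "copd", "stroke"))
    stats["eradication_reduction_2040_pct"] = round_half_away(
        scenario_reduction(ref_2040, erad_2040), 0)

    stats["copd_male_female_ratio_2014"] = round_half_away(
        cases("reference", 2014, "copd", "male")
        / cases("reference", 2014, "copd", "female"), 1)
    stats["male_copd_share_age_60_75_pct"] = round_half_away(
        100.0 * COPD_CASES_AGE_60_75_2014["male"]
        / cases("reference", 2014, "copd", "male"), 2)
    return stats
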