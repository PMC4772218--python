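"""Domain types, CSV schemas and run configuration.

All model inputs and outputs travel through the plain-CSV schemas defined
here.  Conventions shared by every module:

* sexes are the strings ``"male"`` / ``"female"`` (the readers also accept
  ``men`` / ``women`` and map them);
* diseases are ``"ihd"`` / ``"copd"`` / ``"stroke"``;
* ages are integer single years 0..95, where 95 means "95 and older";
* columns holding percentages carry a ``_pct`` suffix; everything held in
  memory is a proportion in [0, 1].
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SEXES: tuple[str, str] = ("male", "female")
DISEASES: tuple[str, str, str] = ("ihd", "copd", "stroke")
MAX_AGE: int = 95
N_AGES: int = MAX_AGE + 1
AGES: np.ndarray = np.arange(N_AGES)

_SEX_ALIASES = {"male": "male", "men": "male", "m": "male",
                "female": "female", "women": "female", "f": "female"}

DEFAULT_NEWBORN_SEX_RATIO = 1.05  # male births per female birth


class SchemaError(ValueError):
    """A table is structurally wrong: missing cells, columns or coverage."""


class DomainError(ValueError):
    """A value lies outside its scientifically valid domain."""


def _canon_sex(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _SEX_ALIASES:
        raise SchemaError(f"unknown sex label {value!r}")
    return _SEX_ALIASES[key]


# ---------------------------------------------------------------------------
# Relative risks
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RelativeRiskTable:
    """Relative risk of each disease given SHS exposure, per sex.

    ``entries`` maps ``(sex, disease)`` to the point-estimate RR.  Optional
    confidence bounds can be stored alongside but are never used by the
    engine (the assessment runs on point estimates only).
    """

    entries: Mapping[tuple[str, str], float]
    ci: Mapping[tuple[str, str], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        missing = [(s, d) for s in SEXES for d in DISEASES
                   if (s, d) not in self.entries]
        if missing:
            raise SchemaError(f"relative-risk table missing cells: {missing}")
        for key, rr in self.entries.items():
            if not np.isfinite(rr) or rr <= 0:
                raise DomainError(f"relative risk for {key} must be finite and > 0, got {rr}")

    def rr(self, sex: str, disease: str) -> float:
        return float(self.entries[(sex, disease)])

    def as_array(self) -> np.ndarray:
        """RR values as an array of shape (n_sexes, n_diseases)."""
        return np.array([[self.entries[(s, d)] for d in DISEASES] for s in SEXES])

    @classmethod
    def from_csv(cls, path: str | Path) -> "RelativeRiskTable":
        df = pd.read_csv(path)
        required = {"sex", "disease", "rr"}
        if not required.issubset(df.columns):
            raise SchemaError(f"relative-risk CSV needs columns {sorted(required)}, "
                              f"got {list(df.columns)}")
        entries: dict[tuple[str, str], float] = {}
        ci: dict[tuple[str, str], tuple[float, float]] = {}
        for _, row in df.iterrows():
            key = (_canon_sex(row["sex"]), str(row["disease"]).strip().lower())
            entries[key] = float(row["rr"])
            if "ci_low" in df.columns and "ci_high" in df.columns and \
                    np.isfinite(row.get("ci_low", np.nan)):
                ci[key] = (float(row["ci_low"]), float(row["ci_high"]))
        return cls(entries=entries, ci=ci or None)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for s in SEXES:
            for d in DISEASES:
                row = {"sex": s, "disease": d, "rr": self.entries[(s, d)]}
                if self.ci and (s, d) in self.ci:
                    row["ci_low"], row["ci_high"] = self.ci[(s, d)]
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def read_rr_table(path: str | Path) -> RelativeRiskTable:
    """Read and validate a relative-risk CSV (columns sex, disease, rr)."""
    return RelativeRiskTable.from_csv(path)


# ---------------------------------------------------------------------------
# Exposure prevalence by age group
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ExposureGroupTable:
    """Fraction of the population exposed to SHS, per sex and age group.

    ``rows`` holds ``(sex, age_lo, age_hi, fraction_exposed)`` with
    ``age_hi = None`` for the open-ended top group ("70+").  Groups must be
    non-overlapping and jointly cover ages 18 through 95.
    """

    rows: Sequence[tuple[str, int, int | None, float]]

    def __post_init__(self) -> None:
        for sex in SEXES:
            covered = np.zeros(N_AGES, dtype=int)
            for s, lo, hi, frac in self.rows:
                if s != sex:
                    continue
                if not (0.0 <= frac <= 1.0):
                    raise DomainError(
                        f"exposed fraction {frac} for {s} {lo}-{hi} outside [0, 1]")
                top = MAX_AGE if hi is None else min(int(hi), MAX_AGE)
                if top < lo:
                    raise SchemaError(f"age group {lo}-{hi} is empty")
                covered[int(lo):top + 1] += 1
            if (covered[18:] > 1).any():
                ages = np.nonzero(covered[18:] > 1)[0] + 18
                raise SchemaError(f"{sex}: overlapping age groups at ages {ages.tolist()}")
            if (covered[18:] == 0).any():
                ages = np.nonzero(covered[18:] == 0)[0] + 18
                raise SchemaError(f"{sex}: ages {ages.tolist()} not covered by any group")

    def fraction(self, sex: str, age: int) -> float:
        age = min(int(age), MAX_AGE)
        if age < 18:
            return 0.0
        for s, lo, hi, frac in self.rows:
            top = MAX_AGE if hi is None else int(hi)
            if s == sex and lo <= age <= top:
                return float(frac)
        raise SchemaError(f"no group covers ({sex}, {age})")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExposureGroupTable":
        df = pd.read_csv(path)
        required = {"sex", "age_lo", "age_hi", "percent_exposed_pct"}
        # accept the un-suffixed spelling too
        pct_col = "percent_exposed_pct" if "percent_exposed_pct" in df.columns \
            else "percent_exposed"
        if not {"sex", "age_lo", pct_col}.issubset(df.columns):
            raise SchemaError(f"exposure CSV needs columns {sorted(required)}, "
                              f"got {list(df.columns)}")
        rows = []
        for _, row in df.iterrows():
            pct = float(row[pct_col])
            if not (0.0 <= pct <= 100.0):
                raise DomainError(f"percent exposed {pct} outside [0, 100]")
            hi = row.get("age_hi")
            hi = None if pd.isna(hi) else int(hi)
            rows.append((_canon_sex(row["sex"]), int(row["age_lo"]), hi, pct / 100.0))
        return cls(rows=tuple(rows))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"sex": s, "age_lo": lo, "age_hi": hi, "percent_exposed_pct": 100.0 * f}
             for s, lo, hi, f in self.rows]
        ).to_csv(path, index=False)


def read_exposure_table(path: str | Path) -> ExposureGroupTable:
    """Read and validate an SHS exposure CSV (percent column -> proportions)."""
    return ExposureGroupTable.from_csv(path)


# ---------------------------------------------------------------------------
# Disease inputs
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DiseaseInputSet:
    """Per (sex, age, disease) epidemiological inputs.

    ``prevalence`` is the population disease prevalence (proportion),
    ``incidence`` the annual risk of onset among the disease-free, and
    ``excess_mortality`` the annual additional death risk of prevalent
    cases.  Arrays have shape ``(n_sexes, n_ages, n_diseases)`` ordered by
    :data:`SEXES`, age 0..95 and :data:`DISEASES`.
    """

    prevalence: np.ndarray
    incidence: np.ndarray
    excess_mortality: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(SEXES), N_AGES, len(DISEASES))
        for name in ("prevalence", "incidence", "excess_mortality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != shape:
                raise SchemaError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.isfinite(arr).all():
                raise DomainError(f"{name} contains non-finite values")
            if (arr < 0).any() or (arr > 1).any():
                raise DomainError(f"{name} values must be annual risks in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product([SEXES, AGES, DISEASES],
                                         names=["sex", "age", "disease"])
        return pd.DataFrame(
            {"prevalence": self.prevalence.ravel(),
             "incidence": self.incidence.ravel(),
             "excess_mortality": self.excess_mortality.ravel()},
            index=idx,
        ).reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DiseaseInputSet":
        required = {"sex", "age", "disease", "prevalence", "incidence", "excess_mortality"}
        if not required.issubset(df.columns):
            raise SchemaError(f"disease-input table needs columns {sorted(required)}")
        arrays = {}
        piv = df.copy()
        piv["sex"] = piv["sex"].map(_canon_sex)
        for name in ("prevalence", "incidence", "excess_mortality"):
            wide = piv.pivot_table(index=["sex", "age"], columns="disease",
                                   values=name, aggfunc="first")
            try:
                arr = np.stack([
                    wide.loc[s].reindex(index=AGES, columns=list(DISEASES)).to_numpy()
                    for s in SEXES
                ])
            except KeyError as exc:
                raise SchemaError(f"disease-input table missing stratum: {exc}") from exc
            if np.isnan(arr).any():
                raise SchemaError(f"disease-input table has missing {name} cells")
            arrays[name] = arr
        return cls(**arrays)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiseaseInputSet":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Population pyramid
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PopulationPyramid:
    """Population counts and all-cause mortality per sex and single-year age.

    ``counts`` and ``all_cause_mortality`` have shape (n_sexes, n_ages); age
    95 is an open-ended top bucket.  ``newborns_per_year`` is the total
    annual birth inflow (both sexes), split male:female by
    ``newborn_sex_ratio`` (default 1.05).  There is no migration.
    """

    counts: np.ndarray
    all_cause_mortality: np.ndarray
    newborns_per_year: float = 0.0
    newborn_sex_ratio: float = DEFAULT_NEWBORN_SEX_RATIO

    def __post_init__(self) -> None:
        shape = (len(SEXES), N_AGES)
        for name in ("counts", "all_cause_mortality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != shape:
                raise SchemaError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.isfinite(arr).all():
                raise DomainError(f"{name} contains non-finite values")
        if (self.counts < 0).any():
            raise DomainError("population counts must be >= 0")
        if (self.all_cause_mortality < 0).any() or (self.all_cause_mortality > 1).any():
            raise DomainError("all-cause mortality must be an annual probability in [0, 1]")
        if self.newborns_per_year < 0:
            raise DomainError("newborns_per_year must be >= 0")
        if self.newborn_sex_ratio <= 0:
            raise DomainError("newborn sex ratio must be > 0")

    @property
    def newborns_by_sex(self) -> np.ndarray:
        """Annual newborn inflow split (male, female) by the sex ratio."""
        r = self.newborn_sex_ratio
        return self.newborns_per_year * np.array([r / (1.0 + r), 1.0 / (1.0 + r)])

    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product([SEXES, AGES], names=["sex", "age"])
        return pd.DataFrame(
            {"count": self.counts.ravel(),
             "all_cause_mortality": self.all_cause_mortality.ravel()},
            index=idx).reset_index()

    @classmethod
    def from_csv(cls, path: str | Path, *, newborns_per_year: float | None = None,
                 newborn_sex_ratio: float = DEFAULT_NEWBORN_SEX_RATIO) -> "PopulationPyramid":
        df = pd.read_csv(path)
        required = {"sex", "age", "count", "all_cause_mortality"}
        if not required.issubset(df.columns):
            raise SchemaError(f"population CSV needs columns {sorted(required)}")
        df = df.copy()
        df["sex"] = df["sex"].map(_canon_sex)
        counts = np.zeros((len(SEXES), N_AGES))
        mort = np.zeros((len(SEXES), N_AGES))
        seen = np.zeros((len(SEXES), N_AGES), dtype=bool)
        for _, row in df.iterrows():
            i, a = SEXES.index(row["sex"]), int(row["age"])
            counts[i, a] = float(row["count"])
            mort[i, a] = float(row["all_cause_mortality"])
            seen[i, a] = True
        if not seen.all():
            raise SchemaError("population CSV does not cover every (sex, age) cell")
        if newborns_per_year is None:
            newborns_per_year = float(counts[:, 0].sum())
        return cls(counts=counts, all_cause_mortality=mort,
                   newborns_per_year=newborns_per_year,
                   newborn_sex_ratio=newborn_sex_ratio)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scenarios and run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Scenario:
    """A counterfactual exposure-reduction policy.

    ``success_rate`` is the fraction by which the exposed share is reduced
    at every (sex, age) from ``start_year`` onwards: 0 leaves the schedule
    untouched (reference), 1 eradicates exposure.
    """

    name: str
    success_rate: float
    start_year: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.success_rate <= 1.0):
            raise DomainError(f"success_rate {self.success_rate} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    start_year: int = 2014
    end_year: int = 2040
    n_individuals: int = 10_000
    rng_seed: int = 0
    scenarios: tuple[Scenario, ...] = ()
    engine_mode: str = "micro"

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise DomainError("end_year must be >= start_year")
        if self.n_individuals < 1:
            raise DomainError("n_individuals must be >= 1")
        if self.engine_mode not in ("micro", "deterministic"):
            raise DomainError(f"engine_mode must be 'micro' or 'deterministic', "
                              f"got {self.engine_mode!r}")
        if not self.scenarios:
            object.__setattr__(
                self, "scenarios",
                (Scenario("reference", 0.0, self.start_year),))
        else:
            object.__setattr__(self, "scenarios", tuple(self.scenarios))

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


@dataclasses.dataclass(frozen=True)
class RunInputs:
    """All loaded tables plus the simulation configuration for one run."""

    population: PopulationPyramid
    disease_inputs: DiseaseInputSet
    exposure: ExposureGroupTable
    rr: RelativeRiskTable
    config: SimulationConfig
    output_dir: Path | None = None


def load_config(path: str | Path) -> RunInputs:
    """Load a YAML run configuration and every table it references.

    Relative paths in the file are resolved against the file's directory.
    Recognised keys: population, exposure, rr, disease_inputs, start_year,
    end_year, n_individuals, seed, scenarios, engine_mode, output_dir,
    newborns_per_year, newborn_sex_ratio.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent

    def _resolve(key: str) -> Path:
        if key not in cfg:
            raise SchemaError(f"config missing required key {key!r}")
        p = Path(cfg[key])
        return p if p.is_absolute() else base / p

    scenarios = tuple(
        Scenario(name=s["name"], success_rate=float(s["success_rate"]),
                 start_year=int(s.get("start_year", cfg.get("start_year", 2014))))
        for s in cfg.get("scenarios", [])
    )
    config = SimulationConfig(
        start_year=int(cfg.get("start_year", 2014)),
        end_year=int(cfg.get("end_year", 2040)),
        n_individuals=int(cfg.get("n_individuals", 10_000)),
        rng_seed=int(cfg.get("seed", 0)),
        scenarios=scenarios,
        engine_mode=str(cfg.get("engine_mode", "micro")),
    )
    population = PopulationPyramid.from_csv(
        _resolve("population"),
        newborns_per_year=cfg.get("newborns_per_year"),
        newborn_sex_ratio=float(cfg.get("newborn_sex_ratio", DEFAULT_NEWBORN_SEX_RATIO)),
    )
    out = cfg.get("output_dir")
    out_dir = (base / out if out and not Path(out).is_absolute() else
               Path(out) if out else None)
    return RunInputs(
        population=population,
        disease_inputs=DiseaseInputSet.from_csv(_resolve("disease_inputs")),
        exposure=ExposureGroupTable.from_csv(_resolve("exposure")),
        rr=RelativeRiskTable.from_csv(_resolve("rr")),
        config=config,
        output_dir=out_dir,
    )


def write_config(path: str | Path, cfg: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Scenario results I/O
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["year", "scenario", "sex", "age", "disease", "total_cases",
                  "counterfactual_cases", "attributable_cases", "population",
                  "population_prevalence_pct"]


def write_results_csv(result_frame: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format scenario-result grid; round-trips losslessly."""
    missing = set(RESULT_COLUMNS) - set(result_frame.columns)
    if missing:
        raise SchemaError(f"result frame missing columns {sorted(missing)}")
    result_frame[RESULT_COLUMNS].to_csv(path, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"result CSV missing columns {sorted(missing)}")
    return df
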