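"""Scenario configuration for the synthetic claims generator.

A :class:`ScenarioConfig` is the generative truth of a simulation run: the
insured population's age/sex structure, the true type-specific incidence
rates, seasonal and pandemic care-seeking multipliers, the district
deprivation gradient, and the coding-noise parameters.  Downstream stages
never see this truth; parameter-recovery tests compare their estimates
against it.

Default values describe a statutory-health-insurance population in Germany
in the late 2010s: the age/sex structure and the type-specific incidence
bands follow published claims-based risk-population and incidence tables,
the prevalent fraction matches the share of insured persons excluded for
pre-existing diabetes (~9 %), and the deprivation rate ratio reflects the
observed high/low-deprivation contrast (~1.3).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .quarters import parse_qlabel

MAX_AGE = 120


class AgeBand(BaseModel):
    """A value per sex on an inclusive range of completed years of age.

    Used both for population proportions and for incidence rates
    (per 100,000 person-years).
    """

    age_min: int = Field(ge=0, le=MAX_AGE)
    age_max: int = Field(ge=0, le=MAX_AGE)
    female: float = Field(ge=0)
    male: float = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.age_max < self.age_min:
            raise ValueError("age_max must be >= age_min")
        return self


def _bands(rows) -> list[AgeBand]:
    return [
        AgeBand(age_min=lo, age_max=hi, female=f, male=m) for lo, hi, f, m in rows
    ]


# Risk-population age/sex structure (shares of the full population; female
# share 0.508).  Shaped after the claims risk population of 2021.
DEFAULT_AGE_SEX_STRUCTURE = _bands(
    [
        (0, 6, 0.0391, 0.0413),
        (7, 10, 0.0198, 0.0207),
        (11, 13, 0.0158, 0.0167),
        (14, 17, 0.0213, 0.0221),
        (18, 34, 0.0991, 0.1077),
        (35, 49, 0.1082, 0.1013),
        (50, 64, 0.1233, 0.1159),
        (65, 79, 0.0579, 0.0487),
        (80, 89, 0.0239, 0.0172),
    ]
)

# Type 1 diabetes incidence per 100,000 person-years (claims-based, 2021).
DEFAULT_T1_RATES = _bands(
    [
        (0, 6, 25.3, 33.6),
        (7, 10, 44.1, 37.4),
        (11, 13, 39.9, 58.6),
        (14, 17, 20.7, 23.2),
        (18, 34, 11.9, 14.1),
        (35, 49, 4.4, 8.6),
        (50, MAX_AGE, 2.8, 3.6),
    ]
)

# Type 2 diabetes incidence per 100,000 person-years (claims-based, 2021).
DEFAULT_T2_RATES = _bands(
    [
        (0, 17, 14.0, 13.0),
        (18, 34, 170.0, 110.0),
        (35, 49, 420.0, 620.0),
        (50, 64, 980.0, 1560.0),
        (65, 79, 1660.0, 2170.0),
        (80, MAX_AGE, 1620.0, 1830.0),
    ]
)

# Mild first-quarter diagnosis peak; mean exactly 1.
DEFAULT_SEASONAL = [1.1, 0.95, 0.95, 1.0]


class ScenarioConfig(BaseModel):
    """Generative truth for one synthetic claims scenario."""

    n_persons: int = Field(default=100_000, ge=0)
    years: tuple[int, int] = (2015, 2021)
    age_sex_structure: list[AgeBand] = Field(
        default_factory=lambda: [b.model_copy() for b in DEFAULT_AGE_SEX_STRUCTURE]
    )
    true_incidence_t1: list[AgeBand] = Field(
        default_factory=lambda: [b.model_copy() for b in DEFAULT_T1_RATES]
    )
    true_incidence_t2: list[AgeBand] = Field(
        default_factory=lambda: [b.model_copy() for b in DEFAULT_T2_RATES]
    )
    seasonal_multipliers: list[float] = Field(
        default_factory=lambda: list(DEFAULT_SEASONAL)
    )
    #: per-quarter care-seeking multiplier in [0, 1], keyed "YYYYQn"
    disruption: dict[str, float] = Field(default_factory=dict)
    deprivation_rate_ratio: float = Field(default=1.3, gt=0)
    n_districts: int = Field(default=40, ge=5)
    prevalent_fraction: float = Field(default=0.09, ge=0, le=1)
    annual_disenrollment_prob: float = Field(default=0.02, ge=0, le=1)
    annual_death_prob: float = Field(default=0.01, ge=0, le=1)
    confirmation_prob: float = Field(default=0.9, ge=0, le=1)
    misc_coding_prob: float = Field(default=0.03, ge=0, le=1)
    catch_up_prob: float = Field(default=0.8, ge=0, le=1)
    outpatient_index_prob: float = Field(default=0.8, ge=0, le=1)
    inpatient_main_index_prob: float = Field(default=0.1, ge=0, le=1)
    t2_medicated_fraction: float = Field(default=0.5, ge=0, le=1)
    filler_diagnosis_rate: float = Field(default=0.5, ge=0)
    rng_seed: int = 20150101

    @field_validator("years")
    @classmethod
    def _years_ordered(cls, v):
        if v[1] < v[0]:
            raise ValueError("years must be an inclusive (first, last) range")
        return v

    @field_validator("seasonal_multipliers")
    @classmethod
    def _seasonal(cls, v):
        if len(v) != 4:
            raise ValueError("seasonal_multipliers must have length 4")
        if any(x < 0 for x in v):
            raise ValueError("seasonal_multipliers must be non-negative")
        if abs(sum(v) / 4.0 - 1.0) > 1e-9:
            raise ValueError("seasonal_multipliers must average to 1")
        return v

    @field_validator("disruption")
    @classmethod
    def _disruption(cls, v):
        for key, mult in v.items():
            parse_qlabel(key)
            if not 0.0 <= mult <= 1.0:
                raise ValueError(f"disruption multiplier for {key} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _structure_sums_to_one(self):
        total = sum(b.female + b.male for b in self.age_sex_structure)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(
                f"age_sex_structure proportions must sum to 1 (got {total:.6f})"
            )
        # renormalise exactly so downstream cell proportions sum to 1
        for b in self.age_sex_structure:
            b.female /= total
            b.male /= total
        if self.outpatient_index_prob + self.inpatient_main_index_prob > 1.0 + 1e-12:
            raise ValueError(
                "outpatient_index_prob + inpatient_main_index_prob must be <= 1"
            )
        return self

    # -- derived views ------------------------------------------------------

    def age_sex_cells(self) -> pd.DataFrame:
        """Expand bands to 1-year age x sex proportions (uniform within band)."""
        rows = []
        for b in self.age_sex_structure:
            span = b.age_max - b.age_min + 1
            for age in range(b.age_min, b.age_max + 1):
                rows.append((age, "female", b.female / span))
                rows.append((age, "male", b.male / span))
        cells = pd.DataFrame(rows, columns=["age", "sex", "proportion"])
        return cells.groupby(["age", "sex"], as_index=False, observed=True)[
            "proportion"
        ].sum()

    def disruption_multiplier(self, year: int, quarter: int) -> float:
        return float(self.disruption.get(f"{year}Q{quarter}", 1.0))

    # -- canned scenarios ---------------------------------------------------

    @classmethod
    def noiseless(cls, **overrides) -> "ScenarioConfig":
        """Regime in which every onset yields a detectable, correctly coded
        record set: full observation (uniform seasonality, no disruption),
        certain confirmation, no miscoding."""
        params = dict(
            seasonal_multipliers=[1.0, 1.0, 1.0, 1.0],
            disruption={},
            confirmation_prob=1.0,
            misc_coding_prob=0.0,
            catch_up_prob=1.0,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def pandemic(cls, **overrides) -> "ScenarioConfig":
        """2020/2021 care-disruption scenario: a sharp second-quarter 2020
        dip, a milder second winter wave, and diagnostic catch-up."""
        params = dict(
            years=(2019, 2021),
            disruption={"2020Q2": 0.4, "2020Q3": 0.8, "2020Q4": 0.8, "2021Q1": 0.9},
            catch_up_prob=0.5,
        )
        params.update(overrides)
        return cls(**params)


def rate_lookup(bands: list[AgeBand], ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
    """Per-person value from an age-band table; ages outside all bands get 0."""
    female = np.zeros(MAX_AGE + 1)
    male = np.zeros(MAX_AGE + 1)
    for b in bands:
        female[b.age_min : b.age_max + 1] = b.female
        male[b.age_min : b.age_max + 1] = b.male
    ages = np.clip(np.asarray(ages, dtype=int), 0, MAX_AGE)
    is_f = np.asarray(sexes) == "female"
    return np.where(is_f, female[ages], male[ages])


def load_config(path) -> ScenarioConfig:
    """Read a scenario config from a YAML or JSON file."""
    import json

    import yaml

    text = open(path, "r", encoding="utf-8").read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "years" in data and isinstance(data["years"], str):
        first, last = data["years"].split(":")
        data["years"] = (int(first), int(last))
    return ScenarioConfig.model_validate(data)


def config_overrides(config: ScenarioConfig, **kwargs) -> ScenarioConfig:
    """Copy a config with field overrides (revalidated)."""
    data = config.model_dump()
    data.update({k: v for k, v in kwargs.items() if v is not None})
    return ScenarioConfig.model_validate(data)
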