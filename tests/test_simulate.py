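"""Synthetic claims generator: structure, determinism, truth recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmclaims import ScenarioConfig, generate_population, simulate_scenario
from dmclaims.config import AgeBand, config_overrides
from dmclaims.deprivation import categorize_districts
from dmclaims.simulate import generate_districts, simulate_onsets


def flat_rate_config(rate: float, **overrides) -> ScenarioConfig:
    """Constant incidence across ages 20-59, all of it type 1."""
    params = dict(
        age_sex_structure=[AgeBand(age_min=20, age_max=59, female=0.5, male=0.5)],
        true_incidence_t1=[AgeBand(age_min=0, age_max=120, female=rate, male=rate)],
        true_incidence_t2=[AgeBand(age_min=0, age_max=120, female=0.0, male=0.0)],
        prevalent_fraction=0.0,
        annual_disenrollment_prob=0.0,
        annual_death_prob=0.0,
        deprivation_rate_ratio=1.0,
    )
    params.update(overrides)
    return ScenarioConfig.noiseless(**params)


def test_empty_population():
    config = ScenarioConfig(n_persons=0)
    persons, spells = generate_population(config)
    assert persons.empty and spells.empty
    data = simulate_scenario(config)
    assert data.onsets.empty and data.diagnoses.empty


def test_continuous_enrollment_without_attrition():
    config = ScenarioConfig(
        n_persons=3000,
        years=(2019, 2020),
        annual_disenrollment_prob=0.0,
        annual_death_prob=0.0,
        rng_seed=3,
    )
    persons, spells = generate_population(config)
    assert spells["person_id"].is_unique
    expected_start = persons["birth_date"].clip(lower=pd.Timestamp(2018, 1, 1))
    assert (spells["start_date"].to_numpy() == expected_start.to_numpy()).all()
    assert (spells["end_date"] == pd.Timestamp(2020, 12, 31)).all()


def test_regeneration_is_byte_identical():
    config = ScenarioConfig(n_persons=10_000, years=(2019, 2019), rng_seed=42)
    a = simulate_scenario(config)
    b = simulate_scenario(config)
    for name in ("persons", "spells", "diagnoses", "prescriptions", "onsets"):
        assert getattr(a, name).to_csv() == getattr(b, name).to_csv()


def test_zero_hazard_yields_no_onsets():
    config = flat_rate_config(0.0, n_persons=5000, years=(2019, 2019))
    data = simulate_scenario(config)
    assert data.onsets.empty


def test_onset_count_matches_poisson_expectation():
    """100,000 person-years at 100/100,000 gives ~100 onsets (3 SD)."""
    config = flat_rate_config(100.0, n_persons=100_000, years=(2019, 2019), rng_seed=5)
    persons, spells = generate_population(config)
    onsets = simulate_onsets(persons, spells, config)
    assert abs(len(onsets) - 100) <= 3 * np.sqrt(100)


def test_no_deprivation_gradient_under_null():
    """With rate ratio 1, onsets are independent of district category:
    chi-square non-significant at alpha=0.01 in at least 19 of 20 seeds."""
    n_significant = 0
    for seed in range(20):
        config = flat_rate_config(
            2000.0, n_persons=10_000, years=(2019, 2019), rng_seed=100 + seed
        )
        persons, spells = generate_population(config)
        districts = generate_districts(config)
        onsets = simulate_onsets(persons, spells, config, districts=districts)
        cat = categorize_districts(districts).set_index("district_code")["category"]
        person_cat = persons.set_index("person_id")["district_code"].map(cat)
        observed = person_cat.loc[onsets["person_id"]].value_counts().sort_index()
        share = person_cat.value_counts(normalize=True).sort_index()
        _, p = stats.chisquare(observed, f_exp=share * observed.sum())
        n_significant += p < 0.01
    assert n_significant <= 1


def test_full_suppression_silences_a_quarter():
    """Disruption multiplier 0 means no index diagnoses dated that quarter."""
    config = flat_rate_config(
        3000.0,
        n_persons=5000,
        years=(2019, 2019),
        disruption={"2019Q2": 0.0},
        confirmation_prob=0.0,  # only index records remain
        filler_diagnosis_rate=0.0,
        rng_seed=9,
    )
    data = simulate_scenario(config)
    assert len(data.diagnoses)
    q2 = data.diagnoses[(data.diagnoses["year"] == 2019) & (data.diagnoses["quarter"] == 2)]
    assert q2.empty


def test_unconfirmed_outpatient_cases_stay_undetected():
    """confirmation_prob=0 with outpatient-only index diagnoses can never
    satisfy m2Q, so the pipeline finds zero incident cases."""
    from dmclaims.pipeline import detect_and_classify

    config = flat_rate_config(
        2000.0,
        n_persons=5000,
        years=(2019, 2019),
        confirmation_prob=0.0,
        outpatient_index_prob=1.0,
        inpatient_main_index_prob=0.0,
        rng_seed=13,
    )
    data = simulate_scenario(config)
    assert len(data.onsets) > 0
    _, cases = detect_and_classify(data, [2019])
    assert cases.empty


def test_config_validation_errors():
    with pytest.raises(ValueError):
        ScenarioConfig(n_persons=-5)
    with pytest.raises(ValueError):
        ScenarioConfig(seasonal_multipliers=[1.2, 1.2, 1.2, 1.2])
    with pytest.raises(ValueError):
        ScenarioConfig(disruption={"2020Q5": 0.5})
    with pytest.raises(ValueError):
        ScenarioConfig(disruption={"2020Q2": 1.5})
    with pytest.raises(ValueError):
        config_overrides(ScenarioConfig(), annual_death_prob=2.0)


def test_age_sex_cells_sum_to_one():
    cells = ScenarioConfig().age_sex_cells()
    assert cells["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
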