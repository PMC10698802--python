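"""Risk-set construction: observability windows and diabetes-free lead time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_diagnoses, make_prescriptions
from dmclaims.cohort import (
    build_risk_set,
    observable_full_year,
    observable_pre_year,
    prior_diabetes_exclusion,
)


def person(pid=1, birth="1980-06-15", sex="female"):
    return pd.Series(
        {"person_id": pid, "birth_date": pd.Timestamp(birth), "sex": sex}
    )


def spells_of(*ranges, pid=1):
    return pd.DataFrame(
        [
            {
                "person_id": pid,
                "start_date": pd.Timestamp(a),
                "end_date": pd.Timestamp(b),
            }
            for a, b in ranges
        ],
        columns=["person_id", "start_date", "end_date"],
    )


class TestObservability:
    def test_superset_coverage(self):
        s = spells_of(("2015-01-01", "2021-12-31"))
        assert observable_full_year(s, person(), 2018)

    def test_one_day_gap_breaks_coverage(self):
        s = spells_of(("2021-01-01", "2021-06-30"), ("2021-07-02", "2021-12-31"))
        assert not observable_full_year(s, person(), 2021)

    def test_adjacent_spells_cover(self):
        s = spells_of(("2021-01-01", "2021-06-30"), ("2021-07-01", "2021-12-31"))
        assert observable_full_year(s, person(), 2021)

    def test_newborn_covered_from_birth(self):
        s = spells_of(("2021-03-15", "2021-12-31"))
        assert observable_full_year(s, person(birth="2021-03-15"), 2021)

    def test_no_spells_is_not_observable(self):
        assert not observable_full_year(spells_of(), person(), 2021)

    def test_pre_year_full_coverage(self):
        s = spells_of(("2020-01-01", "2021-12-31"))
        assert observable_pre_year(s, person(), 2021)

    def test_pre_year_incomplete(self):
        s = spells_of(("2020-02-01", "2021-12-31"))
        assert not observable_pre_year(s, person(birth="2019-07-01"), 2021)

    def test_pre_year_vacuous_for_study_year_newborn(self):
        assert observable_pre_year(spells_of(), person(birth="2021-05-01"), 2021)

    def test_pre_year_from_birth_for_pre_year_newborn(self):
        s = spells_of(("2020-08-01", "2021-12-31"))
        assert observable_pre_year(s, person(birth="2020-08-01"), 2021)


class TestPriorDiabetesExclusion:
    def test_confirmed_outpatient_excludes(self):
        dx = make_diagnoses([(1, "E11", "outpatient", "confirmed", 2020, 3)])
        rx = make_prescriptions([])
        assert prior_diabetes_exclusion(dx, rx, person(), 2021)

    def test_suspected_outpatient_ignored(self):
        dx = make_diagnoses([(1, "E11", "outpatient", "suspected", 2020, 3)])
        rx = make_prescriptions([])
        assert not prior_diabetes_exclusion(dx, rx, person(), 2021)

    def test_prescription_alone_excludes(self):
        dx = make_diagnoses([])
        rx = make_prescriptions([(1, "A10BA02", 2020, 1)])
        assert prior_diabetes_exclusion(dx, rx, person(), 2021)

    def test_records_in_study_year_do_not_exclude(self):
        dx = make_diagnoses([(1, "E11", "inpatient_main", "confirmed", 2021, 1)])
        rx = make_prescriptions([])
        assert not prior_diabetes_exclusion(dx, rx, person(), 2021)


def test_empty_persons_table_gives_zeroed_log():
    persons = pd.DataFrame(
        columns=["person_id", "sex", "birth_date", "district_code"]
    )
    rs = build_risk_set(persons, spells_of(), make_diagnoses([]), make_prescriptions([]), 2020)
    assert rs.members.empty
    assert all(count == 0 for count in rs.exclusion_log.values())


def test_filter_counts_monotone(noisy_run):
    _, _, risk_sets, _ = noisy_run
    for rs in risk_sets.values():
        counts = list(rs.exclusion_log.values())
        assert counts == sorted(counts, reverse=True)


def test_exclusion_completeness_by_rescan(noisy_run):
    """No risk-set member may hold any qualifying diabetes record or A10
    prescription in the pre-observation year."""
    _, data, risk_sets, _ = noisy_run
    for year, rs in risk_sets.items():
        d = data.diagnoses[data.diagnoses["year"] == year - 1]
        qualifying = d[
            d["icd3"].isin(["E10", "E11", "E12", "E13", "E14"])
            & (
                ((d["setting"] == "outpatient") & (d["certainty"] == "confirmed"))
                | d["setting"].isin(["inpatient_main", "inpatient_secondary"])
            )
        ]
        p = data.prescriptions[data.prescriptions["year"] == year - 1]
        flagged = set(qualifying["person_id"]) | set(
            p[p["atc"].str.startswith("A10")]["person_id"]
        )
        assert not flagged & set(rs.members["person_id"])


def test_prevalent_persons_are_exactly_the_diabetes_exclusions(noisy_run):
    """In the first reporting year the only diabetes evidence in the
    pre-observation year comes from prevalent persons, so the stage-4
    exclusions equal the prevalent survivors of stage 3 — and their count
    is binomially consistent with the configured prevalent fraction."""
    config, data, risk_sets, _ = noisy_run
    year = config.years[0]
    rs = risk_sets[year]
    excluded = rs.exclusion_log["observable_pre_year"] - rs.exclusion_log["no_prior_diabetes"]
    prevalent_ids = set(data.persons[data.persons["prevalent"]]["person_id"])
    member_ids = set(rs.members["person_id"])
    assert not prevalent_ids & member_ids
    # binomial consistency: ~prevalent_fraction of the otherwise-eligible
    n = rs.exclusion_log["observable_pre_year"]
    p = config.prevalent_fraction
    assert abs(excluded - n * p) <= 3 * np.sqrt(n * p * (1 - p))


def test_member_ages_valid(noisy_run):
    _, data, risk_sets, _ = noisy_run
    for year, rs in risk_sets.items():
        ages = rs.members["age"]
        assert ages.between(0, 120).all()
        birth = rs.members["person_id"].map(
            data.persons.set_index("person_id")["birth_date"]
        )
        assert (ages.to_numpy() == year - birth.dt.year.to_numpy()).all()
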