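"""Study-population (risk set) construction for one reporting year.

For each reporting year the incidence denominator contains every insured
person who (i) was insured at least one day in the year, (ii) was fully
observable through the year — or from birth to 31 Dec for persons born
during the year, (iii) was fully observable through the preceding calendar
year (the pre-observation period) — again from birth for persons born in
that year, vacuously for persons born in the study year itself — and (iv)
shows no evidence of diabetes in the pre-observation period: no confirmed
outpatient E10–E14 diagnosis, no inpatient main or secondary E10–E14
diagnosis, and no A10A/A10B prescription.

Age is defined as completed years on 31 Dec of the reporting year, the
anchor used for eligibility, extrapolation and standardisation alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIABETES_CODES = ("E10", "E11", "E12", "E13", "E14")
STAGES = [
    "insured_in_year",
    "observable_study_year",
    "observable_pre_year",
    "no_prior_diabetes",
]


@dataclass
class RiskSet:
    """Persons at risk in a reporting year, with the filter flow counts."""

    year: int
    members: pd.DataFrame  # person_id, sex, age, district_code
    exclusion_log: dict[str, int] = field(default_factory=dict)


def _qualifying_diagnosis_mask(diagnoses: pd.DataFrame) -> pd.Series:
    """E10–E14 records that count anywhere in the pipeline: confirmed
    outpatient, or inpatient main/secondary."""
    is_dm = diagnoses["icd3"].isin(DIABETES_CODES)
    outpatient_ok = (diagnoses["setting"] == "outpatient") & (
        diagnoses["certainty"] == "confirmed"
    )
    inpatient = diagnoses["setting"].isin(["inpatient_main", "inpatient_secondary"])
    return is_dm & (outpatient_ok | inpatient)


def _covers(spells: pd.DataFrame, targets: pd.DataFrame) -> pd.Series:
    """True per target person iff the union of that person's spells covers
    [t_start, t_end] without a gap of one day or more.

    ``targets``: person_id, t_start, t_end (one row per person).
    """
    if targets.empty:
        return pd.Series(dtype=bool)
    s = spells.merge(targets, on="person_id", how="inner")
    s = s[(s["end_date"] >= s["t_start"]) & (s["start_date"] <= s["t_end"])]
    result = pd.Series(False, index=targets["person_id"].to_numpy())
    if s.empty:
        return result
    s["cstart"] = s[["start_date", "t_start"]].max(axis=1)
    s["cend"] = s[["end_date", "t_end"]].min(axis=1)
    s = s.sort_values(["person_id", "cstart"], kind="stable")
    cummax_end = s.groupby("person_id")["cend"].cummax()
    prev_end = cummax_end.groupby(s["person_id"]).shift()
    gap = s["cstart"] > prev_end + pd.Timedelta(days=1)
    gap &= prev_end.notna()
    agg = pd.DataFrame(
        {
            "person_id": s["person_id"],
            "first_start": s["cstart"],
            "last_end": cummax_end,
            "gap": gap,
            "t_start": s["t_start"],
            "t_end": s["t_end"],
        }
    ).groupby("person_id")
    ok = (
        (agg["first_start"].min() <= agg["t_start"].first())
        & (agg["last_end"].max() >= agg["t_end"].first())
        & ~agg["gap"].any()
    )
    result.loc[ok.index] = ok
    return result


def _year_targets(persons: pd.DataFrame, year: int, from_birth: bool) -> pd.DataFrame:
    """Coverage targets [max(1 Jan, birth), 31 Dec] of ``year`` per person.

    Persons born after the year's end get an empty (impossible) target.
    """
    start = pd.Series(pd.Timestamp(year, 1, 1), index=persons.index)
    if from_birth:
        start = start.where(
            persons["birth_date"] < start, persons["birth_date"]
        )
    return pd.DataFrame(
        {
            "person_id": persons["person_id"],
            "t_start": start,
            "t_end": pd.Timestamp(year, 12, 31),
        }
    )


def observable_full_year(spells: pd.DataFrame, person: pd.Series, year: int) -> bool:
    """Fully observable through ``year``, or from birth to 31 Dec for a
    person born during the year."""
    birth = pd.Timestamp(person["birth_date"])
    if birth > pd.Timestamp(year, 12, 31):
        return False
    own = spells[spells["person_id"] == person["person_id"]]
    target = pd.DataFrame(
        {
            "person_id": [person["person_id"]],
            "t_start": [max(pd.Timestamp(year, 1, 1), birth)],
            "t_end": [pd.Timestamp(year, 12, 31)],
        }
    )
    return bool(_covers(own, target).iloc[0])


def observable_pre_year(spells: pd.DataFrame, person: pd.Series, year: int) -> bool:
    """Fully observable through the pre-observation year (``year - 1``).

    Persons born during ``year - 1`` must be covered from birth; persons
    born during the study year itself satisfy the requirement vacuously.
    """
    birth = pd.Timestamp(person["birth_date"])
    if birth.year >= year:
        return birth.year == year  # newborn in the study year; later birth: not yet insured
    own = spells[spells["person_id"] == person["person_id"]]
    start = max(pd.Timestamp(year - 1, 1, 1), birth)
    target = pd.DataFrame(
        {
            "person_id": [person["person_id"]],
            "t_start": [start],
            "t_end": [pd.Timestamp(year - 1, 12, 31)],
        }
    )
    return bool(_covers(own, target).iloc[0])


def prior_diabetes_exclusion(
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    person: pd.Series,
    year: int,
) -> bool:
    """True (exclude) iff the person shows diabetes evidence in the four
    quarters of the pre-observation year."""
    pid = person["person_id"]
    d = diagnoses[(diagnoses["person_id"] == pid) & (diagnoses["year"] == year - 1)]
    if _qualifying_diagnosis_mask(d).any():
        return True
    p = prescriptions[
        (prescriptions["person_id"] == pid) & (prescriptions["year"] == year - 1)
    ]
    atc = p["atc"].astype(str)
    return bool((atc.str.startswith("A10A") | atc.str.startswith("A10B")).any())


def build_risk_set(
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    year: int,
) -> RiskSet:
    """Apply the four eligibility filters in flowchart order (vectorised)."""
    log: dict[str, int] = {}
    if persons.empty:
        return RiskSet(year, persons.iloc[0:0], {s: 0 for s in STAGES})

    # stage 1: insured at least one day during the year
    in_year = spells[
        (spells["start_date"] <= pd.Timestamp(year, 12, 31))
        & (spells["end_date"] >= pd.Timestamp(year, 1, 1))
    ]["person_id"].unique()
    stage = persons[persons["person_id"].isin(in_year)]
    stage = stage[stage["birth_date"] <= pd.Timestamp(year, 12, 31)]
    log["insured_in_year"] = len(stage)

    # stage 2: observable through the study year (from birth if born in it)
    ok = _covers(spells, _year_targets(stage, year, from_birth=True))
    stage = stage[stage["person_id"].map(ok).fillna(False).astype(bool)]
    log["observable_study_year"] = len(stage)

    # stage 3: observable through the pre-observation year
    born_in_year = stage["birth_date"].dt.year == year
    earlier = stage[~born_in_year]
    ok_pre = _covers(spells, _year_targets(earlier, year - 1, from_birth=True))
    keep_pre = earlier["person_id"].map(ok_pre).fillna(False).astype(bool)
    stage = pd.concat([stage[born_in_year], earlier[keep_pre]])
    stage = stage.sort_values("person_id", kind="stable")
    log["observable_pre_year"] = len(stage)

    # stage 4: no diabetes evidence in the pre-observation year
    d_pre = diagnoses[diagnoses["year"] == year - 1]
    flagged_dx = d_pre[_qualifying_diagnosis_mask(d_pre)]["person_id"].unique()
    p_pre = prescriptions[prescriptions["year"] == year - 1]
    atc = p_pre["atc"].astype(str)
    flagged_rx = p_pre[
        atc.str.startswith("A10A") | atc.str.startswith("A10B")
    ]["person_id"].unique()
    flagged = np.union1d(flagged_dx, flagged_rx)
    stage = stage[~stage["person_id"].isin(flagged)]
    log["no_prior_diabetes"] = len(stage)

    members = pd.DataFrame(
        {
            "person_id": stage["person_id"].to_numpy(),
            "sex": stage["sex"].to_numpy(),
            "age": year - stage["birth_date"].dt.year.to_numpy(),
            "district_code": stage["district_code"].to_numpy(),
        }
    ).reset_index(drop=True)
    for name, count in log.items():
        logger.info("risk set %d, %s: %d", year, name, count)
    return RiskSet(year=year, members=members, exclusion_log=log)
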