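"""Incident-case detection via the m2Q criterion.

A person in the risk set becomes an incident case in the reporting year if
either

* an inpatient **main** E10–E14 diagnosis is documented in any quarter of
  the year (immediately qualifying), or
* a confirmed outpatient or inpatient **secondary** E10–E14 diagnosis in
  quarter *q* of the year is confirmed by a further E10–E14 diagnosis
  (confirmed outpatient, inpatient secondary, or inpatient main) in one of
  the three subsequent calendar quarters *q+1 … q+3* — the window crosses
  the year boundary.

The diagnosis quarter of a case is the earliest quarter of the year that
holds any qualifying diagnosis (a confirmed index or an inpatient main),
i.e. the first documented diagnosis fixes the time of diagnosis.  The
confirming diagnosis need not repeat the same three-character code: typing
is deferred to the classifier.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import RiskSet
from .quarters import qindex, qnum, qyear

logger = logging.getLogger(__name__)

DIABETES_CODES = ("E10", "E11", "E12", "E13", "E14")

CASE_COLUMNS = ["person_id", "year", "quarter", "pathway"]


def qualifying_diagnoses(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw diagnosis records to per person-quarter flags.

    Returns one row per (person_id, t) with ``amb`` (confirmed outpatient
    or inpatient secondary — the outpatient-equivalent pool) and ``main``
    (inpatient main) indicators.  Non-diabetes codes and non-confirmed
    outpatient records are dropped.
    """
    is_dm = diagnoses["icd3"].isin(DIABETES_CODES)
    amb = is_dm & (
        ((diagnoses["setting"] == "outpatient") & (diagnoses["certainty"] == "confirmed"))
        | (diagnoses["setting"] == "inpatient_secondary")
    )
    main = is_dm & (diagnoses["setting"] == "inpatient_main")
    d = diagnoses[amb | main].copy()
    if d.empty:
        return pd.DataFrame(columns=["person_id", "t", "amb", "main"])
    d["t"] = qindex(d["year"].to_numpy(), d["quarter"].to_numpy())
    d["amb"] = amb[d.index]
    d["main"] = main[d.index]
    return (
        d.groupby(["person_id", "t"], as_index=False, observed=True)[["amb", "main"]]
        .any()
    )


def detect_incident_cases(diagnoses: pd.DataFrame, risk_set: RiskSet) -> pd.DataFrame:
    """All incident cases of the risk set's reporting year.

    Returns a DataFrame with person_id, year, quarter (first documented
    diagnosis) and pathway (``inpatient_main`` or ``m2Q``).
    """
    year = risk_set.year
    members = risk_set.members["person_id"]
    q = qualifying_diagnoses(diagnoses)
    q = q[q["person_id"].isin(members)]
    if q.empty:
        return pd.DataFrame(columns=CASE_COLUMNS)

    t_min, t_max = int(qindex(year, 1)), int(qindex(year, 4))
    in_year = q[(q["t"] >= t_min) & (q["t"] <= t_max)]

    # an amb record at t is a confirmed index iff any qualifying record
    # exists at t+1..t+3 for the same person
    pairs = in_year[in_year["amb"]][["person_id", "t"]].merge(
        q[["person_id", "t"]].rename(columns={"t": "t2"}), on="person_id"
    )
    delta = pairs["t2"] - pairs["t"]
    confirmed = pairs[(delta >= 1) & (delta <= 3)][["person_id", "t"]].drop_duplicates()
    confirmed["confirmed"] = True

    cand = in_year.merge(confirmed, on=["person_id", "t"], how="left")
    cand = cand[cand["main"] | cand["confirmed"].notna()]
    if cand.empty:
        return pd.DataFrame(columns=CASE_COLUMNS)

    cand = cand.sort_values(["person_id", "t"], kind="stable")
    first = cand.groupby("person_id", as_index=False).first()
    cases = pd.DataFrame(
        {
            "person_id": first["person_id"],
            "year": year,
            "quarter": qnum(first["t"].to_numpy()),
            "pathway": np.where(first["main"], "inpatient_main", "m2Q"),
        }
    )
    logger.info("year %d: %d incident cases detected", year, len(cases))
    return cases.reset_index(drop=True)


def detect_incident(
    diagnoses: pd.DataFrame, person: pd.Series, year: int
) -> dict | None:
    """Single-person view of :func:`detect_incident_cases`.

    Returns ``{"person_id", "year", "quarter", "pathway"}`` or ``None``.
    The caller is responsible for the person being a risk-set member.
    """
    pid = person["person_id"] if hasattr(person, "__getitem__") else person
    members = pd.DataFrame(
        {"person_id": [pid], "sex": "unknown", "age": 0, "district_code": ""}
    )
    cases = detect_incident_cases(
        diagnoses[diagnoses["person_id"] == pid],
        RiskSet(year=year, members=members),
    )
    if cases.empty:
        return None
    row = cases.iloc[0]
    return {
        "person_id": row["person_id"],
        "year": int(row["year"]),
        "quarter": int(row["quarter"]),
        "pathway": row["pathway"],
    }
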