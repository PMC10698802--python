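"""Rule-based differentiation of diabetes type from claims profiles.

Each incident case is summarised as a count profile over the
classification window — the diagnosis quarter plus the three subsequent
quarters, aligned with the m2Q confirmation window and the stated
medication window.  Per three-character code E10–E14 the profile carries
an ``amb`` count (confirmed outpatient plus inpatient secondary
diagnoses) and a ``stat`` count (inpatient main diagnoses), alongside
insulin (A10A) and non-insulin anti-diabetic (A10B) prescription counts
and the person's age.

The decision list has six type 1 cases and ten type 2 cases; a profile
matching none is "other" diabetes (which subsumes e.g. gestational and
secondary forms).  Type 1 cases take precedence over type 2 cases.  A
separate flag marks type 2 cases with at least one A10 prescription in
the window (medicated type 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quarters import qindex

PROFILE_FIELDS = [
    "e10_amb",
    "e10_stat",
    "e11_amb",
    "e11_stat",
    "e12_amb",
    "e12_stat",
    "e13_amb",
    "e13_stat",
    "e14_amb",
    "e14_stat",
    "a10a",
    "a10b",
    "age",
]

WINDOW_QUARTERS = 3  # diagnosis quarter + three subsequent quarters


def _t1_cases(p):
    """The six type 1 rules; ``p`` maps profile fields to scalars/arrays."""
    e10a, e10s = p["e10_amb"], p["e10_stat"]
    e11a, e11s = p["e11_amb"], p["e11_stat"]
    a10a, a10b, age = p["a10a"], p["a10b"], p["age"]
    return [
        # Case 1
        ((e10a >= 2) | (e10s >= 1))
        & (e11a == 0) & (e11s == 0) & (a10a >= 1) & (a10b == 0),
        # Case 2
        (e10s >= 1) & (e11a == 0) & (e11s == 0) & (a10a == 0) & (a10b == 0),
        # Case 3
        (e10a == 1) & (e11a == 0) & (e11s == 0) & (a10a >= 1) & (a10b == 0),
        # Case 4
        (e10s >= 1) & (e11a >= 1) & (e11s == 0) & (a10a >= 1) & (a10b == 0),
        # Case 5 (age-conditioned)
        (e10a >= 1) & (e11a >= 1) & (a10a >= 1) & (a10b == 0)
        & ((age < 20) | (e10a > e11a)),
        # Case 6
        (e10s >= 2) & (e11s == 1) & (a10a >= 1) & (a10b == 0),
    ]


def _t2_cases(p):
    """The ten type 2 rules."""
    e10a, e10s = p["e10_amb"], p["e10_stat"]
    e11a, e11s = p["e11_amb"], p["e11_stat"]
    e12a, e12s = p["e12_amb"], p["e12_stat"]
    e13a, e13s = p["e13_amb"], p["e13_stat"]
    e14a, e14s = p["e14_amb"], p["e14_stat"]
    a10a, a10b, age = p["a10a"], p["a10b"], p["age"]
    return [
        # Case 1
        ((e11a >= 2) | (e11s >= 1)) & (e10a == 0) & (e10s == 0),
        # Case 2
        ((e11a >= 1) | (e11s >= 1)) & (a10b >= 1),
        # Case 3
        ((e11a >= 1) | (e11s >= 1)) & (e10s == 0) & (a10a == 0),
        # Case 4
        (e11a == 1) & (e10a == 0) & (e10s == 0) & (e13a == 0) & (e13s == 0)
        & (a10a >= 1) & (a10b == 0),
        # Case 5
        (e11a >= 1) & (e11s >= 1) & (a10a == 0),
        # Case 6
        ((e12a >= 1) | (e14a >= 1)) & (a10b >= 1),
        # Case 7
        ((e12a >= 1) | (e14a >= 1)) & (e10s == 0) & (a10a == 0) & (a10b == 0),
        # Case 8
        ((e11a >= 2) | (e11s >= 1)) & (e10a >= 1) & (e10s == 0) & (a10a == 0),
        # Case 9 (E12/E14 pooled per setting)
        (e11a == 0) & (e11s == 0) & (e10a == 0) & (e10s == 0)
        & (e13a == 0) & (e13s == 0)
        & ((e12a + e14a >= 1) | (e12s + e14s >= 1)) & (a10b >= 1),
        # Case 10 (age-conditioned complement of type 1 case 5)
        (e11a >= 1) & (e10a >= 1) & (a10a >= 1) & (a10b == 0)
        & (age >= 20) & (e11a > e10a),
    ]


def classify_arrays(p: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorised classification; type 1 rules take precedence."""
    t1 = np.logical_or.reduce(_t1_cases(p))
    t2 = np.logical_or.reduce(_t2_cases(p))
    return np.select([t1, t2], ["type1", "type2"], default="other")


def classify(profile) -> str:
    """Label one profile (mapping or Series over PROFILE_FIELDS)."""
    p = {f: np.asarray(profile[f]) for f in PROFILE_FIELDS}
    return str(classify_arrays(p).item())


def rule_matches(p: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean case-hit matrices (profiles x cases) for both rule families."""
    shape = np.broadcast_shapes(*(np.shape(v) for v in p.values()))
    t1 = np.stack([np.broadcast_to(c, shape) for c in _t1_cases(p)], axis=-1)
    t2 = np.stack([np.broadcast_to(c, shape) for c in _t2_cases(p)], axis=-1)
    return t1, t2


def _window_counts(
    records: pd.DataFrame, cases: pd.DataFrame, value_col: str
) -> pd.DataFrame:
    """Count records per case within [first_quarter, first_quarter + 3]."""
    r = records.merge(cases[["person_id", "t0"]], on="person_id")
    t = qindex(r["year"].to_numpy(), r["quarter"].to_numpy())
    r = r[(t >= r["t0"]) & (t <= r["t0"] + WINDOW_QUARTERS)]
    return (
        r.groupby(["person_id", value_col], observed=True)
        .size()
        .unstack(fill_value=0)
    )


def build_profiles(
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    cases: pd.DataFrame,
    ages: pd.Series | None = None,
) -> pd.DataFrame:
    """Diagnosis/prescription count profiles for a table of cases.

    ``cases`` needs person_id, year, quarter (the diagnosis quarter) and —
    unless ``ages`` (indexed by person_id) is given — an ``age`` column.
    Counts pool confirmed outpatient and inpatient secondary records as
    ``amb`` and inpatient main records as ``stat``, within the diagnosis
    quarter plus three subsequent quarters.
    """
    out = cases[["person_id", "year", "quarter"]].copy()
    out["t0"] = qindex(out["year"].to_numpy(), out["quarter"].to_numpy())

    is_dm = diagnoses["icd3"].isin(["E10", "E11", "E12", "E13", "E14"])
    amb = is_dm & (
        ((diagnoses["setting"] == "outpatient") & (diagnoses["certainty"] == "confirmed"))
        | (diagnoses["setting"] == "inpatient_secondary")
    )
    stat = is_dm & (diagnoses["setting"] == "inpatient_main")
    d = diagnoses[amb | stat].copy()
    d["bucket"] = np.where(
        amb[d.index], d["icd3"].str.lower() + "_amb", d["icd3"].str.lower() + "_stat"
    )
    dx_counts = _window_counts(d, out, "bucket") if len(d) else pd.DataFrame()

    rx = prescriptions.copy()
    atc = rx["atc"].astype(str)
    rx["bucket"] = np.where(
        atc.str.startswith("A10A"),
        "a10a",
        np.where(atc.str.startswith("A10B"), "a10b", "other"),
    )
    rx = rx[rx["bucket"] != "other"]
    rx_counts = _window_counts(rx, out, "bucket") if len(rx) else pd.DataFrame()

    profiles = out[["person_id"]].copy()
    for field in PROFILE_FIELDS[:-1]:
        source = rx_counts if field in ("a10a", "a10b") else dx_counts
        if len(source) and field in source.columns:
            profiles[field] = (
                out["person_id"].map(source[field]).fillna(0).astype(int).to_numpy()
            )
        else:
            profiles[field] = 0
    if ages is not None:
        profiles["age"] = out["person_id"].map(ages).to_numpy()
    else:
        profiles["age"] = cases["age"].to_numpy()
    return profiles


def build_profile(
    diagnoses: pd.DataFrame, prescriptions: pd.DataFrame, case
) -> pd.Series:
    """Profile of a single incident case (mapping with person_id, year,
    quarter and age)."""
    cases = pd.DataFrame([{k: case[k] for k in ("person_id", "year", "quarter", "age")}])
    pid = case["person_id"]
    profiles = build_profiles(
        diagnoses[diagnoses["person_id"] == pid],
        prescriptions[prescriptions["person_id"] == pid],
        cases,
    )
    return profiles.iloc[0]


def is_medicated_t2(prescriptions: pd.DataFrame, case) -> bool:
    """At least one A10 prescription in the diagnosis quarter or the three
    subsequent quarters; only defined for type 2 cases."""
    if case.get("diabetes_type") != "type2":
        raise ValueError("is_medicated_t2 is only defined for type 2 cases")
    t0 = int(qindex(case["year"], case["quarter"]))
    p = prescriptions[prescriptions["person_id"] == case["person_id"]]
    t = qindex(p["year"].to_numpy(), p["quarter"].to_numpy())
    in_window = (t >= t0) & (t <= t0 + WINDOW_QUARTERS)
    return bool(p["atc"].astype(str).str.startswith("A10")[in_window].any())


def classify_cases(
    cases: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    ages: pd.Series,
) -> pd.DataFrame:
    """Annotate detected cases with ``diabetes_type`` and ``medicated``.

    ``ages`` is a person_id-indexed Series of completed years on 31 Dec of
    the reporting year (the cohort age convention).  ``medicated`` is the
    medicated-type-2 flag: True only for type 2 cases with an A10
    prescription in the diagnosis quarter or three subsequent quarters.
    """
    out = cases.copy()
    if out.empty:
        out["diabetes_type"] = pd.Series(dtype=str)
        out["medicated"] = pd.Series(dtype=bool)
        return out
    profiles = build_profiles(diagnoses, prescriptions, out, ages=ages)
    p = {f: profiles[f].to_numpy() for f in PROFILE_FIELDS}
    out["diabetes_type"] = classify_arrays(p)

    t0 = qindex(out["year"].to_numpy(), out["quarter"].to_numpy())
    rx = prescriptions[prescriptions["atc"].astype(str).str.startswith("A10")]
    rx = rx.merge(
        pd.DataFrame({"person_id": out["person_id"], "t0": t0}), on="person_id"
    )
    t = qindex(rx["year"].to_numpy(), rx["quarter"].to_numpy())
    rx = rx[(t >= rx["t0"]) & (t <= rx["t0"] + WINDOW_QUARTERS)]
    has_rx = out["person_id"].isin(rx["person_id"].unique())
    out["medicated"] = (out["diabetes_type"] == "type2") & has_rx
    return out
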