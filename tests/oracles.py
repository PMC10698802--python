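"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np
import pandas as pd

DIABETES = {"E10", "E11", "E12", "E13", "E14"}


def brute_force_m2q(diagnoses: pd.DataFrame, year: int):
    """Enumerate every (index, confirmation) quarter pair explicitly.

    Independent re-statement of the m2Q criterion: scans all quarter pairs
    (q_index, q_confirm) with q_index < q_confirm <= q_index + 3, plus the
    immediately qualifying inpatient-main pathway.  Returns
    (quarter_in_year, pathway) or None.
    """
    amb_t, main_t = set(), set()
    for _, row in diagnoses.iterrows():
        if row["icd3"] not in DIABETES:
            continue
        t = row["year"] * 4 + row["quarter"] - 1
        if row["setting"] == "inpatient_main":
            main_t.add(t)
        elif row["setting"] == "inpatient_secondary":
            amb_t.add(t)
        elif row["setting"] == "outpatient" and row["certainty"] == "confirmed":
            amb_t.add(t)
    year_ts = range(year * 4, year * 4 + 4)
    qualifying = {t for t in main_t if t in year_ts}
    all_t = amb_t | main_t
    for t in amb_t:
        if t not in year_ts:
            continue
        for t2 in all_t:
            if t < t2 <= t + 3:
                qualifying.add(t)
                break
    if not qualifying:
        return None
    first = min(qualifying)
    pathway = "inpatient_main" if first in main_t else "m2Q"
    return first % 4 + 1, pathway


def random_record_set(rng: np.random.Generator, year: int = 2020) -> pd.DataFrame:
    """A small random diagnosis history spanning the year and its margins."""
    n = int(rng.integers(0, 7))
    ts = rng.integers(year * 4 - 3, year * 4 + 7, n)  # prior-year Q2 .. next-year Q3
    settings = rng.choice(
        ["outpatient", "outpatient", "inpatient_main", "inpatient_secondary"], n
    )
    certainty = rng.choice(["confirmed", "confirmed", "confirmed", "suspected"], n)
    codes = rng.choice(["E10", "E11", "E13", "E14", "I10"], n)
    return pd.DataFrame(
        {
            "person_id": 1,
            "icd3": codes,
            "setting": settings,
            "certainty": np.where(
                settings == "outpatient", certainty, "confirmed"
            ),
            "year": ts // 4,
            "quarter": ts % 4 + 1,
        }
    )
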