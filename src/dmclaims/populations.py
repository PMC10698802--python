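"""Synthetic reference and standard population tables.

The real analysis extrapolates to the German population as of 31 Dec of
the reporting year and standardises to the population as of 31 Dec 2021
(Federal Statistical Office tables).  Those tables are not shipped here:
this module constructs a synthetic Destatis-like table — a smooth national
age pyramid at national scale (~83 million) — that can be swapped for the
real counts by supplying any CSV with age, sex, count columns.
"""

from __future__ import annotations

import pandas as pd

from .config import DEFAULT_AGE_SEX_STRUCTURE


def synthetic_reference_population(
    year: int, total: float | None = None
) -> pd.DataFrame:
    """Destatis-like national population by 1-year age and sex (synthetic).

    Totals drift from ~82.2 M in 2015 by +150 k per year; proportions follow
    the default insured-population age/sex structure, uniform within bands.

    Returns a DataFrame with columns age, sex, count and attrs
    ``reference_date`` (31 Dec of ``year``) and ``source``.
    """
    if total is None:
        total = 82_200_000 + 150_000 * (year - 2015)
    rows = []
    for band in DEFAULT_AGE_SEX_STRUCTURE:
        span = band.age_max - band.age_min + 1
        for age in range(band.age_min, band.age_max + 1):
            rows.append((age, "female", band.female / span * total))
            rows.append((age, "male", band.male / span * total))
    table = pd.DataFrame(rows, columns=["age", "sex", "count"])
    table = table.sort_values(["age", "sex"]).reset_index(drop=True)
    table.attrs["reference_date"] = f"{year}-12-31"
    table.attrs["source"] = "synthetic-destatis-like"
    return table


def load_population_table(path) -> pd.DataFrame:
    """Read an age x sex population CSV (columns: age, sex, count)."""
    table = pd.read_csv(path)
    required = {"age", "sex", "count"}
    if not required.issubset(table.columns):
        raise ValueError(f"population table needs columns {sorted(required)}")
    if (table["count"] < 0).any():
        raise ValueError("population counts must be non-negative")
    return table[["age", "sex", "count"]]
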