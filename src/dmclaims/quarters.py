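"""Calendar-quarter arithmetic.

Every analytic rule in the pipeline (pre-observation exclusion, m2Q
confirmation, classification window, quarterly stratification) operates on
calendar quarters, so quarters are represented by a single integer index
``t = 4*year + (quarter - 1)``.  CSV files carry quarters as ``"YYYYQn"``.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


def qindex(year, quarter):
    """Absolute quarter index; accepts scalars or arrays."""
    return np.asarray(year) * 4 + (np.asarray(quarter) - 1)


def qyear(t):
    """Reporting year of an absolute quarter index."""
    return np.asarray(t) // 4


def qnum(t):
    """Quarter number 1..4 of an absolute quarter index."""
    return np.asarray(t) % 4 + 1


def qlabel(year: int, quarter: int) -> str:
    return f"{year}Q{quarter}"


def parse_qlabel(label: str) -> tuple[int, int]:
    m = _QUARTER_RE.match(str(label))
    if not m:
        raise ValueError(f"not a quarter label (expected YYYYQn): {label!r}")
    return int(m.group(1)), int(m.group(2))


def quarter_start(year, quarter) -> pd.Timestamp:
    return pd.Timestamp(year=int(year), month=3 * (int(quarter) - 1) + 1, day=1)


def series_to_labels(year: pd.Series, quarter: pd.Series) -> pd.Series:
    return year.astype(str) + "Q" + quarter.astype(str)


def labels_to_series(labels: pd.Series) -> pd.DataFrame:
    """Split a ``YYYYQn`` column into integer ``year``/``quarter`` columns."""
    s = labels.astype(str)
    bad = ~s.str.match(_QUARTER_RE)
    if bad.any():
        raise ValueError(f"malformed quarter labels, e.g. {s[bad].iloc[0]!r}")
    return pd.DataFrame(
        {"year": s.str[:4].astype(int), "quarter": s.str[5].astype(int)},
        index=labels.index,
    )
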