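"""CSV round-tripping of the claims tables.

All tables are UTF-8 headered CSV with ISO-8601 dates; quarters travel as
``YYYYQn`` labels and are split back into integer year/quarter columns on
read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .quarters import labels_to_series, series_to_labels

TABLES = ("persons", "spells", "diagnoses", "prescriptions", "districts")
_QUARTERED = ("diagnoses", "prescriptions", "onsets", "cases")
_DATED = {"persons": ["birth_date"], "spells": ["start_date", "end_date"]}


def _serialise(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if name in _QUARTERED and {"year", "quarter"}.issubset(out.columns):
        out["quarter"] = series_to_labels(out["year"], out["quarter"])
        out = out.drop(columns=["year"])
    for col in _DATED.get(name, []):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    return out


def _deserialise(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if name in _QUARTERED and "quarter" in out.columns and len(out):
        yq = labels_to_series(out["quarter"])
        out["year"] = yq["year"]
        out["quarter"] = yq["quarter"]
    elif name in _QUARTERED and "quarter" in out.columns:
        out["year"] = pd.Series(dtype=int)
        out["quarter"] = pd.Series(dtype=int)
    for col in _DATED.get(name, []):
        out[col] = pd.to_datetime(out[col])
    return out


def write_table(out_dir, name: str, df: pd.DataFrame) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.csv"
    _serialise(name, df).to_csv(path, index=False)
    return path


def read_table(in_dir, name: str) -> pd.DataFrame:
    path = Path(in_dir) / f"{name}.csv"
    return _deserialise(name, pd.read_csv(path))


def write_claims(out_dir, data) -> list[Path]:
    """Write the five claims tables (and latent onsets) of a simulation."""
    paths = [write_table(out_dir, name, getattr(data, name)) for name in TABLES]
    paths.append(write_table(out_dir, "onsets", data.onsets))
    return paths


def read_claims(in_dir) -> dict[str, pd.DataFrame]:
    tables = {name: read_table(in_dir, name) for name in TABLES}
    onsets = Path(in_dir) / "onsets.csv"
    if onsets.exists():
        tables["onsets"] = read_table(in_dir, "onsets")
    return tables
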