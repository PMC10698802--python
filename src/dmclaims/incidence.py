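"""Incidence estimation: crude, stratified, age-standardised, extrapolated.

The incidence in a reporting year is the number of newly diagnosed persons
divided by the number of persons at risk in that year (whole-year member
counts, not person-time).  95 % confidence intervals assume a binomial
numerator and use the Clopper–Pearson exact interval, which stays valid in
the small pediatric type 1 strata.  Direct age-standardisation reweights
1-year age x sex cell rates by a standard population; extrapolation scales
sample case counts to a national reference population cell by cell.
Quarterly strata keep the full-year risk set as denominator, since the
denominator is defined as all persons at risk in the year.

Type 1 rates are conventionally reported per 100,000 persons and type 2
rates in percent; computation is on the proportion scale throughout.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# reporting age-group schemes, (lower, upper) completed years inclusive
T1_AGE_GROUPS: list[tuple[int, int]] = [
    (0, 6), (7, 10), (11, 13), (14, 17), (18, 34), (35, 49), (50, 120),
]
T2_AGE_GROUPS: list[tuple[int, int]] = [
    (0, 17), (18, 34), (35, 49), (50, 64), (65, 79), (80, 120),
]
# collapsed variants used when case counts are low
T1_AGE_GROUPS_COLLAPSED = [(0, 17), (18, 120)]
T2_AGE_GROUPS_COLLAPSED = [(0, 34), (35, 49), (50, 64), (65, 120)]

SCALES = {"proportion": 1.0, "per100k": 1e5, "percent": 100.0}


def check_age_groups(groups: Sequence[tuple[int, int]]) -> None:
    """Age groups must be contiguous, non-overlapping and exhaustive."""
    expected_lo = 0
    for lo, hi in groups:
        if lo != expected_lo or hi < lo:
            raise ValueError(f"age groups not contiguous at ({lo}, {hi})")
        expected_lo = hi + 1
    if groups[-1][1] < 120:
        raise ValueError("age groups must cover ages up to 120")


def group_label(lo: int, hi: int) -> str:
    if lo == 0:
        return f"<{hi + 1}"
    if hi >= 120:
        return f">={lo}"
    return f"{lo}-{hi}"


def assign_age_group(ages, groups: Sequence[tuple[int, int]]) -> pd.Series:
    ages = pd.Series(ages)
    bins = [g[0] for g in groups] + [groups[-1][1] + 1]
    labels = [group_label(lo, hi) for lo, hi in groups]
    return pd.cut(ages, bins=bins, labels=labels, right=False, include_lowest=True)


def binomial_ci(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper–Pearson exact interval on the proportion scale.

    ``low`` is 0 when x = 0 and ``high`` is 1 when x = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _binomial_ci_arrays(x: np.ndarray, n: np.ndarray, alpha: float):
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        low = np.where(x == 0, 0.0, stats.beta.ppf(alpha / 2, x, n - x + 1))
        high = np.where(x == n, 1.0, stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def crude_incidence(
    cases: pd.DataFrame,
    risk_set,
    strata: Iterable[str] = (),
    scale: str = "per100k",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Crude incidence per stratum.

    ``strata`` may contain case-level columns (``diabetes_type``,
    ``quarter``, ``medicated``) and member-level columns (``sex``,
    ``age_group``, ``deprivation``).  Member-level strata split the
    denominator; case-level strata (type, quarter) share the stratum's
    full-year denominator.  Cases must be a subset of the risk set.
    """
    members = risk_set.members if hasattr(risk_set, "members") else risk_set
    factor = SCALES[scale]
    strata = list(strata)
    member_cols = [c for c in strata if c in members.columns]
    case_cols = [c for c in strata if c not in member_cols]
    missing = [c for c in case_cols if c not in cases.columns]
    if missing:
        raise KeyError(f"strata not found in cases or members: {missing}")
    if not cases.empty and not cases["person_id"].isin(members["person_id"]).all():
        raise ValueError("cases must be members of the risk set")

    c = cases
    if member_cols:
        c = c.merge(
            members[["person_id", *member_cols]], on="person_id",
            how="left", suffixes=("", "_m"),
        )

    if member_cols:
        denom = (
            members.groupby(member_cols, observed=False)
            .size()
            .rename("denominator")
            .reset_index()
        )
    else:
        denom = pd.DataFrame({"denominator": [len(members)]})

    if member_cols or case_cols:
        num = (
            c.groupby(member_cols + case_cols, observed=False)
            .size()
            .rename("numerator")
            .reset_index()
        )
    else:
        num = pd.DataFrame({"numerator": [len(c)]})

    if member_cols:
        # keep member strata without cases; case-level combos come from num
        out = num.merge(denom, on=member_cols, how="outer")
    elif case_cols:
        out = num.assign(denominator=len(members))
    else:
        out = pd.concat([num, denom], axis=1)
    out["numerator"] = out["numerator"].fillna(0).astype(int)
    out["denominator"] = out["denominator"].fillna(0).astype(int)

    bad = (out["denominator"] == 0) & (out["numerator"] > 0)
    if bad.any():
        raise ValueError("stratum with cases but an empty denominator")
    empty = out["denominator"] == 0
    if empty.any():
        logger.warning("%d empty strata flagged (rate undefined)", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = out["numerator"] / out["denominator"]
    low, high = _binomial_ci_arrays(
        out["numerator"].to_numpy(),
        np.where(empty, 1, out["denominator"].to_numpy()),
        alpha,
    )
    out["rate"] = np.where(empty, np.nan, p * factor)
    out["ci_low"] = np.where(empty, np.nan, low * factor)
    out["ci_high"] = np.where(empty, np.nan, high * factor)
    out["standardised"] = False
    return out.drop(columns=["_overall"], errors="ignore")


def cell_estimates(cases: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Case and member counts per 1-year age x sex cell."""
    denom = members.groupby(["age", "sex"], observed=True).size().rename("n")
    c = cases.merge(members[["person_id", "age", "sex"]], on="person_id", how="inner")
    num = c.groupby(["age", "sex"], observed=True).size().rename("x")
    out = denom.to_frame().join(num, how="left").fillna({"x": 0}).reset_index()
    out["x"] = out["x"].astype(int)
    return out


def standardise(
    cells: pd.DataFrame,
    standard: pd.DataFrame,
    age_groups: Sequence[tuple[int, int]] | None = None,
    scale: str = "per100k",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Directly age-standardised rates from 1-year cell estimates.

    ``cells`` has columns age, sex, x (cases), n (members); ``standard``
    has columns age, sex, count.  The standard population is subdivided by
    1-year age groups and the weights summed within each reporting age
    group; cells with standard weight but no sample members are reweighted
    to zero with a warning.  Output has one row per sex per age group,
    plus all-ages rows per sex and an age- and sex-standardised total.
    The CI combines cell-level binomial variances under the same weights
    (normal approximation, truncated to the unit interval).
    """
    factor = SCALES[scale]
    z = stats.norm.ppf(1 - alpha / 2)
    if age_groups is not None:
        check_age_groups(age_groups)
    merged = standard.merge(cells, on=["age", "sex"], how="left")
    orphan = merged["n"].isna() & (merged["count"] > 0)
    if orphan.any():
        logger.warning(
            "%d standard-population cells without sample members reweighted to 0",
            int(orphan.sum()),
        )
    merged = merged[~merged["n"].isna() & (merged["n"] > 0)].copy()
    merged["r"] = merged["x"] / merged["n"]
    merged["var"] = merged["r"] * (1 - merged["r"]) / merged["n"]

    def _combine(g: pd.DataFrame) -> pd.Series:
        w = g["count"].to_numpy(dtype=float)
        total = w.sum()
        if total == 0:
            return pd.Series({"rate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                              "numerator": 0, "denominator": 0})
        w = w / total
        rate = float((w * g["r"]).sum())
        se = float(np.sqrt((w**2 * g["var"]).sum()))
        return pd.Series(
            {
                "rate": rate * factor,
                "ci_low": max(rate - z * se, 0.0) * factor,
                "ci_high": min(rate + z * se, 1.0) * factor,
                "numerator": int(g["x"].sum()),
                "denominator": int(g["n"].sum()),
            }
        )

    rows = []
    if age_groups is not None:
        merged["age_group"] = assign_age_group(merged["age"], age_groups)
        by_group = (
            merged.groupby(["sex", "age_group"], observed=True)
            .apply(_combine, include_groups=False)
            .reset_index()
        )
        rows.append(by_group)
    for sex, g in merged.groupby("sex", observed=True):
        rows.append(pd.DataFrame([{"sex": sex, "age_group": "all", **_combine(g)}]))
    rows.append(pd.DataFrame([{"sex": "total", "age_group": "all", **_combine(merged)}]))
    out = pd.concat(rows, ignore_index=True)
    out["standardised"] = True
    return out


def extrapolate(
    cases: pd.DataFrame, members: pd.DataFrame, reference: pd.DataFrame
) -> dict[str, float]:
    """Extrapolated case counts: sample counts scaled to the reference
    population cell by cell (1-year age x sex).

    Reference cells without sample members contribute 0 with a warning.
    Returns ``{"female": ..., "male": ..., "total": ...}``.
    """
    cells = cell_estimates(cases, members)
    merged = reference.merge(cells, on=["age", "sex"], how="left")
    uncovered = (merged["n"].isna() | (merged["n"] == 0)) & (merged["count"] > 0)
    if uncovered.any():
        logger.warning(
            "%d reference cells without sample members contribute 0",
            int(uncovered.sum()),
        )
    merged = merged[~merged["n"].isna() & (merged["n"] > 0)]
    contrib = merged["x"] * merged["count"] / merged["n"]
    by_sex = contrib.groupby(merged["sex"], observed=True).sum()
    result = {sex: float(by_sex.get(sex, 0.0)) for sex in ("female", "male")}
    return aggregate_sexes(result)


def aggregate_sexes(estimates: dict[str, float]) -> dict[str, float]:
    """Add the two sex strata into a total (women + men, exactly)."""
    for key in ("female", "male"):
        if key not in estimates:
            raise KeyError(f"missing sex stratum: {key}")
    out = dict(estimates)
    out["total"] = out["female"] + out["male"]
    return out
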