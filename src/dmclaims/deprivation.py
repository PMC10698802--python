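"""District-level socioeconomic deprivation linkage.

Districts carry a GISD-like composite deprivation score (higher = more
deprived).  For analysis they are collapsed into three categories covering
20 % / 60 % / 20 % of *districts* (not population): the fifth of districts
with the lowest scores is "low", the fifth with the highest scores "high",
the remainder "medium".  On counts not divisible by five, the remainder
goes to the medium category so the extremes keep their definition as the
most and least deprived 20 %.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ["low", "medium", "high"]


def categorize_districts(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each district to a deprivation category.

    Parameters
    ----------
    scores : DataFrame with columns ``district_code`` and ``score``.

    Returns
    -------
    DataFrame with columns ``district_code``, ``score``, ``category``.
    Districts are ranked ascending by score; ties are broken by
    lexicographic district code so the split is reproducible.
    """
    df = scores[["district_code", "score"]].copy()
    if df["district_code"].duplicated().any():
        dupes = df.loc[df["district_code"].duplicated(), "district_code"].tolist()
        raise ValueError(f"duplicate district codes: {dupes}")
    missing = df["score"].isna()
    if missing.any():
        logger.warning("dropping %d districts without a score", int(missing.sum()))
        df = df[~missing]
    n = len(df)
    if n < 5:
        raise ValueError(f"need at least 5 scored districts, got {n}")
    df = df.sort_values(
        ["score", "district_code"], kind="stable"
    ).reset_index(drop=True)
    n_tail = n // 5  # floor(20 %); remainder stays medium
    category = pd.Series("medium", index=df.index)
    category.iloc[:n_tail] = "low"
    category.iloc[n - n_tail :] = "high"
    df["category"] = pd.Categorical(category, categories=CATEGORIES, ordered=True)
    return df.sort_values("district_code", kind="stable").reset_index(drop=True)


def link_person_category(
    persons: pd.DataFrame, districts: pd.DataFrame
) -> pd.DataFrame:
    """Map persons to deprivation categories via their district of residence.

    Persons whose district code is absent from the categorised table get a
    missing category; they are meant to be dropped from deprivation-
    stratified outputs only, never from overall estimates.
    """
    out = persons[["person_id", "district_code"]].merge(
        districts[["district_code", "category"]], on="district_code", how="left"
    )
    n_unmatched = int(out["category"].isna().sum())
    if n_unmatched:
        logger.warning(
            "%d persons in unknown districts excluded from deprivation strata",
            n_unmatched,
        )
    return out[["person_id", "category"]]
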