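"""Crude, standardised and extrapolated incidence with exact binomial CIs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from dmclaims.incidence import (
    T1_AGE_GROUPS,
    T2_AGE_GROUPS,
    aggregate_sexes,
    assign_age_group,
    binomial_ci,
    cell_estimates,
    check_age_groups,
    crude_incidence,
    extrapolate,
    standardise,
)


class TestBinomialCI:
    def test_zero_count_lower_bound(self):
        low, high = binomial_ci(0, 100)
        assert low == 0.0 and 0 < high < 0.05

    def test_full_count_upper_bound(self):
        low, high = binomial_ci(100, 100)
        assert high == 1.0 and low > 0.95

    def test_matches_independent_beta_quantiles(self):
        """Clopper-Pearson against statsmodels' beta-quantile implementation."""
        for x, n in [(50, 1000), (1, 20), (7, 7), (0, 5), (123, 456)]:
            low, high = binomial_ci(x, n)
            exp_low, exp_high = proportion_confint(x, n, alpha=0.05, method="beta")
            assert low == pytest.approx(exp_low, abs=1e-10)
            assert high == pytest.approx(exp_high, abs=1e-10)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 0)
        with pytest.raises(ValueError):
            binomial_ci(6, 5)


def tiny_risk_set(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "sex": rng.choice(["female", "male"], n),
            "age": rng.integers(0, 90, n),
            "district_code": "D00",
        }
    )


def test_one_case_per_hundred_thousand():
    members = tiny_risk_set(100_000)
    cases = pd.DataFrame({"person_id": [17], "year": 2020, "quarter": 1})
    out = crude_incidence(cases, members, scale="per100k")
    assert out["rate"].iloc[0] == pytest.approx(1.0)
    assert out["numerator"].iloc[0] == 1

    zero = crude_incidence(cases.iloc[0:0], members, scale="per100k")
    assert zero["rate"].iloc[0] == 0.0 and zero["ci_low"].iloc[0] == 0.0


def test_quarterly_numerators_sum_to_annual(noisy_run):
    _, _, risk_sets, cases = noisy_run
    for year, rs in risk_sets.items():
        year_cases = cases[cases["year"] == year]
        quarterly = crude_incidence(year_cases, rs, strata=["quarter"])
        annual = crude_incidence(year_cases, rs)
        assert quarterly["numerator"].sum() == annual["numerator"].iloc[0]
        assert (quarterly["denominator"] == len(rs.members)).all()


def test_type_and_sex_conservation(noisy_run):
    _, _, risk_sets, cases = noisy_run
    for year, rs in risk_sets.items():
        year_cases = cases[cases["year"] == year]
        by_type = crude_incidence(year_cases, rs, strata=["diabetes_type"])
        assert by_type["numerator"].sum() == len(year_cases)
        by_sex = crude_incidence(year_cases, rs, strata=["sex"])
        assert by_sex["numerator"].sum() == len(year_cases)
        assert by_sex["denominator"].sum() == len(rs.members)


def test_cases_outside_risk_set_rejected():
    members = tiny_risk_set(10)
    cases = pd.DataFrame({"person_id": [999], "year": 2020, "quarter": 1})
    with pytest.raises(ValueError):
        crude_incidence(cases, members)


def cells_from(rows):
    return pd.DataFrame(rows, columns=["age", "sex", "x", "n"])


def std_from(rows):
    return pd.DataFrame(rows, columns=["age", "sex", "count"])


class TestStandardise:
    def test_equal_rates_invariant_under_any_weights(self):
        cells = cells_from([(a, "female", a % 3 + 1, 10_000) for a in range(10)])
        cells["x"] = 20  # uniform rate 0.002
        std = std_from([(a, "female", (a + 1) * 1000) for a in range(10)])
        out = standardise(cells, std, scale="proportion")
        total = out[(out["sex"] == "total")]
        assert total["rate"].iloc[0] == pytest.approx(0.002)

    def test_two_cell_hand_arithmetic(self):
        # rates 10 and 30 per 100,000, standard weights 0.25/0.75 -> 25
        cells = cells_from(
            [(40, "male", 10, 100_000), (41, "male", 30, 100_000)]
        )
        std = std_from([(40, "male", 250), (41, "male", 750)])
        out = standardise(cells, std, scale="per100k")
        assert out[out["sex"] == "total"]["rate"].iloc[0] == pytest.approx(25.0)

    def test_uniform_standard_gives_plain_mean(self):
        cells = cells_from(
            [(50, "female", 5, 1000), (51, "female", 15, 1000), (52, "female", 10, 1000)]
        )
        std = std_from([(50, "female", 7), (51, "female", 7), (52, "female", 7)])
        out = standardise(cells, std, scale="proportion")
        assert out[out["sex"] == "total"]["rate"].iloc[0] == pytest.approx(0.01)

    def test_rate_bounded_by_cell_rates(self, noisy_run):
        _, _, risk_sets, cases = noisy_run
        rs = risk_sets[2019]
        sub = cases[(cases["year"] == 2019) & (cases["diabetes_type"] == "type2")]
        cells = cell_estimates(sub, rs.members)
        from dmclaims.populations import synthetic_reference_population

        std = synthetic_reference_population(2020)
        out = standardise(cells, std, age_groups=T2_AGE_GROUPS, scale="proportion")
        rates = cells["x"] / cells["n"]
        total = out[(out["sex"] == "total") & (out["age_group"] == "all")]
        assert rates.min() <= total["rate"].iloc[0] <= rates.max()
        assert (out["ci_low"] <= out["rate"]).all()
        assert (out["rate"] <= out["ci_high"]).all()

    def test_unsampled_standard_cells_reweighted(self):
        cells = cells_from([(40, "male", 10, 100_000)])
        std = std_from([(40, "male", 500), (41, "male", 500)])
        out = standardise(cells, std, scale="per100k")
        assert out[out["sex"] == "total"]["rate"].iloc[0] == pytest.approx(10.0)


class TestExtrapolate:
    def test_identity_when_reference_equals_sample(self):
        members = tiny_risk_set(5000, seed=1)
        cases = pd.DataFrame(
            {"person_id": members["person_id"].iloc[:40], "year": 2020, "quarter": 1}
        )
        reference = (
            members.groupby(["age", "sex"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        out = extrapolate(cases, members, reference)
        assert out["total"] == pytest.approx(40.0)

    def test_homogeneous_doubling(self):
        members = tiny_risk_set(5000, seed=2)
        cases = pd.DataFrame(
            {"person_id": members["person_id"].iloc[:40], "year": 2020, "quarter": 1}
        )
        reference = (
            members.groupby(["age", "sex"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        reference["count"] *= 2
        out = extrapolate(cases, members, reference)
        assert out["total"] == pytest.approx(80.0)
        assert out["total"] == out["female"] + out["male"]


class TestAggregateSexes:
    @pytest.mark.parametrize(
        "female, male, total",
        [
            (3228.0, 3779.0, 7007.0),
            (3790.0, 4908.0, 8698.0),  # independently rounded inputs
            (257486.0, 298832.0, 556318.0),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_totals(self, female, male, total):
        assert aggregate_sexes({"female": female, "male": male})["total"] == total

    def test_missing_stratum_rejected(self):
        with pytest.raises(KeyError):
            aggregate_sexes({"female": 10.0})


def test_age_group_schemes_are_valid_partitions():
    for scheme in (T1_AGE_GROUPS, T2_AGE_GROUPS):
        check_age_groups(scheme)
    groups = assign_age_group([0, 6, 7, 17, 18, 50, 119], T1_AGE_GROUPS)
    assert list(groups.astype(str)) == ["<7", "<7", "7-10", "14-17", "18-34", ">=50", ">=50"]
    with pytest.raises(ValueError):
        check_age_groups([(0, 10), (12, 120)])
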