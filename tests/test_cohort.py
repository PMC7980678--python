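import numpy as np
import pandas as pd
import pytest

import promoscan as ps
from promoscan.errors import ConfigError, ContractError
from promoscan.cohort import quartile_sizes, size_group


@pytest.fixture()
def linkage():
    return pd.DataFrame(
        {
            "household_id": ["H0", "H1", "H2", "H3"],
            "total_oz": [100.0, 100.0, 100.0, 100.0],
            "covered_oz": [80.0, 79.0, 95.0, 60.0],
            "coverage": [0.80, 0.79, 0.95, 0.60],
        }
    )


class TestInclusion:
    def test_boundary_is_inclusive(self, linkage):
        kept = ps.apply_inclusion(linkage, 0.80)
        assert "H0" in kept and "H1" not in kept

    def test_threshold_monotonicity(self, linkage):
        loose = set(ps.apply_inclusion(linkage, 0.60))
        tight = set(ps.apply_inclusion(linkage, 0.90))
        assert tight <= loose

    def test_bad_threshold_rejected(self, linkage):
        with pytest.raises(ConfigError):
            ps.apply_inclusion(linkage, 0.0)
        with pytest.raises(ConfigError):
            ps.apply_inclusion(linkage, 1.2)


class TestOutcome:
    def test_per_capita_arithmetic(self, tiny_tables):
        tables = ps.validate_tables(tiny_tables)
        out = ps.annual_per_capita(tables["purchases"], tables["households"]).set_index(
            "household_id"
        )
        assert out.loc["H0", "annual_oz"] == pytest.approx(50.0)  # 100 oz, size 2
        assert out.loc["H1", "annual_oz"] == pytest.approx(416.0)  # one 12-oz 12-pack
        assert out.loc["H2", "annual_oz"] == pytest.approx(25.0)  # 100 oz, size 4

    def test_outcome_includes_uncovered_lines(self, tiny_tables):
        # H0's 20 oz at the uncovered store "UX" count toward the outcome.
        tables = ps.validate_tables(tiny_tables)
        out = ps.annual_per_capita(tables["purchases"], tables["households"])
        total_h0 = out.set_index("household_id").loc["H0", "annual_oz"] * 2
        assert total_h0 == pytest.approx(100.0)

    def test_servings_conversion(self):
        assert ps.oz_to_servings_per_week(624.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ps.oz_to_servings_per_week(-1.0)


class TestIncomeBins:
    @pytest.mark.parametrize(
        "category, size, expected",
        [
            ("35000-49999", 3, "<=15000"),  # midpoint 42000 / 3 = 14000
            ("<25000", 1, "<=15000"),
            (">=100000", 2, ">=50000"),  # boundary 50000 goes to the higher bin
            ("70000-99999", 2, "30001-50000"),  # 42250
            ("50000-69999", 2, "15001-30000"),
        ],
    )
    def test_examples(self, category, size, expected):
        assert ps.income_per_capita_bin(category, size) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ConfigError):
            ps.income_per_capita_bin("mystery", 1)


class TestQuartiles:
    def test_sizes_near_equal_earlier_never_larger(self):
        for n in (4, 8, 11299, 101, 1003):
            sizes = quartile_sizes(n)
            assert sum(sizes) == n
            assert max(sizes) - min(sizes) <= 1
            assert list(sizes) == sorted(sizes)

    def test_eight_distinct_values(self):
        labels = ps.assign_quartiles([5, 1, 7, 3, 8, 2, 6, 4])
        assert sorted(labels) == [1, 1, 2, 2, 3, 3, 4, 4]
        # ranks follow the values
        assert labels[1] == 1 and labels[4] == 4

    def test_ties_resolved_by_stable_order(self):
        labels = ps.assign_quartiles([2.0, 2.0, 2.0, 2.0])
        assert list(labels) == [1, 2, 3, 4]

    def test_too_small_rejected(self):
        with pytest.raises(ContractError):
            ps.assign_quartiles([1.0, 2.0, 3.0])


class TestBuildCohortAndTables:
    def test_cohort_fields(self, default_cohort):
        coh = default_cohort
        assert (coh["annual_oz"] > 0).all()
        assert np.allclose(coh["log_annual_oz"], np.log(coh["annual_oz"]))
        assert set(coh["purchase_quartile"]) == {1, 2, 3, 4}
        assert coh["size_group"].isin(("1", "2", "3-4", "5+")).all()

    def test_size_group_mapping(self):
        assert [size_group(s) for s in (1, 2, 3, 4, 5, 7)] == ["1", "2", "3-4", "3-4", "5+", "5+"]

    def test_descriptive_medians_match_hand_computation(self):
        toy = pd.DataFrame(
            {
                "household_id": [f"H{i}" for i in range(8)],
                "annual_oz": [100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0],
                "frequency": np.linspace(0.1, 0.8, 8),
                "magnitude": np.linspace(0.01, 0.08, 8),
                "size": [1] * 8,
                "size_group": ["1"] * 8,
                "income_category": ["<25000"] * 8,
                "income_per_capita_bin": ["<=15000"] * 8,
                "male_head_age": ["35-54"] * 8,
                "female_head_age": ["35-54"] * 8,
                "male_head_education": ["college_grad"] * 8,
                "female_head_education": ["college_grad"] * 8,
                "male_head_occupation": ["white_collar"] * 8,
                "female_head_occupation": ["white_collar"] * 8,
                "children_present": [False] * 8,
                "race": ["white"] * 8,
                "hispanic": [False] * 8,
                "region": ["pacific"] * 8,
                "metro": ["metropolitan"] * 8,
                "purchase_quartile": ps.assign_quartiles([100, 200, 300, 400, 500, 600, 700, 800]),
            }
        )
        tables = ps.descriptive_tables(toy)
        overall = tables["outcome_by_exposure"].set_index("group").loc["overall"]
        assert overall["median"] == pytest.approx(450.0)
        assert overall["mean"] == pytest.approx(450.0)

    def test_identical_outcomes_have_zero_iqr(self):
        values = pd.Series([42.0] * 10)
        from promoscan.cohort import _summary_row

        row = _summary_row("x", values)
        assert row["p75"] - row["p25"] == 0.0

    def test_covariate_percentages_sum_to_100(self, default_cohort):
        t1 = ps.descriptive_tables(default_cohort)["covariates_by_quartile"]
        for cov, block in t1.groupby("covariate"):
            assert block["total_pct"].sum() == pytest.approx(100.0, abs=0.5)


def test_retention_percent():
    assert ps.retention_percent(15, 100) == 15.0
    with pytest.raises(ValueError):
        ps.retention_percent(5, 0)
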