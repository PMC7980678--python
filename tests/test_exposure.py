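import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import promoscan as ps
from conftest import brute_force_annual, pipeline_annual, random_exposure_instance


def _price_frame(price_counts, store="S0", product="P0"):
    rows = []
    w = 1
    for price, count in price_counts:
        for _ in range(count):
            rows.append((store, w, product, price))
            w += 1
    return pd.DataFrame(rows, columns=["store_id", "week_index", "product_id", "unit_price"])


class TestModalPrices:
    @pytest.mark.parametrize(
        "price_counts, expected",
        [
            ([(1.00, 40), (0.90, 12)], 1.00),  # unique mode
            ([(1.00, 26), (0.90, 26)], 1.00),  # tie broken to higher price
            ([(0.99, 1)], 0.99),  # singleton is its own mode
        ],
    )
    def test_modal_price(self, price_counts, expected):
        modal = ps.compute_modal_prices(_price_frame(price_counts))
        assert modal.loc[0, "modal_unit_price"] == expected


class TestWeeklyDiscount:
    @pytest.mark.parametrize(
        "price, modal, expected",
        [(0.95, 1.00, 0.05), (1.10, 1.00, 0.00), (1.80, 2.00, 0.10)],
    )
    def test_examples(self, price, modal, expected):
        assert ps.weekly_discount(price, modal) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            ps.weekly_discount(0.0, 1.0)
        with pytest.raises(ValueError):
            ps.weekly_discount(1.0, -1.0)


class TestStoreWeekMagnitude:
    def _magnitude(self, discounts, weights):
        prices = pd.DataFrame(
            [("S0", 1, p, 1.0 - d) for p, d in discounts.items()],
            columns=["store_id", "week_index", "product_id", "unit_price"],
        )
        modal = pd.DataFrame(
            [("S0", p, 1.0) for p in discounts],
            columns=["store_id", "product_id", "modal_unit_price"],
        )
        w = pd.Series(weights, name="weight")
        w.index.name = "product_id"
        return ps.store_week_magnitudes(prices, modal, w).loc[0, "magnitude"]

    def test_weighted_mean(self):
        assert self._magnitude({"A": 0.10, "B": 0.0}, {"A": 0.5, "B": 0.5}) == pytest.approx(0.05)

    def test_renormalizes_over_observed_products(self):
        # only A observed; weights renormalize to A alone
        assert self._magnitude({"A": 0.08}, {"A": 0.3, "B": 0.7}) == pytest.approx(0.08)

    def test_all_zero_discounts(self):
        assert self._magnitude({"A": 0.0, "B": 0.0}, {"A": 0.5, "B": 0.5}) == 0.0


class TestHouseholdWeekExposure:
    def _weekly(self, mags, aggregation):
        sw = pd.DataFrame(
            [(f"S{i}", 1, m) for i, m in enumerate(mags)],
            columns=["store_id", "week_index", "magnitude"],
        )
        sets = pd.DataFrame(
            [("H0", f"S{i}") for i in range(len(mags))],
            columns=["household_id", "store_id"],
        )
        weekly = ps.household_week_exposure(sw, sets, aggregation, n_weeks=2)
        return weekly.set_index("week_index")["magnitude"]

    def test_largest_and_average(self):
        assert self._weekly([0.02, 0.08], "largest").loc[1] == pytest.approx(0.08)
        assert self._weekly([0.02, 0.08], "average").loc[1] == pytest.approx(0.05)

    def test_single_store_modes_agree(self):
        assert self._weekly([0.03], "largest").loc[1] == self._weekly([0.03], "average").loc[1]

    def test_weeks_without_information_score_zero(self):
        assert self._weekly([0.02, 0.08], "largest").loc[2] == 0.0


class TestAnnualize:
    def _annual(self, weekly_values, threshold=0.05):
        weekly = pd.DataFrame(
            {
                "household_id": "H0",
                "week_index": np.arange(1, len(weekly_values) + 1),
                "magnitude": weekly_values,
            }
        )
        config = ps.ExposureConfig(promo_threshold=threshold)
        row = ps.annualize(weekly, config).iloc[0]
        return row["frequency"], row["magnitude"]

    def test_count_and_mean(self):
        freq, mag = self._annual([0.06] * 23 + [0.0] * 29)
        assert freq == pytest.approx(23 / 52)
        assert mag == pytest.approx(23 * 0.06 / 52)

    def test_all_zero(self):
        assert self._annual([0.0] * 52) == (0.0, 0.0)

    def test_threshold_boundary_is_inclusive(self):
        freq, mag = self._annual([0.05] * 52)
        assert freq == 1.0
        assert mag == pytest.approx(0.05)

    def test_wrong_vector_length_rejected(self):
        from promoscan.errors import ContractError

        with pytest.raises(ContractError):
            self._annual([0.05] * 10)


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(2016)
        for _ in range(60):
            instance = random_exposure_instance(rng)
            expected = brute_force_annual(*instance)
            got = pipeline_annual(*instance)
            assert set(got) == set(expected)
            for hh in expected:
                assert got[hh][0] == pytest.approx(expected[hh][0], abs=1e-12)
                assert got[hh][1] == pytest.approx(expected[hh][1], abs=1e-12)


class TestInvariants:
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_monotonicity_and_dominance(self, seed):
        """frequency/magnitude in [0,1]; frequency non-increasing in the
        threshold; largest-aggregation exposure dominates average."""
        rng = np.random.default_rng(seed)
        rows, sets, weights, _, _, n_weeks = random_exposure_instance(rng)
        results = {
            (thr, agg): pipeline_annual(rows, sets, weights, thr, agg, n_weeks)
            for thr in (0.02, 0.05, 0.10)
            for agg in ("largest", "average")
        }
        for annual in results.values():
            for freq, mag in annual.values():
                assert 0.0 <= freq <= 1.0
                assert 0.0 <= mag <= 1.0
        for agg in ("largest", "average"):
            for hh in results[(0.02, agg)]:
                f2 = results[(0.02, agg)][hh][0]
                f5 = results[(0.05, agg)][hh][0]
                f10 = results[(0.10, agg)][hh][0]
                assert f2 >= f5 >= f10
        for thr in (0.02, 0.05, 0.10):
            for hh in results[(thr, "largest")]:
                assert (
                    results[(thr, "largest")][hh][1]
                    >= results[(thr, "average")][hh][1] - 1e-12
                )

    def test_annual_magnitude_bounded_by_max_weekly(self, default_dataset):
        derived = ps.compute_annual_exposure(default_dataset, ps.ExposureConfig())
        weekly_max = derived["weekly"].groupby("household_id")["magnitude"].max()
        annual = derived["annual"].set_index("household_id")
        assert (annual["magnitude"] <= weekly_max + 1e-15).all()
        nonzero = annual["frequency"] > 0
        assert (annual.loc[nonzero, "magnitude"] > 0).all()


def test_mean_price_ratio():
    assert ps.mean_price_ratio(0.046) == pytest.approx(0.954)
    with pytest.raises(ValueError):
        ps.mean_price_ratio(1.5)
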