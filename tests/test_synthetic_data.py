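import numpy as np
import pandas as pd
import pytest

import promoscan as ps
from promoscan.errors import ConfigError, ConsistencyError


SMALL = dict(n_households=120, n_stores=8, n_products=5)


class TestConfig:
    def test_infeasible_store_range_rejected(self):
        with pytest.raises(ConfigError):
            ps.GeneratorConfig(n_stores=3, stores_per_household=(1, 5))

    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigError):
            ps.GeneratorConfig(promo_prob=1.5)
        with pytest.raises(ConfigError):
            ps.GeneratorConfig(promo_depth_mean=0.0)


class TestDeterminism:
    def test_same_seed_byte_identical_different_seed_differs(self):
        a = ps.generate(ps.GeneratorConfig(seed=7, **SMALL))
        b = ps.generate(ps.GeneratorConfig(seed=7, **SMALL))
        c = ps.generate(ps.GeneratorConfig(seed=8, **SMALL))
        for name in ("stores", "prices", "products", "households", "purchases", "truth"):
            pd.testing.assert_frame_equal(a[name], b[name], check_exact=True)
        assert not a["purchases"]["volume_oz"].equals(c["purchases"]["volume_oz"])


class TestEdgeConditions:
    def test_no_promotions_means_zero_exposure(self):
        ds = ps.generate(ps.GeneratorConfig(promo_prob=0.0, seed=1, **SMALL))
        assert (ds["truth"]["frequency"] == 0).all()
        assert (ds["truth"]["magnitude"] == 0).all()
        derived = ps.compute_annual_exposure(ds)
        assert (derived["annual"]["frequency"] == 0).all()
        assert (derived["annual"]["magnitude"] == 0).all()

    def test_saturated_promotion_truth(self):
        """Perpetual promotion at constant depth: every week promoted at the
        full depth relative to the regular price."""
        cfg = ps.GeneratorConfig(
            promo_prob=1.0,
            promo_depth_mean=0.10,
            promo_depth_sd=0.0,
            stores_per_household=(1, 1),
            seed=2,
            **SMALL,
        )
        ds = ps.generate(cfg)
        assert (ds["truth"]["frequency"] == 1.0).all()
        assert np.allclose(ds["truth"]["magnitude"], 0.10)


class TestTruthConsistency:
    def test_pipeline_recovers_truth(self, default_dataset):
        report = ps.verify_truth(default_dataset)
        assert report["max_weekly_deviation"] < 1e-9
        assert report["max_frequency_deviation"] < 1e-9
        assert report["max_magnitude_deviation"] < 1e-9

    def test_perturbed_price_is_localized(self):
        ds = ps.generate(ps.GeneratorConfig(seed=4, **SMALL))
        prices = ds["prices"].copy()
        # force a deep fake discount in one store-week
        target = prices.index[100]
        prices.loc[target, "unit_price"] = prices.loc[target, "unit_price"] * 0.2
        with pytest.raises(ConsistencyError, match="household"):
            ps.verify_truth({**ds, "prices": prices})

    def test_threshold_change_affects_only_frequency(self):
        ds = ps.generate(ps.GeneratorConfig(seed=5, **SMALL))
        alt = ps.ExposureConfig(promo_threshold=0.15, weight_scheme="sample_volume")
        derived = ps.compute_annual_exposure(ds, alt)
        merged = derived["annual"].merge(
            ds["truth"], on="household_id", suffixes=("_alt", "_truth")
        )
        assert np.allclose(merged["magnitude_alt"], merged["magnitude_truth"], atol=1e-9)
        assert not np.allclose(merged["frequency_alt"], merged["frequency_truth"])


class TestStatisticalStructure:
    def test_storeweek_promotion_rate_matches_config(self):
        cfg = ps.GeneratorConfig(seed=6, n_households=50, n_stores=30, n_products=12)
        ds = ps.generate(cfg)
        modal = ps.compute_modal_prices(ds["prices"])
        df = ds["prices"].merge(modal, on=["store_id", "product_id"])
        discounted = (df["unit_price"] < df["modal_unit_price"]).mean()
        n = len(df)
        se = np.sqrt(cfg.promo_prob * (1 - cfg.promo_prob) / n)
        assert discounted == pytest.approx(cfg.promo_prob, abs=5 * se)

    def test_null_planted_effect_centers_on_one(self):
        cfg = ps.GeneratorConfig(n_households=4000, beta_freq_per10=1.0)
        ests = []
        for seed in range(8):
            coh = ps.generate_cohort(cfg, seed=300 + seed)
            ests.append(ps.fit_main(coh, ps.ModelSpec("frequency")).exp_estimate)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.03)

    def test_coverage_mix_makes_all_filters_bite(self, default_dataset):
        linkage = ps.linkage_report(
            default_dataset["purchases"], default_dataset["stores"]
        )
        counts = [
            len(ps.apply_inclusion(linkage, thr)) for thr in (0.60, 0.70, 0.80, 0.90)
        ]
        assert counts[0] < len(linkage)  # even the loosest filter excludes someone
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cohort_and_tables_agree_on_truth_exposure(self):
        ds = ps.generate(ps.GeneratorConfig(seed=9, **SMALL))
        derived = ps.compute_annual_exposure(ds)
        merged = derived["annual"].merge(
            ds["truth"], on="household_id", suffixes=("_p", "_t")
        )
        assert np.allclose(merged["frequency_p"], merged["frequency_t"], atol=1e-9)
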