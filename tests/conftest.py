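"""Shared fixtures and the independent brute-force exposure oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import promoscan as ps

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the generator's default conditions."""
    return ps.generate(ps.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_cohort(default_dataset):
    ds = default_dataset
    linkage = ps.linkage_report(ds["purchases"], ds["stores"])
    included = ps.apply_inclusion(linkage, 0.80)
    derived = ps.compute_annual_exposure(ds, ps.ExposureConfig(), households=included)
    return ps.build_cohort(ds, derived["annual"], included)


@pytest.fixture()
def tiny_tables():
    """Hand-built two-store, three-product tables for plumbing tests."""
    stores = pd.DataFrame(
        {
            "store_id": ["S0", "S1"],
            "retailer_code": ["R0", "R0"],
            "channel": ["food", "drug"],
            "metro": ["metropolitan", "urban_rural"],
        }
    )
    rows = []
    for s in ("S0", "S1"):
        for p in ("P0", "P1", "P2"):
            for w in range(1, 53):
                rows.append((s, w, p, 0.05 if w % 4 else 0.045))
    prices = pd.DataFrame(rows, columns=["store_id", "week_index", "product_id", "unit_price"])
    products = pd.DataFrame(
        {
            "product_id": ["P0", "P1", "P2"],
            "category": ["carbonated_soft_drink", "carbonated_soft_drink", "fruit_drink"],
            "package_oz": [416.0, 195.0, 12.0],
        }
    )
    households = pd.DataFrame(
        {
            "household_id": ["H0", "H1", "H2", "H3"],
            "size": [2, 1, 4, 1],
            "income_category": ["<25000", "35000-49999", ">=100000", "70000-99999"],
            "male_head_age": ["35-54", "no_head", "55+", "<35"],
            "female_head_age": ["35-54", "55+", "55+", "no_head"],
            "male_head_education": ["college_grad", "no_head", "some_college", "college_grad"],
            "female_head_education": ["college_grad", "high_school_or_less", "some_college", "no_head"],
            "male_head_occupation": ["white_collar", "no_head", "blue_collar", "other"],
            "female_head_occupation": ["white_collar", "other", "blue_collar", "no_head"],
            "children_present": [True, False, True, False],
            "race": ["white", "black", "other", "white"],
            "hispanic": [False, False, True, False],
            "region": ["pacific", "new_england", "mountain", "south_atlantic"],
            "metro": ["metropolitan", "metropolitan", "urban_rural", "metropolitan"],
        }
    )
    purchases = pd.DataFrame(
        {
            "household_id": ["H0", "H0", "H1", "H2", "H3"],
            "store_id": ["S0", "UX", "S1", "S0", "S1"],
            "week_index": [1, 2, 3, 4, 5],
            "product_id": ["P0", "P0", "P1", "P2", "P0"],
            "volume_oz": [80.0, 20.0, 416.0, 100.0, 992.0],
        }
    )
    return {
        "stores": stores,
        "prices": prices,
        "products": products,
        "households": households,
        "purchases": purchases,
    }


# ---------------------------------------------------------------------------
# Brute-force oracle: plain-python enumeration over (store, product, week)
# triples, written independently of the pandas pipeline.
# ---------------------------------------------------------------------------


def brute_force_annual(price_rows, store_sets, weights, threshold, aggregation, n_weeks):
    """Enumerate exposure the slow way.

    price_rows: iterable of (store, week, product, price).
    store_sets: dict household -> list of stores.
    weights: dict product -> weight.
    Returns dict household -> (frequency, magnitude).
    """
    by_sp = {}
    for s, w, p, price in price_rows:
        by_sp.setdefault((s, p), []).append(price)
    modal = {}
    for key, series in by_sp.items():
        counts = {}
        for price in series:
            counts[price] = counts.get(price, 0) + 1
        best = max(counts.values())
        modal[key] = max(price for price, c in counts.items() if c == best)

    sw_mag = {}
    by_sw = {}
    for s, w, p, price in price_rows:
        by_sw.setdefault((s, w), []).append((p, price))
    for (s, w), obs in by_sw.items():
        num = den = dsum = 0.0
        for p, price in obs:
            m = modal[(s, p)]
            d = max(0.0, (m - price) / m)
            wt = weights.get(p, 0.0)
            num += wt * d
            den += wt
            dsum += d
        sw_mag[(s, w)] = num / den if den > 0 else dsum / len(obs)

    out = {}
    for hh, stores in store_sets.items():
        weekly = []
        for w in range(1, n_weeks + 1):
            vals = [sw_mag[(s, w)] for s in stores if (s, w) in sw_mag]
            if not vals:
                weekly.append(0.0)
            elif aggregation == "largest":
                weekly.append(max(vals))
            else:
                weekly.append(sum(vals) / len(vals))
        freq = sum(1 for v in weekly if v >= threshold) / n_weeks
        mag = sum(weekly) / n_weeks
        out[hh] = (freq, mag)
    return out


def random_exposure_instance(rng):
    """A tiny random price/store-set/weight instance for oracle comparison."""
    n_stores = rng.integers(1, 4)
    n_products = rng.integers(1, 4)
    n_weeks = int(rng.integers(1, 7))
    stores = [f"S{i}" for i in range(n_stores)]
    products = [f"P{i}" for i in range(n_products)]
    price_grid = [1.0, 0.9, 0.8, 1.1, 0.95]
    rows = []
    for s in stores:
        for p in products:
            for w in range(1, n_weeks + 1):
                if rng.random() < 0.75:
                    rows.append((s, w, p, float(rng.choice(price_grid))))
    # ensure at least one observation so modal prices exist
    if not rows:
        rows.append((stores[0], 1, products[0], 1.0))
    raw_w = rng.random(n_products) * (rng.random(n_products) > 0.2)
    total = raw_w.sum()
    weights = {
        p: (float(raw_w[i] / total) if total > 0 else 0.0)
        for i, p in enumerate(products)
    }
    n_households = int(rng.integers(1, 4))
    store_sets = {}
    for h in range(n_households):
        k = int(rng.integers(1, n_stores + 1))
        store_sets[f"H{h}"] = list(rng.choice(stores, size=k, replace=False))
    threshold = float(rng.choice([0.02, 0.05, 0.10]))
    aggregation = "largest" if rng.random() < 0.5 else "average"
    return rows, store_sets, weights, threshold, aggregation, n_weeks


def pipeline_annual(rows, store_sets, weights, threshold, aggregation, n_weeks):
    """Run the production exposure chain on an oracle instance."""
    prices = pd.DataFrame(rows, columns=["store_id", "week_index", "product_id", "unit_price"])
    modal = ps.compute_modal_prices(prices)
    w = pd.Series(weights, name="weight")
    w.index.name = "product_id"
    sw = ps.store_week_magnitudes(prices, modal, w)
    sets = pd.DataFrame(
        [(h, s) for h, stores in store_sets.items() for s in stores],
        columns=["household_id", "store_id"],
    )
    weekly = ps.household_week_exposure(sw, sets, aggregation, n_weeks)
    config = ps.ExposureConfig(
        promo_threshold=threshold, aggregation=aggregation, n_weeks=n_weeks
    )
    annual = ps.annualize(weekly, config)
    return {
        row.household_id: (row.frequency, row.magnitude)
        for row in annual.itertuples()
    }
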