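"""Household promotion-exposure derivation from weekly store prices.

A *price promotion* is a temporary reduction of a product's weekly store
price below its regular price.  The regular price is proxied by the **modal
price**: the most frequently observed weekly unit price of that product at
that store over the year.  Because promotions deflect prices downward, the
regular price is the upper mode; frequency ties are therefore broken to the
highest tied price.

For every store-week the product-level discounts

    discount = max(0, (modal - price) / modal)

are combined into a single store-week promotion magnitude by a weighted mean
whose weights are each product's share of total purchase volume in the
household sample (so the measure is dominated by the products people actually
buy, and is comparable across stores).  Weights are renormalized within each
store-week over the products that have a price observation there; a
store-week with no price record contributes no information (missing is not a
zero discount).

A household's weekly exposure is then the **largest** (main definition) or
the **average** (sensitivity definition) store-week magnitude among the
stores where the household bought sugar-sweetened beverages during the year.
Weeks in which no shopped store has a defined magnitude score 0, keeping the
annual denominator at the full 52 weeks.  Annually,

    frequency = #(weeks with weekly magnitude >= threshold) / 52
    magnitude = mean of the 52 weekly magnitudes (sub-threshold weeks included)

with a default promotion threshold of 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .scanner_model import N_WEEKS

AGGREGATIONS = ("largest", "average")
WEIGHT_SCHEMES = ("sample_volume", "uniform")


@dataclass(frozen=True)
class ExposureConfig:
    """Parameters of the exposure derivation.

    promo_threshold
        Minimum weekly magnitude (fraction off modal price) for a week to
        count as promoted in the annual frequency; default 0.05 and the weekly
        comparison is inclusive (``>=``).
    aggregation
        How store-week magnitudes combine across a household's shopped
        stores: ``"largest"`` (main analysis) or ``"average"`` (sensitivity).
    weight_scheme
        ``"sample_volume"`` weights products by total ounces purchased in the
        sample; ``"uniform"`` weights observed products equally.
    n_weeks
        Number of week bins in the calendar (52 for an annual study).
    """

    promo_threshold: float = 0.05
    aggregation: str = "largest"
    weight_scheme: str = "sample_volume"
    n_weeks: int = N_WEEKS

    def __post_init__(self):
        if not (0.0 < self.promo_threshold < 1.0):
            raise ConfigError(
                f"promo_threshold must be in (0, 1); got {self.promo_threshold}"
            )
        if self.aggregation not in AGGREGATIONS:
            raise ConfigError(f"aggregation must be one of {AGGREGATIONS}")
        if self.weight_scheme not in WEIGHT_SCHEMES:
            raise ConfigError(f"weight_scheme must be one of {WEIGHT_SCHEMES}")
        if self.n_weeks < 1:
            raise ConfigError("n_weeks must be >= 1")


def compute_modal_prices(prices: pd.DataFrame) -> pd.DataFrame:
    """Most frequently observed unit price per (store, product).

    Frequency ties are broken to the highest tied price (the regular price is
    the upper mode under downward price deflections).  A singleton series is
    its own mode.
    """
    counts = (
        prices.groupby(["store_id", "product_id", "unit_price"], sort=True)
        .size()
        .reset_index(name="n_weeks_observed")
    )
    # Global sort by (count, price): within each (store, product) group the
    # rows appear in increasing (count, price) order, so keep="last" selects
    # the maximal count with ties resolved to the highest price.
    counts = counts.sort_values(["n_weeks_observed", "unit_price"], kind="stable")
    modal = counts.drop_duplicates(subset=["store_id", "product_id"], keep="last")
    modal = modal.rename(columns={"unit_price": "modal_unit_price"})
    return (
        modal[["store_id", "product_id", "modal_unit_price"]]
        .sort_values(["store_id", "product_id"], kind="stable")
        .reset_index(drop=True)
    )


def weekly_discount(unit_price, modal_unit_price):
    """Fractional discount of a weekly price relative to the modal price.

    ``max(0, (modal - price) / modal)``; prices above the modal price clamp
    to 0 (a price rise is not a negative promotion).  Accepts scalars or
    arrays; all inputs must be strictly positive.
    """
    price = np.asarray(unit_price, dtype=float)
    modal = np.asarray(modal_unit_price, dtype=float)
    if (price <= 0).any() or (modal <= 0).any():
        raise ValueError("unit_price and modal_unit_price must be strictly positive")
    out = np.maximum(0.0, (modal - price) / modal)
    if np.isscalar(unit_price) and np.isscalar(modal_unit_price):
        return float(out)
    return out


def compute_volume_weights(
    purchases: pd.DataFrame,
    scheme: str = "sample_volume",
    product_ids=None,
) -> pd.Series:
    """Per-product standardization weights, summing to one.

    ``sample_volume`` makes each weight proportional to the product's total
    purchased ounces across the given purchase lines (the volume actually
    moved in the sample).  ``uniform`` gives equal weight to every product in
    ``product_ids`` (or, failing that, every product seen in the purchases).
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ConfigError(f"weight scheme must be one of {WEIGHT_SCHEMES}")
    if scheme == "uniform":
        if product_ids is None:
            product_ids = sorted(purchases["product_id"].unique())
        ids = pd.Index(product_ids, name="product_id")
        return pd.Series(1.0 / len(ids), index=ids, name="weight")
    totals = purchases.groupby("product_id", sort=True)["volume_oz"].sum()
    w = totals / totals.sum()
    w.name = "weight"
    return w


def store_week_magnitudes(
    prices: pd.DataFrame,
    modal_prices: pd.DataFrame,
    weights: pd.Series,
) -> pd.DataFrame:
    """Volume-weighted promotion magnitude per (store, week).

    The magnitude is the weighted mean of product-level discounts over the
    products with a price observation in that store-week, with weights
    renormalized over those observed products.  Products missing from the
    weight vector carry weight 0; if every observed product has zero weight
    the plain mean of discounts is used (uniform fallback).  Store-weeks with
    no price observation at all are simply absent from the result: missing
    means "no information", not "no discount offered".
    """
    df = prices.merge(modal_prices, on=["store_id", "product_id"], how="left")
    df["discount"] = weekly_discount(
        df["unit_price"].to_numpy(), df["modal_unit_price"].to_numpy()
    )
    df["w"] = df["product_id"].map(weights).fillna(0.0).to_numpy()
    df["wd"] = df["w"] * df["discount"]
    g = df.groupby(["store_id", "week_index"], sort=True).agg(
        wsum=("w", "sum"),
        wdsum=("wd", "sum"),
        dsum=("discount", "sum"),
        nobs=("discount", "size"),
    )
    g["magnitude"] = np.where(
        g["wsum"] > 0, g["wdsum"] / g["wsum"], g["dsum"] / g["nobs"]
    )
    return g.reset_index()[["store_id", "week_index", "magnitude"]]


def household_store_sets(
    purchases: pd.DataFrame, stores: pd.DataFrame
) -> pd.DataFrame:
    """Unique (household, store) pairs over *covered* stores.

    The store set is the year-long set of covered stores at which the
    household bought sugar-sweetened beverages; uncovered stores carry no
    price data and are excluded.  Households whose purchases are entirely
    uncovered are absent from the result (they fail the inclusion filter
    upstream).
    """
    covered = purchases[purchases["store_id"].isin(set(stores["store_id"]))]
    return (
        covered[["household_id", "store_id"]]
        .drop_duplicates()
        .sort_values(["household_id", "store_id"], kind="stable")
        .reset_index(drop=True)
    )


def household_week_exposure(
    store_week_mags: pd.DataFrame,
    store_sets: pd.DataFrame,
    aggregation: str = "largest",
    n_weeks: int = N_WEEKS,
) -> pd.DataFrame:
    """Weekly promotion magnitude experienced by each household.

    ``largest`` takes the maximum defined store-week magnitude over the
    household's store set in that week (the salient-discount premise of the
    main analysis); ``average`` takes the mean over the same stores
    (sensitivity definition).  Weeks in which no store in the set has a
    defined magnitude score 0.  The result has exactly ``n_weeks`` rows per
    household.
    """
    if aggregation not in AGGREGATIONS:
        raise ConfigError(f"aggregation must be one of {AGGREGATIONS}")
    if store_sets.empty:
        raise ContractError("empty store set: no household has a covered store")
    joined = store_sets.merge(store_week_mags, on="store_id", how="inner")
    agg_fn = "max" if aggregation == "largest" else "mean"
    weekly = joined.groupby(["household_id", "week_index"], sort=True)[
        "magnitude"
    ].agg(agg_fn)
    households = store_sets["household_id"].unique()
    full = pd.MultiIndex.from_product(
        [np.sort(households), np.arange(1, n_weeks + 1)],
        names=["household_id", "week_index"],
    )
    weekly = weekly.reindex(full, fill_value=0.0)
    return weekly.reset_index()


def annualize(weekly: pd.DataFrame, config: ExposureConfig) -> pd.DataFrame:
    """Annual promotion frequency and magnitude per household.

    ``frequency`` is the share of the year's weeks whose weekly magnitude is
    at or above the promotion threshold; ``magnitude`` is the arithmetic mean
    of all weekly magnitudes, sub-threshold weeks included.  Requires exactly
    ``config.n_weeks`` weekly values per household.
    """
    sizes = weekly.groupby("household_id", sort=True).size()
    if (sizes != config.n_weeks).any():
        bad = sizes[sizes != config.n_weeks].index[0]
        raise ContractError(
            f"household {bad!r} has {sizes[bad]} weekly values; "
            f"expected exactly {config.n_weeks}"
        )
    df = weekly.assign(hit=weekly["magnitude"] >= config.promo_threshold)
    annual = df.groupby("household_id", sort=True).agg(
        frequency=("hit", "mean"), magnitude=("magnitude", "mean")
    )
    return annual.reset_index()


def compute_annual_exposure(
    tables: dict,
    config: ExposureConfig | None = None,
    households=None,
) -> dict:
    """Run the full exposure derivation on validated tables.

    ``households`` optionally restricts the purchase lines used for the
    volume weights and store sets to an analytic subsample (the weights are
    computed once, globally over that sample's purchases).  Returns a dict
    with ``modal_prices``, ``volume_weights``, ``store_week``, ``weekly`` and
    ``annual`` tables.
    """
    config = config or ExposureConfig()
    purchases = tables["purchases"]
    if households is not None:
        purchases = purchases[purchases["household_id"].isin(set(households))]
    modal = compute_modal_prices(tables["prices"])
    weights = compute_volume_weights(purchases, scheme=config.weight_scheme)
    sw = store_week_magnitudes(tables["prices"], modal, weights)
    sets = household_store_sets(purchases, tables["stores"])
    weekly = household_week_exposure(sw, sets, config.aggregation, config.n_weeks)
    annual = annualize(weekly, config)
    return {
        "modal_prices": modal,
        "volume_weights": weights,
        "store_week": sw,
        "weekly": weekly,
        "annual": annual,
    }


def mean_price_ratio(annual_magnitude: float) -> float:
    """Average annual price as a fraction of the modal price.

    A mean promotion magnitude of 0.046 means households paid on average
    1 - 0.046 = 0.954 of the regular (modal) price.
    """
    m = float(annual_magnitude)
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"annual magnitude must be in [0, 1]; got {m}")
    return 1.0 - m
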