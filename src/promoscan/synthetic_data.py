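"""Seeded synthetic scanner-and-panel data with planted promotion effects.

The generator emulates the statistical structure the analysis assumes:

* every store carries every product every week (a complete weekly price
  panel); each (store, product) has a regular unit price and, with
  probability ``promo_prob`` per week, a discount whose depth is drawn from a
  truncated normal on (0, 1) — so the regular price is the modal price as
  long as promotions are intermittent;
* households shop a fixed year-long set of 1-5 covered stores and may route
  part of their volume through an uncovered store (absent from the price
  data), which exercises the coverage-based inclusion filter;
* demographic covariates are drawn from category margins resembling a large
  US consumer panel;
* the log of annual per-capita purchase volume is linear in the household's
  *true* annual promotion exposure with a planted multiplicative coefficient,
  plus covariate shifts and log-normal noise.

Every household buys the same global product mix (a Dirichlet draw shared by
all households).  This makes the sample-volume product weights known in
closed form, so the planted exposure is exactly what the exposure pipeline
recomputes from the emitted tables — regardless of which households survive
the inclusion filter.

Truth is defined relative to the *regular* (base) price.  Modal-price
detection recovers it exactly when promotions are intermittent
(``promo_prob`` well below 0.5 or a dispersed depth distribution); under
perpetual promotion at a constant depth the modal price collapses onto the
discounted price and the pipeline, like any modal-price method, reports no
promotion.  :func:`verify_truth` checks the intermittent regime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError, ConsistencyError
from . import cohort as cohort_mod
from . import exposure as exposure_mod
from .scanner_model import (
    CATEGORIES,
    CHANNELS,
    HEAD_AGES,
    HEAD_EDUCATIONS,
    HEAD_OCCUPATIONS,
    INCOME_CATEGORIES,
    METRO_LEVELS,
    N_WEEKS,
    RACES,
    REGIONS,
    validate_tables,
    write_tables,
)

# Category margins echoing a large US household panel (shares renormalize).
_SIZE_GROUP_P = {"1": 0.266, "2": 0.424, "3-4": 0.245, "5+": 0.065}
_INCOME_P = dict(zip(INCOME_CATEGORIES, (0.123, 0.103, 0.163, 0.187, 0.220, 0.205)))
_MALE_HEAD_PRESENT = 0.738
_FEMALE_HEAD_PRESENT = 0.891
_MALE_AGE_P = (0.065, 0.262, 0.411)  # <35, 35-54, 55+ among households with a male head
_FEMALE_AGE_P = (0.095, 0.327, 0.469)
_MALE_EDU_P = (0.194, 0.200, 0.344)
_FEMALE_EDU_P = (0.200, 0.259, 0.431)
_MALE_OCC_P = (0.321, 0.189, 0.228)
_FEMALE_OCC_P = (0.444, 0.087, 0.360)
_CHILDREN_P = 0.212
_RACE_P = (0.838, 0.080, 0.083)
_HISPANIC_P = 0.059
_REGION_P = (0.062, 0.052, 0.171, 0.074, 0.184, 0.066, 0.082, 0.135, 0.174)
_METRO_P = (0.902, 0.098)

_PACKAGE_OZ = (12.0, 20.0, 67.6, 144.0, 195.0, 416.0)
_PACKAGE_P = (0.25, 0.15, 0.20, 0.15, 0.15, 0.10)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic scanner-and-panel world.

    The promotion parameters (``promo_prob = 0.10``, depth ~ truncated
    normal(0.25, 0.08) on (0, 1), 1-5 stores per household) put derived
    annual exposures near the ranges observed in large US scanner panels
    (mean frequency around 0.44, mean magnitude around 0.05).  The planted
    coefficients default to multiplicative effects of 1.137 per 10
    percentage points of frequency and 1.153 per 1 percentage point of
    magnitude; ``outcome_driver`` selects which exposure generates the
    outcome.  The log-outcome intercept and noise (5.65, 1.6 on the natural
    log scale) reproduce the strong right skew of annual per-capita purchase
    volumes.
    """

    n_households: int = 1000
    n_stores: int = 20
    n_products: int = 10
    promo_prob: float = 0.10
    promo_depth_mean: float = 0.25
    promo_depth_sd: float = 0.08
    stores_per_household: tuple[int, int] = (1, 5)
    baseline_log_oz_mean: float = 5.65
    baseline_log_oz_sd: float = 1.6
    beta_freq_per10: float = 1.137
    beta_mag_per1: float = 1.153
    outcome_driver: str = "frequency"
    covariate_effects: dict = field(
        default_factory=lambda: {
            "children_present=True": 0.15,
            "race=black": 0.20,
            "income_per_capita_bin=<=15000": 0.15,
            "metro=urban_rural": -0.10,
        }
    )
    coverage_mix: float = 0.5
    uncovered_share_alpha: float = 1.5
    uncovered_share_beta: float = 6.0
    promo_threshold: float = 0.05
    aggregation: str = "largest"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.stores_per_household
        if not (1 <= lo <= hi):
            raise ConfigError("stores_per_household must be a range with 1 <= lo <= hi")
        if hi > self.n_stores:
            raise ConfigError(
                f"stores_per_household upper bound {hi} exceeds n_stores {self.n_stores}"
            )
        if not (0.0 <= self.promo_prob <= 1.0):
            raise ConfigError("promo_prob must be in [0, 1]")
        if not (0.0 < self.promo_depth_mean < 1.0):
            raise ConfigError("promo_depth_mean must be in (0, 1)")
        if self.promo_depth_sd < 0:
            raise ConfigError("promo_depth_sd must be nonnegative")
        if not (0.0 <= self.coverage_mix <= 1.0):
            raise ConfigError("coverage_mix must be in [0, 1]")
        if not (0.0 < self.promo_threshold < 1.0):
            raise ConfigError("promo_threshold must be in (0, 1)")
        if self.outcome_driver not in ("frequency", "magnitude"):
            raise ConfigError("outcome_driver must be 'frequency' or 'magnitude'")
        if self.aggregation not in exposure_mod.AGGREGATIONS:
            raise ConfigError(
                f"aggregation must be one of {exposure_mod.AGGREGATIONS}"
            )
        if self.beta_freq_per10 <= 0 or self.beta_mag_per1 <= 0:
            raise ConfigError("planted multiplicative effects must be > 0")

    def exposure_config(self) -> exposure_mod.ExposureConfig:
        """The exposure settings under which the planted truth is exact."""
        return exposure_mod.ExposureConfig(
            promo_threshold=self.promo_threshold,
            aggregation=self.aggregation,
            weight_scheme="sample_volume",
        )


def _draw_depths(cfg: GeneratorConfig, shape, rng) -> np.ndarray:
    if cfg.promo_depth_sd == 0:
        return np.full(shape, cfg.promo_depth_mean)
    a = (0.0 - cfg.promo_depth_mean) / cfg.promo_depth_sd
    b = (1.0 - cfg.promo_depth_mean) / cfg.promo_depth_sd
    return scipy.stats.truncnorm.rvs(
        a, b, loc=cfg.promo_depth_mean, scale=cfg.promo_depth_sd,
        size=shape, random_state=rng,
    )


def _simulate_market(cfg: GeneratorConfig, rng):
    """Base prices, discount tensor and store-week magnitudes.

    Returns (base_prices (S, P), discounts (S, P, W), store_week_mag (S, W),
    product_weights (P,)).
    """
    S, P, W = cfg.n_stores, cfg.n_products, N_WEEKS
    weights = rng.dirichlet(np.full(P, 2.0))
    base = rng.uniform(0.03, 0.09, size=(S, P))
    promoted = rng.random((S, P, W)) < cfg.promo_prob
    depth = _draw_depths(cfg, (S, P, W), rng)
    discounts = np.where(promoted, depth, 0.0)
    mags = np.einsum("spw,p->sw", discounts, weights)
    return base, discounts, mags, weights


def _sample_store_sets(cfg: GeneratorConfig, rng):
    """(k sizes, index matrix (n, kmax)) of distinct covered-store indices."""
    n, S = cfg.n_households, cfg.n_stores
    lo, hi = cfg.stores_per_household
    k = rng.integers(lo, hi + 1, size=n)
    order = np.argsort(rng.random((n, S)), axis=1)
    return k, order[:, : hi]


def _household_weekly(mags: np.ndarray, set_idx: np.ndarray, k: np.ndarray,
                      aggregation: str) -> np.ndarray:
    """(n, W) weekly exposure for each household from (S, W) store magnitudes."""
    n, kmax = set_idx.shape
    sel = mags[set_idx]  # (n, kmax, W)
    mask = np.arange(kmax)[None, :] < k[:, None]  # (n, kmax)
    if aggregation == "largest":
        masked = np.where(mask[:, :, None], sel, -np.inf)
        return masked.max(axis=1)
    masked = np.where(mask[:, :, None], sel, 0.0)
    return masked.sum(axis=1) / k[:, None]


def _sample_covariates(cfg: GeneratorConfig, rng) -> pd.DataFrame:
    n = cfg.n_households
    def pick(levels, probs):
        p = np.asarray(probs, dtype=float)
        return rng.choice(levels, size=n, p=p / p.sum())

    group = pick(list(_SIZE_GROUP_P), list(_SIZE_GROUP_P.values()))
    size = np.where(
        group == "1", 1,
        np.where(
            group == "2", 2,
            np.where(group == "3-4", rng.integers(3, 5, n), 5 + rng.poisson(0.5, n)),
        ),
    ).astype(np.int64)

    def head_block(present_p, age_p, edu_p, occ_p):
        present = rng.random(n) < present_p
        age = np.where(present, pick(HEAD_AGES[:-1], age_p), "no_head")
        edu = np.where(present, pick(HEAD_EDUCATIONS[:-1], edu_p), "no_head")
        occ = np.where(present, pick(HEAD_OCCUPATIONS[:-1], occ_p), "no_head")
        return age, edu, occ

    m_age, m_edu, m_occ = head_block(_MALE_HEAD_PRESENT, _MALE_AGE_P, _MALE_EDU_P, _MALE_OCC_P)
    f_age, f_edu, f_occ = head_block(_FEMALE_HEAD_PRESENT, _FEMALE_AGE_P, _FEMALE_EDU_P, _FEMALE_OCC_P)
    return pd.DataFrame(
        {
            "household_id": [f"H{i:05d}" for i in range(n)],
            "size": size,
            "income_category": pick(INCOME_CATEGORIES, list(_INCOME_P.values())),
            "male_head_age": m_age,
            "female_head_age": f_age,
            "male_head_education": m_edu,
            "female_head_education": f_edu,
            "male_head_occupation": m_occ,
            "female_head_occupation": f_occ,
            "children_present": rng.random(n) < _CHILDREN_P,
            "race": pick(RACES, _RACE_P),
            "hispanic": rng.random(n) < _HISPANIC_P,
            "region": pick(REGIONS, _REGION_P),
            "metro": pick(METRO_LEVELS, _METRO_P),
        }
    )


def _covariate_shift(cfg: GeneratorConfig, hh: pd.DataFrame) -> np.ndarray:
    shift = np.zeros(len(hh))
    derived = hh.copy()
    derived["income_per_capita_bin"] = [
        cohort_mod.income_per_capita_bin(c, s)
        for c, s in zip(hh["income_category"], hh["size"])
    ]
    for key, delta in cfg.covariate_effects.items():
        col, _, level = key.partition("=")
        if col not in derived.columns:
            raise ConfigError(f"covariate_effects key {key!r}: unknown column {col!r}")
        shift += np.where(derived[col].astype(str) == level, float(delta), 0.0)
    return shift


def _draw_outcome(cfg: GeneratorConfig, freq, mag, shift, rng):
    """Expected and realized log per-capita annual ounces."""
    if cfg.outcome_driver == "frequency":
        x, beta = freq * 10.0, np.log(cfg.beta_freq_per10)
    else:
        x, beta = mag * 100.0, np.log(cfg.beta_mag_per1)
    mu = cfg.baseline_log_oz_mean + beta * x + shift
    log_pc = mu + rng.normal(0.0, cfg.baseline_log_oz_sd, size=len(mu))
    return mu, log_pc


def _simulate(cfg: GeneratorConfig, rng):
    """Shared core: market, households, true exposure, outcome, coverage."""
    base, discounts, mags, weights = _simulate_market(cfg, rng)
    hh = _sample_covariates(cfg, rng)
    k, set_idx = _sample_store_sets(cfg, rng)
    weekly = _household_weekly(mags, set_idx, k, cfg.aggregation)
    freq = (weekly >= cfg.promo_threshold).mean(axis=1)
    mag = weekly.mean(axis=1)
    shift = _covariate_shift(cfg, hh)
    mu, log_pc = _draw_outcome(cfg, freq, mag, shift, rng)
    n = cfg.n_households
    has_unc = rng.random(n) < cfg.coverage_mix
    unc_share = np.where(
        has_unc,
        rng.beta(cfg.uncovered_share_alpha, cfg.uncovered_share_beta, size=n),
        0.0,
    )
    return {
        "base": base,
        "discounts": discounts,
        "mags": mags,
        "weights": weights,
        "households": hh,
        "k": k,
        "set_idx": set_idx,
        "weekly": weekly,
        "frequency": freq,
        "magnitude": mag,
        "mu": mu,
        "log_pc": log_pc,
        "uncovered_share": unc_share,
    }


def generate_cohort(cfg: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Fast path: a fitted-model-ready cohort without materializing tables.

    Returns one row per household with true exposure, the drawn outcome and
    all model covariates — the input :func:`promoscan.inference.fit_main`
    expects.  Used for Monte-Carlo parameter-recovery and test-calibration
    studies where emitting full purchase line items would dominate runtime.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sim = _simulate(cfg, rng)
    hh = sim["households"].copy()
    hh["frequency"] = sim["frequency"]
    hh["magnitude"] = sim["magnitude"]
    hh["log_annual_oz"] = sim["log_pc"]
    hh["annual_oz"] = np.exp(sim["log_pc"])
    hh["income_per_capita_bin"] = [
        cohort_mod.income_per_capita_bin(c, s)
        for c, s in zip(hh["income_category"], hh["size"])
    ]
    hh["size_group"] = hh["size"].map(cohort_mod.size_group)
    return hh


def _emit_prices(cfg, base, discounts, store_ids, product_ids) -> pd.DataFrame:
    S, P, W = cfg.n_stores, cfg.n_products, N_WEEKS
    unit = base[:, :, None] * (1.0 - discounts)  # (S, P, W)
    idx_s, idx_p, idx_w = np.meshgrid(
        np.arange(S), np.arange(P), np.arange(1, W + 1), indexing="ij"
    )
    return pd.DataFrame(
        {
            "store_id": np.asarray(store_ids)[idx_s.ravel()],
            "week_index": idx_w.ravel().astype(np.int64),
            "product_id": np.asarray(product_ids)[idx_p.ravel()],
            "unit_price": unit.ravel(),
        }
    )


def _emit_purchases(cfg, sim, store_ids, product_ids) -> pd.DataFrame:
    """Weekly purchase lines whose annual sums match the drawn volumes.

    Each household's total routes through its covered stores (rotating week
    by week so the whole store set is recoverable from the lines) and, for
    households with an uncovered share, through a private uncovered store.
    Product volumes follow the global mix exactly: week j carries product
    ``j mod P`` with volume ``total * w_p / n_p`` where ``n_p`` is the number
    of weeks assigned to product p — so every household's (and therefore the
    sample's) per-product volume shares equal the generator's weights.
    """
    n, P, W = cfg.n_households, cfg.n_products, N_WEEKS
    weights = sim["weights"]
    k, set_idx = sim["k"], sim["set_idx"]
    total = np.exp(sim["log_pc"]) * sim["households"]["size"].to_numpy()
    unc = sim["uncovered_share"]

    weeks = np.arange(1, W + 1)
    p_of_week = (weeks - 1) % P  # product index per week, same for everyone
    n_p = np.bincount(p_of_week, minlength=P).astype(float)
    week_share = weights[p_of_week] / n_p[p_of_week]  # (W,)

    store_col = np.take_along_axis(
        set_idx, ((weeks - 1)[None, :] % k[:, None]), axis=1
    )  # (n, W)

    hh_ids = sim["households"]["household_id"].to_numpy()
    hh_rep = np.repeat(hh_ids, W)
    week_rep = np.tile(weeks, n)
    prod_rep = np.tile(np.asarray(product_ids)[p_of_week], n)

    covered_vol = (total * (1.0 - unc))[:, None] * week_share[None, :]
    frames = [
        pd.DataFrame(
            {
                "household_id": hh_rep,
                "store_id": np.asarray(store_ids)[store_col.ravel()],
                "week_index": week_rep,
                "product_id": prod_rep,
                "volume_oz": covered_vol.ravel(),
            }
        )
    ]
    with_unc = np.flatnonzero(unc > 0)
    if with_unc.size:
        unc_vol = (total * unc)[with_unc, None] * week_share[None, :]
        frames.append(
            pd.DataFrame(
                {
                    "household_id": np.repeat(hh_ids[with_unc], W),
                    "store_id": np.repeat(
                        np.array([f"U-{h}" for h in hh_ids[with_unc]]), W
                    ),
                    "week_index": np.tile(weeks, with_unc.size),
                    "product_id": np.tile(np.asarray(product_ids)[p_of_week], with_unc.size),
                    "volume_oz": unc_vol.ravel(),
                }
            )
        )
    purchases = pd.concat(frames, ignore_index=True)
    return purchases.sort_values(
        ["household_id", "week_index", "store_id"], kind="stable"
    ).reset_index(drop=True)


def generate(cfg: GeneratorConfig) -> dict:
    """Emit a full synthetic dataset plus planted truth.

    Returns a dict with the five scanner/panel tables, a ``truth`` table
    (per-household true annual frequency, magnitude and expected log
    outcome), a ``truth_weekly`` table of true weekly magnitudes, and a
    ``meta`` dict recording the configuration and the product weights.
    Identical configurations and seeds produce identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    sim = _simulate(cfg, rng)
    S, P = cfg.n_stores, cfg.n_products
    store_ids = [f"S{i:03d}" for i in range(S)]
    product_ids = [f"P{i:03d}" for i in range(P)]

    stores = pd.DataFrame(
        {
            "store_id": store_ids,
            "retailer_code": [f"R{i % max(1, S // 2):02d}" for i in range(S)],
            "channel": rng.choice(CHANNELS, size=S, p=(0.70, 0.15, 0.15)),
            "metro": rng.choice(METRO_LEVELS, size=S, p=(0.9, 0.1)),
        }
    )
    products = pd.DataFrame(
        {
            "product_id": product_ids,
            "category": rng.choice(CATEGORIES, size=P, p=(0.62, 0.38)),
            "package_oz": rng.choice(_PACKAGE_OZ, size=P, p=_PACKAGE_P),
        }
    )
    prices = _emit_prices(cfg, sim["base"], sim["discounts"], store_ids, product_ids)
    purchases = _emit_purchases(cfg, sim, store_ids, product_ids)

    hh_ids = sim["households"]["household_id"]
    truth = pd.DataFrame(
        {
            "household_id": hh_ids,
            "frequency": sim["frequency"],
            "magnitude": sim["magnitude"],
            "expected_log_oz": sim["mu"],
        }
    )
    n, W = cfg.n_households, N_WEEKS
    truth_weekly = pd.DataFrame(
        {
            "household_id": np.repeat(hh_ids.to_numpy(), W),
            "week_index": np.tile(np.arange(1, W + 1), n),
            "magnitude": sim["weekly"].ravel(),
        }
    )
    tables = validate_tables(
        {
            "stores": stores,
            "prices": prices,
            "products": products,
            "households": sim["households"],
            "purchases": purchases,
        }
    )
    tables["truth"] = truth
    tables["truth_weekly"] = truth_weekly
    tables["meta"] = {
        "config": dataclasses.asdict(cfg),
        "product_weights": dict(zip(product_ids, sim["weights"])),
    }
    return tables


def write_dataset(dataset: dict, out_dir) -> None:
    """Write the generated tables plus truth as CSVs."""
    out_dir = Path(out_dir)
    write_tables(dataset, out_dir)
    dataset["truth"].to_csv(out_dir / "truth.csv", index=False)
    dataset["truth_weekly"].to_csv(out_dir / "truth_weekly.csv", index=False)


def verify_truth(
    dataset: dict,
    truth: pd.DataFrame | None = None,
    exposure_config: exposure_mod.ExposureConfig | None = None,
    tol: float = 1e-9,
) -> dict:
    """Recompute exposure from the emitted tables and compare with truth.

    Runs the exposure pipeline on the dataset under ``exposure_config``
    (default: the generator's own settings, under which truth is exact) and
    asserts weekly and annual agreement to ``tol``.  Raises
    :class:`ConsistencyError` naming the worst household and week on
    failure; returns a report with the maximal absolute deviations.
    """
    truth = dataset["truth"] if truth is None else truth
    if exposure_config is None:
        c = dataset["meta"]["config"]
        exposure_config = exposure_mod.ExposureConfig(
            promo_threshold=c["promo_threshold"],
            aggregation=c["aggregation"],
            weight_scheme="sample_volume",
        )
    derived = exposure_mod.compute_annual_exposure(dataset, exposure_config)

    weekly = derived["weekly"].merge(
        dataset["truth_weekly"],
        on=["household_id", "week_index"],
        suffixes=("_pipeline", "_truth"),
    )
    weekly_dev = (weekly["magnitude_pipeline"] - weekly["magnitude_truth"]).abs()
    if weekly_dev.max() > tol:
        worst = weekly.loc[weekly_dev.idxmax()]
        raise ConsistencyError(
            f"weekly exposure deviates from truth by {weekly_dev.max():.3e} "
            f"for household {worst['household_id']!r} week {int(worst['week_index'])}"
        )
    annual = derived["annual"].merge(
        truth, on="household_id", suffixes=("_pipeline", "_truth")
    )
    freq_dev = (annual["frequency_pipeline"] - annual["frequency_truth"]).abs()
    mag_dev = (annual["magnitude_pipeline"] - annual["magnitude_truth"]).abs()
    for name, dev in (("frequency", freq_dev), ("magnitude", mag_dev)):
        if dev.max() > tol:
            worst = annual.loc[dev.idxmax(), "household_id"]
            raise ConsistencyError(
                f"annual {name} deviates from truth by {dev.max():.3e} "
                f"for household {worst!r}"
            )
    return {
        "max_weekly_deviation": float(weekly_dev.max()),
        "max_frequency_deviation": float(freq_dev.max()),
        "max_magnitude_deviation": float(mag_dev.max()),
        "n_households": int(len(annual)),
    }
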