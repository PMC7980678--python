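"""Analytic cohort construction: inclusion filter, outcome, covariates, tables.

The analytic sample keeps households that made most (by default >= 80%) of
their sugar-sweetened-beverage purchase volume at stores covered by the
retailer price data, so that store prices represent the retail environment
the household actually shopped.  The outcome is annual per-capita purchase
volume: the household's total SSB ounces over the year — covered and
uncovered lines alike — divided by household size, log-transformed for
regression because of its right skew.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .scanner_model import INCOME_CATEGORIES

logger = logging.getLogger(__name__)

#: Midpoints of the household income brackets, used to derive income per
#: capita (midpoint / household size).  The open top bracket is top-coded at
#: its floor.
INCOME_MIDPOINTS = {
    "<25000": 12_500.0,
    "25000-34999": 29_500.0,
    "35000-49999": 42_000.0,
    "50000-69999": 59_500.0,
    "70000-99999": 84_500.0,
    ">=100000": 100_000.0,
}

#: Ordered income-per-capita bins; boundary values assign to the higher bin.
INCOME_PC_BINS = ("<=15000", "15001-30000", "30001-50000", ">=50000")
_INCOME_PC_EDGES = (15_000.0, 30_000.0, 50_000.0)

OZ_PER_SERVING = 12.0

#: Covariate columns summarized in the descriptive tables.
COVARIATE_BLOCKS = (
    "size_group",
    "income_category",
    "income_per_capita_bin",
    "male_head_age",
    "female_head_age",
    "male_head_education",
    "female_head_education",
    "male_head_occupation",
    "female_head_occupation",
    "children_present",
    "race",
    "hispanic",
    "region",
    "metro",
)


def apply_inclusion(linkage: pd.DataFrame, threshold: float = 0.80) -> pd.Index:
    """Households whose covered purchase share meets the coverage threshold.

    The boundary is inclusive (coverage of exactly 0.80 is retained at the
    default threshold).  Raises :class:`ConfigError` for thresholds outside
    (0, 1].
    """
    if not (0.0 < threshold <= 1.0):
        raise ConfigError(f"coverage threshold must be in (0, 1]; got {threshold}")
    keep = linkage["coverage"] >= threshold
    excluded = int((~keep).sum())
    logger.info(
        "inclusion at coverage >= %.2f: retained %d, excluded %d households",
        threshold,
        int(keep.sum()),
        excluded,
    )
    return pd.Index(linkage.loc[keep, "household_id"])


def retention_percent(n_retained: int, n_total: int) -> float:
    """Share of the panel retained by the filter, as a whole percent."""
    if n_total <= 0 or n_retained < 0 or n_retained > n_total:
        raise ValueError("need 0 <= n_retained <= n_total with n_total > 0")
    return float(round(100.0 * n_retained / n_total))


def annual_per_capita(
    purchases: pd.DataFrame, households: pd.DataFrame
) -> pd.DataFrame:
    """Annual per-capita purchase ounces per household.

    Sums *all* of a household's purchase lines (covered and uncovered — the
    inclusion filter conditions on coverage, the outcome does not discard the
    remainder) and divides by household size.  Households with no purchase
    lines are absent from the result.
    """
    totals = purchases.groupby("household_id", sort=True)["volume_oz"].sum()
    sizes = households.set_index("household_id")["size"]
    df = totals.rename("total_oz").reset_index()
    df["size"] = df["household_id"].map(sizes)
    if df["size"].isna().any():
        missing = df.loc[df["size"].isna(), "household_id"].iloc[0]
        raise ContractError(f"purchasing household {missing!r} not in household table")
    df["annual_oz"] = df["total_oz"] / df["size"]
    return df[["household_id", "annual_oz"]]


def oz_to_servings_per_week(annual_oz: float, decimals: int = 2) -> float:
    """Convert annual ounces to weekly 12-oz servings (annual_oz / (12*52))."""
    if annual_oz < 0:
        raise ValueError(f"annual_oz must be nonnegative; got {annual_oz}")
    return round(annual_oz / (OZ_PER_SERVING * 52.0), decimals)


def income_per_capita(income_category: str, size: int) -> float:
    """Bracket midpoint divided by household size."""
    if income_category not in INCOME_MIDPOINTS:
        raise ConfigError(f"unknown income category {income_category!r}")
    if size < 1:
        raise ContractError(f"household size must be >= 1; got {size}")
    return INCOME_MIDPOINTS[income_category] / size


def income_per_capita_bin(income_category: str, size: int) -> str:
    """Assign income per capita to one of the four ordered bins.

    Boundary values assign to the higher bin (e.g. exactly 50,000 falls in
    the top bin).
    """
    pc = income_per_capita(income_category, size)
    for edge, label in zip(_INCOME_PC_EDGES, INCOME_PC_BINS[:-1]):
        if pc < edge:
            return label
    return INCOME_PC_BINS[-1]


def quartile_sizes(n: int) -> tuple[int, int, int, int]:
    """Group sizes of a rank-based quartile split: as equal as possible,
    earlier groups never larger than later ones."""
    if n < 4:
        raise ContractError(f"need n >= 4 for a quartile split; got {n}")
    base, rem = divmod(n, 4)
    return tuple([base] * (4 - rem) + [base + 1] * rem)


def assign_quartiles(values) -> np.ndarray:
    """Rank-based quartile labels (1..4) for positive values.

    Ties are resolved by stable input order; group sizes differ by at most
    one and earlier groups are never larger than later ones.
    """
    v = np.asarray(values, dtype=float)
    sizes = quartile_sizes(len(v))
    order = np.argsort(v, kind="stable")
    labels = np.empty(len(v), dtype=np.int64)
    bounds = np.cumsum((0,) + sizes)
    for q in range(4):
        labels[order[bounds[q] : bounds[q + 1]]] = q + 1
    return labels


def size_group(size: int) -> str:
    if size <= 2:
        return str(size)
    if size <= 4:
        return "3-4"
    return "5+"


def build_cohort(
    tables: dict,
    annual_exposure: pd.DataFrame,
    included,
) -> pd.DataFrame:
    """Assemble the one-row-per-household analytic table.

    Joins the outcome (annual per-capita ounces over *all* purchase lines),
    the derived annual exposure, and the demographic covariates for the
    included households, adding the log outcome, income-per-capita bin,
    household-size group and outcome quartile.
    """
    included = set(included)
    purchases = tables["purchases"]
    purchases = purchases[purchases["household_id"].isin(included)]
    outcome = annual_per_capita(purchases, tables["households"])
    cohort = outcome.merge(annual_exposure, on="household_id", how="inner")
    cohort = cohort.merge(tables["households"], on="household_id", how="left")
    if (cohort["annual_oz"] <= 0).any():
        raise ContractError("annual_oz must be strictly positive for all households")
    cohort["log_annual_oz"] = np.log(cohort["annual_oz"])
    cohort["income_per_capita_bin"] = [
        income_per_capita_bin(c, s)
        for c, s in zip(cohort["income_category"], cohort["size"])
    ]
    cohort["size_group"] = cohort["size"].map(size_group)
    cohort["purchase_quartile"] = assign_quartiles(cohort["annual_oz"])
    return cohort.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Descriptive tables
# ---------------------------------------------------------------------------


def table_covariates_by_quartile(cohort: pd.DataFrame) -> pd.DataFrame:
    """Covariate counts and percentages by outcome quartile (long form)."""
    rows = []
    for cov in COVARIATE_BLOCKS:
        series = cohort[cov].astype(str)
        for level in sorted(series.unique()):
            mask = series == level
            row = {"covariate": cov, "level": level}
            for q in (1, 2, 3, 4):
                in_q = cohort["purchase_quartile"] == q
                n = int((mask & in_q).sum())
                row[f"q{q}_n"] = n
                row[f"q{q}_pct"] = round(100.0 * n / in_q.sum(), 1)
            row["total_n"] = int(mask.sum())
            row["total_pct"] = round(100.0 * mask.mean(), 1)
            rows.append(row)
    return pd.DataFrame(rows)


def _summary_row(label: str, values: pd.Series) -> dict:
    return {
        "group": label,
        "n": int(values.size),
        "mean": values.mean(),
        "sd": values.std(ddof=1),
        "median": values.median(),
        "p25": values.quantile(0.25),
        "p75": values.quantile(0.75),
    }


def table_outcome_by_exposure_quartile(
    cohort: pd.DataFrame,
    purchases: pd.DataFrame | None = None,
    products: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Outcome distribution overall and by exposure quartile.

    Reports mean/SD and median/IQR of annual per-capita ounces overall, by
    beverage category (when purchase lines and a product table are given),
    and within empirically computed quartiles of annual promotion frequency
    and magnitude.  Exposure-quartile boundaries are always computed from the
    data, never hard-coded.
    """
    rows = [_summary_row("overall", cohort["annual_oz"])]
    if purchases is not None and products is not None:
        cat = products.set_index("product_id")["category"]
        lines = purchases[purchases["household_id"].isin(set(cohort["household_id"]))]
        lines = lines.assign(category=lines["product_id"].map(cat))
        sizes = cohort.set_index("household_id")["size"]
        for level, sub in lines.groupby("category", sort=True):
            per_hh = sub.groupby("household_id")["volume_oz"].sum()
            per_capita = per_hh / per_hh.index.map(sizes)
            rows.append(_summary_row(f"category:{level}", per_capita))
    for exp_col in ("frequency", "magnitude"):
        q = assign_quartiles(cohort[exp_col])
        for i in (1, 2, 3, 4):
            rows.append(
                _summary_row(f"{exp_col}_q{i}", cohort.loc[q == i, "annual_oz"])
            )
    return pd.DataFrame(rows)


def table_exposure_by_covariate(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of annual promotion frequency and magnitude by covariate level."""
    rows = [
        {
            "covariate": "overall",
            "level": "",
            "n": len(cohort),
            "frequency_mean": cohort["frequency"].mean(),
            "frequency_sd": cohort["frequency"].std(ddof=1),
            "magnitude_mean": cohort["magnitude"].mean(),
            "magnitude_sd": cohort["magnitude"].std(ddof=1),
        }
    ]
    for cov in COVARIATE_BLOCKS:
        series = cohort[cov].astype(str)
        for level in sorted(series.unique()):
            sub = cohort[series == level]
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "n": len(sub),
                    "frequency_mean": sub["frequency"].mean(),
                    "frequency_sd": sub["frequency"].std(ddof=1),
                    "magnitude_mean": sub["magnitude"].mean(),
                    "magnitude_sd": sub["magnitude"].std(ddof=1),
                }
            )
    return pd.DataFrame(rows)


def descriptive_tables(
    cohort: pd.DataFrame,
    purchases: pd.DataFrame | None = None,
    products: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """The three descriptive tables of the study layout."""
    return {
        "covariates_by_quartile": table_covariates_by_quartile(cohort),
        "outcome_by_exposure": table_outcome_by_exposure_quartile(
            cohort, purchases, products
        ),
        "exposure_by_covariate": table_exposure_by_covariate(cohort),
    }
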