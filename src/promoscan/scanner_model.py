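"""Domain tables for linked retail-scanner and consumer-panel data.

The analysis consumes four delimited tables plus an optional product table:

* ``stores.csv`` — one row per store covered by the retailer price database
  (``store_id``, ``retailer_code``, ``channel``, ``metro``).
* ``prices.csv`` — one row per store x week x product observation of the unit
  price in currency per fluid ounce (``store_id``, ``week_index``,
  ``product_id``, ``unit_price``).
* ``households.csv`` — one row per panel household with demographic
  covariates.
* ``purchases.csv`` — one scanned sugar-sweetened-beverage purchase line
  (``household_id``, ``store_id``, ``week_index``, ``product_id``,
  ``volume_oz``).  The store may be *uncovered*, i.e. absent from the store
  table; such lines count toward the outcome but carry no price information.
* ``products.csv`` (optional) — beverage category and package size per
  product.

The year is represented as 52 week bins of 7 days; the final two days of the
calendar year fold into week 52, so every annual denominator is 52.

All identifiers are opaque strings.  Unit prices are stored per fluid ounce so
discounts are comparable across package sizes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

N_WEEKS = 52

# ---------------------------------------------------------------------------
# Closed enums
# ---------------------------------------------------------------------------

CHANNELS = ("food", "drug", "mass")
METRO_LEVELS = ("metropolitan", "urban_rural")
CATEGORIES = ("carbonated_soft_drink", "fruit_drink")

#: Six household income brackets, ordered low to high.
INCOME_CATEGORIES = (
    "<25000",
    "25000-34999",
    "35000-49999",
    "50000-69999",
    "70000-99999",
    ">=100000",
)

HEAD_AGES = ("<35", "35-54", "55+", "no_head")
HEAD_EDUCATIONS = ("high_school_or_less", "some_college", "college_grad", "no_head")
HEAD_OCCUPATIONS = ("white_collar", "blue_collar", "other", "no_head")
RACES = ("white", "black", "other")

#: The nine US census divisions.
REGIONS = (
    "new_england",
    "middle_atlantic",
    "east_north_central",
    "west_north_central",
    "south_atlantic",
    "east_south_central",
    "west_south_central",
    "mountain",
    "pacific",
)

HOUSEHOLD_SIZE_GROUPS = ("1", "2", "3-4", "5+")

_HEAD_FIELDS = {
    "male": ("male_head_age", "male_head_education", "male_head_occupation"),
    "female": ("female_head_age", "female_head_education", "female_head_occupation"),
}

# ---------------------------------------------------------------------------
# Schemas: table name -> ordered column spec
#   kind: "str" | "int" | "float" | "bool" | tuple of allowed string levels
# ---------------------------------------------------------------------------

SCHEMAS: dict[str, dict[str, object]] = {
    "stores": {
        "store_id": "str",
        "retailer_code": "str",
        "channel": CHANNELS,
        "metro": METRO_LEVELS,
    },
    "prices": {
        "store_id": "str",
        "week_index": "int",
        "product_id": "str",
        "unit_price": "float",
    },
    "products": {
        "product_id": "str",
        "category": CATEGORIES,
        "package_oz": "float",
    },
    "households": {
        "household_id": "str",
        "size": "int",
        "income_category": INCOME_CATEGORIES,
        "male_head_age": HEAD_AGES,
        "female_head_age": HEAD_AGES,
        "male_head_education": HEAD_EDUCATIONS,
        "female_head_education": HEAD_EDUCATIONS,
        "male_head_occupation": HEAD_OCCUPATIONS,
        "female_head_occupation": HEAD_OCCUPATIONS,
        "children_present": "bool",
        "race": RACES,
        "hispanic": "bool",
        "region": REGIONS,
        "metro": METRO_LEVELS,
    },
    "purchases": {
        "household_id": "str",
        "store_id": "str",
        "week_index": "int",
        "product_id": "str",
        "volume_oz": "float",
    },
}

TABLE_FILES = {name: f"{name}.csv" for name in SCHEMAS}

_BOOL_MAP = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


def _coerce_column(table: str, col: str, kind, series: pd.Series) -> pd.Series:
    if kind == "str":
        return series.astype(str)
    if kind == "int":
        try:
            return series.astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise IntegrityError(f"{table}.{col}: non-integer value ({exc})") from exc
    if kind == "float":
        try:
            return series.astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise IntegrityError(f"{table}.{col}: non-numeric value ({exc})") from exc
    if kind == "bool":
        if series.dtype == bool:
            return series
        lowered = series.astype(str).str.lower().map(_BOOL_MAP)
        if lowered.isna().any():
            bad = series[lowered.isna()].index[0]
            raise IntegrityError(f"{table}.{col}: unparseable boolean at row {bad}")
        return lowered.astype(bool)
    # closed enum
    s = series.astype(str)
    bad = ~s.isin(kind)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise IntegrityError(
            f"{table}.{col}: value {s.iloc[row]!r} at row {row} not in {kind}"
        )
    return s


def validate_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a raw table against its schema.

    Returns a typed copy.  Raises :class:`SchemaError` for missing columns and
    :class:`IntegrityError` for invariant violations.
    """
    schema = SCHEMAS[name]
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"table {name!r} is missing required column {col!r}")
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        out[col] = _coerce_column(name, col, kind, df[col])

    if name == "stores":
        dup = out["store_id"].duplicated()
        if dup.any():
            raise IntegrityError(
                f"stores: duplicate store_id {out.loc[dup, 'store_id'].iloc[0]!r}"
            )
    if name == "prices":
        bad = out["unit_price"] <= 0
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise IntegrityError(f"prices: nonpositive unit_price at row {row}")
        _check_weeks("prices", out["week_index"])
        dup = out.duplicated(subset=["store_id", "week_index", "product_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            key = out.iloc[row][["store_id", "week_index", "product_id"]].tolist()
            raise IntegrityError(
                f"prices: duplicate (store, week, product) row for {key} at row {row}"
            )
    if name == "products":
        bad = out["package_oz"] <= 0
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise IntegrityError(f"products: nonpositive package_oz at row {row}")
    if name == "purchases":
        bad = out["volume_oz"] <= 0
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise IntegrityError(f"purchases: nonpositive volume_oz at row {row}")
        _check_weeks("purchases", out["week_index"])
    if name == "households":
        bad = out["size"] < 1
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise IntegrityError(f"households: size < 1 at row {row}")
        # "no head" must be consistent across the age/education/occupation
        # triple for each head of household.
        for head, fields in _HEAD_FIELDS.items():
            absent = out[fields[0]] == "no_head"
            for f in fields[1:]:
                mismatch = absent != (out[f] == "no_head")
                if mismatch.any():
                    row = int(np.flatnonzero(mismatch.to_numpy())[0])
                    raise IntegrityError(
                        f"households: inconsistent 'no_head' status between "
                        f"{fields[0]} and {f} at row {row} (no {head} head must "
                        "be absent in all three fields)"
                    )
    return out


def _check_weeks(table: str, weeks: pd.Series) -> None:
    bad = (weeks < 1) | (weeks > N_WEEKS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise IntegrityError(
            f"{table}: week_index {weeks.iloc[row]} outside 1..{N_WEEKS} at row {row}"
        )


def validate_tables(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Validate a dict of raw tables; ``products`` may be absent or None."""
    out = {}
    for name in SCHEMAS:
        df = tables.get(name)
        if df is None:
            if name == "products":
                out[name] = None
                continue
            raise SchemaError(f"required table {name!r} is missing")
        out[name] = validate_table(name, df)
    return out


def read_tables(data_dir) -> dict[str, pd.DataFrame]:
    """Read and validate the scanner/panel tables from a directory of CSVs.

    ``products.csv`` is optional; the corresponding entry is None when absent.
    """
    data_dir = Path(data_dir)
    raw = {}
    for name, fname in TABLE_FILES.items():
        path = data_dir / fname
        if not path.exists():
            if name == "products":
                raw[name] = None
                continue
            raise SchemaError(f"missing input file: {path}")
        raw[name] = pd.read_csv(path, dtype=str, keep_default_na=False)
    tables = validate_tables(raw)
    for name, df in tables.items():
        if df is not None:
            logger.info("read %s: %d rows", name, len(df))
    return tables


def write_tables(tables: dict[str, pd.DataFrame], data_dir) -> None:
    """Write tables as UTF-8 comma-delimited CSVs (round-trips bit-exactly)."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    for name in SCHEMAS:
        df = tables.get(name)
        if df is None:
            continue
        df.to_csv(data_dir / TABLE_FILES[name], index=False)


def linkage_report(purchases: pd.DataFrame, stores: pd.DataFrame) -> pd.DataFrame:
    """Per-household coverage of purchase volume by the retailer price data.

    Returns one row per purchasing household with ``total_oz``, ``covered_oz``
    and ``coverage = covered_oz / total_oz`` in [0, 1].  A purchase is covered
    when its store appears in the store table (i.e. the panel trip links to
    the retailer database by a common store identifier).  Households with zero
    total ounces cannot occur because purchase volumes are strictly positive.
    """
    covered_ids = set(stores["store_id"])
    df = purchases[["household_id", "store_id", "volume_oz"]].copy()
    df["covered_oz"] = df["volume_oz"].where(df["store_id"].isin(covered_ids), 0.0)
    rep = (
        df.groupby("household_id", sort=True)
        .agg(total_oz=("volume_oz", "sum"), covered_oz=("covered_oz", "sum"))
        .reset_index()
    )
    rep["coverage"] = rep["covered_oz"] / rep["total_oz"]
    return rep
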