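"""End-to-end study orchestration and the sensitivity grid.

One call evaluates every cell of the sensitivity grid — promotion threshold
{2%, 5%, 10%, 15%} x store aggregation {largest, average} x coverage
threshold {60%, 70%, 80%, 90%} — and fits both exposures in each cell.  The
main-analysis cell (threshold 5%, largest, coverage 80%) is always present
and flagged.  Exposure tables are cached per (threshold, aggregation) and
reused across coverage cells, because the exposure derivation does not
depend on the inclusion filter.  A failing cell is recorded and skipped; the
rest of the grid still runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError
from .cohort import apply_inclusion, build_cohort, descriptive_tables
from .exposure import ExposureConfig, compute_annual_exposure
from .inference import ModelSpec, fit_interaction, fit_main, percent_change
from .scanner_model import linkage_report

logger = logging.getLogger(__name__)

MAIN_CELL = (0.05, "largest", 0.80)


@dataclass(frozen=True)
class RunManifest:
    thresholds: tuple = (0.02, 0.05, 0.10, 0.15)
    aggregations: tuple = ("largest", "average")
    coverages: tuple = (0.60, 0.70, 0.80, 0.90)
    exposures: tuple = ("frequency", "magnitude")
    modifiers: tuple = ()
    seed: int = 0

    def __post_init__(self):
        thr, agg, cov = MAIN_CELL
        if thr not in self.thresholds or agg not in self.aggregations or cov not in self.coverages:
            raise ConfigError(
                f"the main-analysis cell {MAIN_CELL} must be present in the grid"
            )


def _fit_row(cell, exposure, result, is_main):
    thr, agg, cov = cell
    return {
        "threshold": thr,
        "aggregation": agg,
        "coverage": cov,
        "exposure": exposure,
        "n": result.n,
        "beta": result.beta,
        "se": result.se,
        "exp_estimate": result.exp_estimate,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "p_value": result.p_value,
        "pct_change": percent_change(result.exp_estimate),
        "is_main": is_main,
    }


def run_study(tables: dict, manifest: RunManifest | None = None) -> dict:
    """Evaluate the full grid on validated tables.

    Returns a bundle with a ``fits`` table (one row per grid cell and
    exposure), descriptive tables for the main cell, interaction fits for
    any requested modifiers (main cell only), a failure list and a run log.
    """
    manifest = manifest or RunManifest()
    linkage = linkage_report(tables["purchases"], tables["stores"])
    included = {
        cov: apply_inclusion(linkage, cov) for cov in sorted(manifest.coverages)
    }

    fit_rows, failures = [], []
    bundle = {"manifest": manifest, "linkage": linkage}
    interaction_rows = []

    for thr in sorted(manifest.thresholds):
        for agg in sorted(manifest.aggregations):
            config = ExposureConfig(promo_threshold=thr, aggregation=agg)
            try:
                derived = compute_annual_exposure(tables, config)
            except Exception as exc:  # noqa: BLE001 - cell isolation
                for cov in sorted(manifest.coverages):
                    failures.append(
                        {"cell": (thr, agg, cov), "stage": "exposure", "error": str(exc)}
                    )
                continue
            for cov in sorted(manifest.coverages):
                cell = (thr, agg, cov)
                is_main = cell == MAIN_CELL
                try:
                    cohort = build_cohort(tables, derived["annual"], included[cov])
                    for exposure in manifest.exposures:
                        res = fit_main(cohort, ModelSpec(exposure=exposure))
                        fit_rows.append(_fit_row(cell, exposure, res, is_main))
                    if is_main:
                        bundle["main_cohort"] = cohort
                        bundle["tables"] = descriptive_tables(
                            cohort, tables["purchases"], tables.get("products")
                        )
                        for modifier in manifest.modifiers:
                            for exposure in manifest.exposures:
                                spec = ModelSpec(exposure=exposure, modifier=modifier)
                                ires = fit_interaction(cohort, spec)
                                for _, srow in ires.strata.iterrows():
                                    interaction_rows.append(
                                        {
                                            "exposure": exposure,
                                            "modifier": modifier,
                                            "level": srow["level"],
                                            "n": srow["n"],
                                            "exp_estimate": srow["exp_estimate"],
                                            "ci_low": srow["ci_low"],
                                            "ci_high": srow["ci_high"],
                                            "interaction_p": ires.interaction_p,
                                        }
                                    )
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    failures.append({"cell": cell, "stage": "fit", "error": str(exc)})
                    logger.warning("cell %s failed: %s", cell, exc)

    bundle["fits"] = pd.DataFrame(fit_rows)
    bundle["interactions"] = pd.DataFrame(interaction_rows)
    bundle["failures"] = failures
    bundle["log"] = {
        "promoscan_version": __version__,
        "seed": manifest.seed,
        "manifest": dataclasses.asdict(manifest),
        "n_cells": len(manifest.thresholds)
        * len(manifest.aggregations)
        * len(manifest.coverages),
        "n_failures": len(failures),
    }
    return bundle


def sensitivity_report(bundle: dict) -> pd.DataFrame:
    """Side-by-side exponentiated estimates for the two aggregation modes.

    One row per (threshold, coverage, exposure) with the estimate under the
    largest-discount and average-discount definitions, and a flag for whether
    the average-mode estimate is attenuated (<= the largest-mode estimate) —
    the expected direction, reported not asserted.  Cells missing from the
    bundle yield a partial report with a warning.
    """
    fits = bundle["fits"]
    rows = []
    if fits.empty:
        logger.warning("sensitivity report: no fitted cells in bundle")
        return pd.DataFrame(rows)
    for (thr, cov, exposure), sub in fits.groupby(
        ["threshold", "coverage", "exposure"], sort=True
    ):
        by_agg = sub.set_index("aggregation")["exp_estimate"]
        row = {
            "threshold": thr,
            "coverage": cov,
            "exposure": exposure,
            "exp_largest": by_agg.get("largest"),
            "exp_average": by_agg.get("average"),
        }
        if row["exp_largest"] is None or row["exp_average"] is None:
            logger.warning(
                "sensitivity report: missing aggregation mode for cell %s",
                (thr, cov, exposure),
            )
            row["average_attenuated"] = None
        else:
            row["average_attenuated"] = bool(row["exp_average"] <= row["exp_largest"])
        rows.append(row)
    return pd.DataFrame(rows)


def write_bundle(bundle: dict, out_dir) -> None:
    """Write the results bundle as CSVs plus a plain-text run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["fits"].to_csv(out_dir / "fits.csv", index=False)
    sensitivity_report(bundle).to_csv(out_dir / "sensitivity.csv", index=False)
    if not bundle["interactions"].empty:
        bundle["interactions"].to_csv(out_dir / "interactions.csv", index=False)
    for name, df in bundle.get("tables", {}).items():
        df.to_csv(out_dir / f"table_{name}.csv", index=False)
    with open(out_dir / "run_log.txt", "w", encoding="utf-8") as fh:
        for key, value in sorted(bundle["log"].items()):
            fh.write(f"{key}: {value}\n")
        for failure in bundle["failures"]:
            fh.write(f"FAILED {failure['cell']} at {failure['stage']}: {failure['error']}\n")
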