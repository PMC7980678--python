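"""Log-linear purchase models and subgroup interaction analyses.

The core model is an ordinary least squares regression of the log-transformed
annual per-capita purchase volume on one promotion exposure plus dummy-coded
household covariates:

    ln(annual_oz_i) = alpha + beta * x_i + gamma' z_i + eps_i

where x is annual promotion frequency multiplied by 10 (so exp(beta) is the
multiplicative change per 10-percentage-point increase in frequency) or
annual promotion magnitude multiplied by 100 (exp(beta) per 1-percentage-
point increase in magnitude).  The exponentiated coefficient is reported with
a classical 95% confidence interval; percent change = 100 * (exp(beta) - 1).

Subgroup analyses add exposure x modifier interaction terms to a single
model.  Per-stratum slopes are reconstructed as exp(main + interaction) with
delta-method standard errors, and heterogeneity is judged by a Type-3 test:
the extra-sum-of-squares partial F-test of the whole interaction block
against the main-effects model.

Covariates are dummy coded against the first listed level of each block
(exposure-slope inference is invariant to the reference choice).  Because a
household without a male (or female) head is "absent" simultaneously in the
age, education and occupation fields, a single no-head indicator per head is
used and the education/occupation blocks are coded only among households
with that head; repeating the no-head level in every block would make the
design singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .errors import ConfigError, ContractError, SingularDesignError
from .cohort import INCOME_PC_BINS
from .scanner_model import (
    HEAD_AGES,
    HEAD_EDUCATIONS,
    HEAD_OCCUPATIONS,
    HOUSEHOLD_SIZE_GROUPS,
    METRO_LEVELS,
    RACES,
    REGIONS,
)

EXPOSURES = ("frequency", "magnitude")
EXPOSURE_SCALES = {"frequency": 10.0, "magnitude": 100.0}

#: Effect modifiers available for interaction models, mapping the public name
#: to (cohort column, ordered levels).
MODIFIERS = {
    "income_per_capita": ("income_per_capita_bin", INCOME_PC_BINS),
    "female_head_education": ("female_head_education", HEAD_EDUCATIONS),
    "race": ("race", RACES),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which exposure to fit and (optionally) which modifier to interact."""

    exposure: str = "frequency"
    modifier: str | None = None

    def __post_init__(self):
        if self.exposure not in EXPOSURES:
            raise ConfigError(f"exposure must be one of {EXPOSURES}")
        if self.modifier is not None and self.modifier not in MODIFIERS:
            raise ConfigError(f"modifier must be one of {tuple(MODIFIERS)} or None")

    @property
    def exposure_scale(self) -> float:
        return EXPOSURE_SCALES[self.exposure]

    @property
    def exposure_column(self) -> str:
        scale = int(self.exposure_scale)
        return f"promotion_{self.exposure}_x{scale}"


@dataclass
class FitResult:
    """Result of a (possibly interacted) log-linear purchase model."""

    exposure: str
    exposure_scale: float
    beta: float
    se: float
    p_value: float
    exp_estimate: float
    ci_low: float
    ci_high: float
    n: int
    params: pd.Series
    modifier: str | None = None
    interaction_p: float | None = None
    strata: pd.DataFrame | None = field(default=None)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

_SIMPLE_BLOCKS = (
    ("size_group", HOUSEHOLD_SIZE_GROUPS),
    ("income_per_capita_bin", INCOME_PC_BINS),
    ("race", RACES),
    ("region", REGIONS),
    ("metro", METRO_LEVELS),
)


def _add_dummies(X, series, levels, prefix):
    for level in levels[1:]:
        X[f"{prefix}[{level}]"] = (series == level).astype(float)


def build_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Covariate design matrix (constant plus dummy columns).

    Reference levels are the first listed category of each block.  Each head
    of household contributes one no-head indicator; the head's age (ref <35),
    education (ref high school or less) and occupation (ref white collar)
    dummies are zero for households without that head.
    """
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    for col, levels in _SIMPLE_BLOCKS:
        _add_dummies(X, cohort[col], levels, col)
    X["children_present"] = cohort["children_present"].astype(float)
    for head in ("male", "female"):
        age = cohort[f"{head}_head_age"]
        X[f"no_{head}_head"] = (age == "no_head").astype(float)
        _add_dummies(X, age, HEAD_AGES[:-1], f"{head}_head_age")
        _add_dummies(
            X, cohort[f"{head}_head_education"], HEAD_EDUCATIONS[:-1],
            f"{head}_head_education",
        )
        _add_dummies(
            X, cohort[f"{head}_head_occupation"], HEAD_OCCUPATIONS[:-1],
            f"{head}_head_occupation",
        )
    return X


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Names of columns that do not increase the rank of the design."""
    arr = np.asarray(X, dtype=float)
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [X.columns[piv[i]] for i in range(rank, arr.shape[1])]


def fit_ols(y: pd.Series, X: pd.DataFrame):
    """Least-squares fit with an explicit rank check.

    Raises :class:`SingularDesignError` naming the linearly dependent
    columns when the design is rank deficient.
    """
    dependent = _dependent_columns(X)
    if dependent:
        raise SingularDesignError(dependent)
    if len(y) <= X.shape[1]:
        raise ContractError(
            f"n = {len(y)} does not exceed the parameter count {X.shape[1]}"
        )
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def _prepare(cohort: pd.DataFrame, spec: ModelSpec):
    needed = ["annual_oz", "log_annual_oz", spec.exposure] + [
        c for c, _ in _SIMPLE_BLOCKS
    ] + ["children_present"] + [
        f"{h}_head_{f}" for h in ("male", "female") for f in ("age", "education", "occupation")
    ]
    data = cohort.dropna(subset=[c for c in needed if c in cohort.columns])
    if (data["annual_oz"] <= 0).any():
        raise ContractError("annual_oz must be strictly positive (log undefined)")
    X = build_design(data)
    x_exp = data[spec.exposure].astype(float) * spec.exposure_scale
    X.insert(1, spec.exposure_column, x_exp)
    y = data["log_annual_oz"]
    return data, y, X


def _exp_ci(beta, se, df_resid):
    tcrit = scipy.stats.t.ppf(0.975, df_resid)
    return float(np.exp(beta - tcrit * se)), float(np.exp(beta + tcrit * se))


def fit_main(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the adjusted log-linear model for one exposure.

    Complete-case analysis on all model variables; the exposure enters on its
    reporting scale (x10 for frequency, x100 for magnitude).
    """
    data, y, X = _prepare(cohort, spec)
    res = fit_ols(y, X)
    name = spec.exposure_column
    beta = float(res.params[name])
    se = float(res.bse[name])
    lo, hi = _exp_ci(beta, se, res.df_resid)
    return FitResult(
        exposure=spec.exposure,
        exposure_scale=spec.exposure_scale,
        beta=beta,
        se=se,
        p_value=float(res.pvalues[name]),
        exp_estimate=float(np.exp(beta)),
        ci_low=lo,
        ci_high=hi,
        n=int(res.nobs),
        params=res.params,
    )


def fit_interaction(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Single model with exposure x modifier interaction terms.

    Per-stratum exponentiated slopes are exp(main + interaction) with
    delta-method confidence intervals; the interaction p-value is the Type-3
    (extra-sum-of-squares) partial F-test of the full interaction block.
    """
    if spec.modifier is None:
        raise ConfigError("fit_interaction requires a modifier in the ModelSpec")
    mod_col, levels = MODIFIERS[spec.modifier]
    data, y, X_main = _prepare(cohort, spec)
    mod = data[mod_col].astype(str)
    counts = {lv: int((mod == lv).sum()) for lv in levels}
    for lv, n_lv in counts.items():
        if n_lv == 0:
            raise ContractError(
                f"empty stratum: modifier {spec.modifier!r} level {lv!r} has no households"
            )
    name = spec.exposure_column
    X_full = X_main.copy()
    inter_cols = []
    for lv in levels[1:]:
        col = f"{name}:{mod_col}[{lv}]"
        X_full[col] = X_main[name] * (mod == lv).astype(float)
        inter_cols.append(col)
    full = fit_ols(y, X_full)
    reduced = fit_ols(y, X_main)
    f_stat, inter_p, _ = full.compare_f_test(reduced)

    cov = full.cov_params()
    tcrit = scipy.stats.t.ppf(0.975, full.df_resid)
    rows = []
    for lv in levels:
        if lv == levels[0]:
            b = float(full.params[name])
            var = float(cov.loc[name, name])
        else:
            col = f"{name}:{mod_col}[{lv}]"
            b = float(full.params[name] + full.params[col])
            var = float(
                cov.loc[name, name] + cov.loc[col, col] + 2.0 * cov.loc[name, col]
            )
        se_lv = np.sqrt(var)
        rows.append(
            {
                "level": lv,
                "n": counts[lv],
                "beta": b,
                "se": se_lv,
                "exp_estimate": float(np.exp(b)),
                "ci_low": float(np.exp(b - tcrit * se_lv)),
                "ci_high": float(np.exp(b + tcrit * se_lv)),
            }
        )

    beta = float(full.params[name])
    se = float(full.bse[name])
    lo, hi = _exp_ci(beta, se, full.df_resid)
    return FitResult(
        exposure=spec.exposure,
        exposure_scale=spec.exposure_scale,
        beta=beta,
        se=se,
        p_value=float(full.pvalues[name]),
        exp_estimate=float(np.exp(beta)),
        ci_low=lo,
        ci_high=hi,
        n=int(full.nobs),
        params=full.params,
        modifier=spec.modifier,
        interaction_p=float(inter_p),
        strata=pd.DataFrame(rows),
    )


def percent_change(exp_estimate: float, decimals: int = 1) -> float:
    """Percent change implied by an exponentiated coefficient.

    ``100 * (exp_estimate - 1)``, rounded to the reporting precision
    (1 decimal by default).  Note the asymmetry of the log scale:
    percent_change(1/x) != -percent_change(x) except at x = 1.
    """
    if exp_estimate <= 0:
        raise ValueError(f"exp_estimate must be positive; got {exp_estimate}")
    return round(100.0 * (exp_estimate - 1.0), decimals)
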