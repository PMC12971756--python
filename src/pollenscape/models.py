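"""Single-predictor model comparison by AICc and Akaike weights.

Each response variable (proportion of high-mobility hummingbirds,
pollen-pool haplotype diversity h, biparental inbreeding t_m - t_s) is
regressed on each connectivity metric in turn.  Proportions are
arcsine-square-root transformed; all variables are standardized after
transformation so slopes are beta coefficients.  Competing metrics are
ranked within a model set (the 3 intra-patch metrics, or the 12 local
metrics, per response) by AICc, with relative support expressed as
Akaike weights

    w_m = exp(-dAICc_m / 2) / sum_n exp(-dAICc_n / 2)

and factor-level support as the summed weights over all models sharing
a level (habitat definition, distance weighting, gap-crossing mode).
Intra-patch and local model sets are never mixed: the metrics are
alternative single-predictor explanations, not additive terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectivity import (
    BROAD,
    KERNEL,
    LOCAL,
    INTRA_PATCH,
    MetricSpec,
    NARROW,
    PROBABILISTIC,
    THRESHOLD,
    UNLIMITED,
    UNWEIGHTED,
)

RESPONSES = ("prop_high_mobility", "h", "tm_minus_ts")
#: responses constrained to [0, 1], transformed before standardization
PROPORTION_RESPONSES = ("prop_high_mobility", "h")

FACTORS = {
    "habitat_def": (NARROW, BROAD),
    "weighting": (UNWEIGHTED, KERNEL),
    "gap_mode": (UNLIMITED, THRESHOLD, PROBABILISTIC),
}


class DegenerateInputError(ValueError):
    """A constant vector where variation is required."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit."""


@dataclass(frozen=True)
class ModelComparisonRow:
    """One fitted simple regression in a model-comparison table."""

    response: str
    metric: str
    n: int
    beta: float
    se: float
    r2: float
    aicc: float
    delta_aicc: float = math.nan
    weight: float = math.nan


def arcsine_sqrt(x) -> np.ndarray | float:
    """Variance-stabilizing transform for proportions: asin(sqrt(x))."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to sample standard deviation 1 (n-1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("standardization needs at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (arr - arr.mean()) / sd


def fit_simple_ols(x, y) -> tuple[float, float, float, float, int]:
    """Least-squares fit of y on x with intercept.

    Returns (slope, slope SE, unadjusted R^2, Gaussian log-likelihood
    with the ML variance estimate RSS/n, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need at least 4 observations, got {n}")
    if x.std(ddof=0) == 0:
        raise DegenerateInputError("predictor has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return (
        float(res.params[1]),
        float(res.bse[1]),
        float(res.rsquared),
        float(res.llf),
        n,
    )


def aicc(loglik: float, n: int, k: int = 3) -> float:
    """Small-sample corrected Akaike information criterion.

    k = 3 for the simple regression: intercept, slope, residual variance.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights of a model set; invariant to a constant AICc shift."""
    arr = np.asarray(aicc_values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty model set")
    if not np.all(np.isfinite(arr)):
        raise ValueError("AICc values must be finite")
    delta = arr - arr.min()
    e = np.exp(-delta / 2.0)
    return e / e.sum()


def summed_factor_weights(rows: pd.DataFrame, factor: str) -> dict[str, float]:
    """Sum of Akaike weights over all local models sharing a factor level.

    ``rows`` must be the complete 12-model local set for one response,
    with columns ``habitat_def``, ``weighting``, ``gap_mode``, ``weight``.
    Level sums partition the unit total weight.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    levels = FACTORS[factor]
    combos = set(zip(rows["habitat_def"], rows["weighting"], rows["gap_mode"]))
    if len(rows) != 12 or len(combos) != 12:
        raise ValueError("rows must be the complete 2x2x3 local factorial")
    return {
        level: float(rows.loc[rows[factor] == level, "weight"].sum())
        for level in levels
    }


def _transform_response(name: str, values: np.ndarray) -> np.ndarray:
    if name in PROPORTION_RESPONSES:
        return arcsine_sqrt(values)
    return values


def compare_metrics(
    response_values: np.ndarray,
    response_name: str,
    metrics: pd.DataFrame,
) -> pd.DataFrame:
    """Rank a model set: one simple regression per metric column set.

    ``metrics`` holds one row per site (aligned with
    ``response_values``) and one column per metric, already on the scale
    to be standardized (intra-patch metrics log-transformed upstream).
    """
    y = standardize(_transform_response(response_name, np.asarray(response_values, float)))
    rows = []
    for name in metrics.columns:
        x = standardize(metrics[name].to_numpy())
        beta, se, r2, llf, n = fit_simple_ols(x, y)
        rows.append(
            {
                "response": response_name,
                "metric": name,
                "n": n,
                "beta": beta,
                "se": se,
                "r2": r2,
                "aicc": aicc(llf, n),
            }
        )
    out = pd.DataFrame(rows)
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    out["weight"] = akaike_weights(out["aicc"].to_numpy())
    return out


def compare_all(responses: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Full model-comparison table over responses and both metric scales.

    ``responses``: site_id + response columns (NaN = site not measured).
    ``metrics``: long format with columns site_id, scale, habitat_def,
    weighting, gap_mode, variant, value_ha, transformed.  Intra-patch
    and local sets are ranked separately per response.
    """
    out_frames = []
    for response in RESPONSES:
        if response not in responses.columns:
            continue
        resp = responses[["site_id", response]].dropna()
        for scale in (INTRA_PATCH, LOCAL):
            sub = metrics[metrics["scale"] == scale]
            if sub.empty:
                continue
            if scale == INTRA_PATCH:
                sub = sub.assign(metric=sub["variant"])
            else:
                sub = sub.assign(
                    metric=sub["habitat_def"] + ":" + sub["weighting"] + ":" + sub["gap_mode"]
                )
            wide = sub.pivot(index="site_id", columns="metric", values="transformed")
            merged = resp.merge(wide, left_on="site_id", right_index=True).dropna()
            if len(merged) < 4:
                raise InsufficientDataError(
                    f"response {response!r} x scale {scale!r}: "
                    f"only {len(merged)} sites shared"
                )
            table = compare_metrics(
                merged[response].to_numpy(), response, merged.drop(columns=["site_id", response])
            )
            table.insert(1, "scale", scale)
            if scale == LOCAL:
                parts = table["metric"].str.split(":", expand=True)
                table["habitat_def"], table["weighting"], table["gap_mode"] = (
                    parts[0],
                    parts[1],
                    parts[2],
                )
            out_frames.append(table)
    return pd.concat(out_frames, ignore_index=True)
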