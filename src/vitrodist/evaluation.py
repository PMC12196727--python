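"""Prediction–observation comparison on the log10 scale.

Accuracy is summarized by the mean absolute error (MAE) and bias by the mean
error (ME), both on log10-transformed values; association by Pearson's r (on
logs) and Spearman's ρ.  Optional weights (the inverse-variance use case)
apply to all four statistics.  Censored bound-fraction measurements reported
as "<10" / ">99" % bound are replaced by the interval midpoints 5% and
99.5%, i.e. unbound fractions 0.95 and 0.005.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import EvaluationConfig
from .errors import ValidationError, VitrodistError

CENSOR_NONE = "none"
CENSOR_BELOW = "below_lower"
CENSOR_ABOVE = "above_upper"

ENDPOINTS = ("f_free_media", "a_media", "a_cell")


@dataclass
class ObservationRecord:
    """One measured endpoint for one chemical in one test system."""

    chemical_id: str
    endpoint: str
    value: float
    censor: str = CENSOR_NONE
    timepoint: float = 24.0  # h
    system_id: str = ""
    source: str = ""

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValidationError("endpoint", f"unknown endpoint {self.endpoint!r}")
        if self.censor == CENSOR_NONE and not self.value > 0:
            raise ValidationError("value", "uncensored observation must be positive")


@dataclass
class MetricsResult:
    n: int
    pearson_r: float
    spearman_rho: float
    mae: float  # log10 units
    me: float  # log10 units


@dataclass
class TrendResult:
    property: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def decensor_bound_fraction(raw) -> float:
    """Unbound fraction from a bound-% value or censor marker.

    ``"<10"`` → bound 5% → unbound 0.95; ``">99"`` → bound 99.5% → unbound
    0.005; a numeric bound percentage b → (100 − b)/100.
    """
    if isinstance(raw, str):
        marker = raw.strip()
        if marker == "<10":
            return 0.95
        if marker == ">99":
            return 0.005
        raw = float(marker)
    if not (0.0 <= raw <= 100.0):
        raise ValidationError("bound_percent", f"{raw} outside [0, 100]")
    return (100.0 - raw) / 100.0


def _weighted_pearson(x, y, w):
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    return cov / np.sqrt(vx * vy)


def compute_metrics(pred, obs, weights=None, config: EvaluationConfig | None = None) -> MetricsResult:
    """MAE, ME, Pearson r and Spearman ρ of predictions vs observations.

    All statistics are computed on log10-transformed values (Spearman on
    average ranks, hence invariant to the transform).  Zero or negative
    inputs are floored at a small positive constant with a warning.  Weights,
    when given, are applied to all four statistics.
    """
    cfg = config or EvaluationConfig()
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise VitrodistError(f"length mismatch: {pred.shape} vs {obs.shape}")
    n = pred.size
    if n < 2:
        raise VitrodistError("need at least 2 points for correlations")
    if (pred <= 0).any() or (obs <= 0).any():
        warnings.warn(
            f"non-positive values floored at {cfg.log_floor} before log10", stacklevel=2
        )
        pred = np.maximum(pred, cfg.log_floor)
        obs = np.maximum(obs, cfg.log_floor)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != pred.shape:
        raise VitrodistError("weights length mismatch")
    w = w / w.sum()

    lp, lo = np.log10(pred), np.log10(obs)
    diff = lp - lo
    me = float(w @ diff)
    mae = float(w @ np.abs(diff))
    pearson = float(_weighted_pearson(lp, lo, w))
    rp, ro = stats.rankdata(lp), stats.rankdata(lo)
    spearman = float(_weighted_pearson(rp, ro, w))
    return MetricsResult(n=n, pearson_r=pearson, spearman_rho=spearman, mae=mae, me=me)


def residual_trends(
    residuals,
    properties,
    exclude: set | None = None,
    config: EvaluationConfig | None = None,
) -> list[TrendResult]:
    """OLS of log10 residuals against each chemical property.

    ``residuals`` is a mapping/Series chemical id → log10 error;
    ``properties`` a DataFrame indexed by chemical id with one column per
    property.  Chemicals in ``exclude`` (e.g. extreme-property outliers) are
    removed before fitting.  Constant or under-determined properties are
    skipped with a warning.
    """
    import pandas as pd

    resid = pd.Series(residuals, dtype=float)
    exclude = exclude or set()
    keep = [cid for cid in resid.index if cid not in exclude and cid in properties.index]
    if not keep:
        raise VitrodistError("no chemicals left after exclusion")
    resid = resid.loc[keep]
    results = []
    for prop in properties.columns:
        x = properties.loc[keep, prop].astype(float)
        mask = x.notna() & resid.notna()
        if mask.sum() < 3 or x[mask].nunique() < 2:
            warnings.warn(f"property {prop!r} skipped (constant or too few values)", stacklevel=2)
            continue
        fit = stats.linregress(x[mask].to_numpy(), resid[mask].to_numpy())
        results.append(
            TrendResult(
                property=prop,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=float(fit.rvalue**2),
                p_value=float(fit.pvalue),
                n=int(mask.sum()),
            )
        )
    return results


def material_trends(trends: list[TrendResult], config: EvaluationConfig | None = None,
                    alpha: float = 0.05) -> list[TrendResult]:
    """Trends that are statistically significant with a material R²."""
    cfg = config or EvaluationConfig()
    return [t for t in trends if t.p_value < alpha and t.r_squared >= cfg.r2_material]
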