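"""Odds-ratio contrasts, exposure-response curves, stratified fits, Cochran's Q.

Odds ratios are anchored at a referent temperature (23.5 degC for daily
maximum temperature): for temperature t the contrast vector is
c = basis(t) - basis(ref) padded with zeros over the covariate columns,
log OR = c'beta, and the delta-method standard error is sqrt(c' Sigma c).
Effect modification across strata (ICE terciles, census regions) is
assessed by refitting the model within each stratum and testing the
stratum-specific log-ORs at a fixed contrast with Cochran's Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clr import Design, FitResult, ModelSpec, fit_model

__all__ = [
    "DEFAULT_PROBS",
    "ORRow",
    "QTestResult",
    "exposure_percentiles",
    "or_at",
    "or_table",
    "response_curve",
    "stratified_fits",
    "cochran_q",
]

logger = logging.getLogger(__name__)

DEFAULT_PROBS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99)
Z_95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class ORRow:
    temperature: float
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class QTestResult:
    q: float
    df: int
    p_value: float
    estimates: tuple
    ses: tuple


def exposure_percentiles(values, probs=DEFAULT_PROBS, min_n: int = 100) -> pd.Series:
    """Empirical quantiles (linear interpolation) of case-day exposure values."""
    values = np.asarray(values, dtype=float)
    if values.size < min_n:
        raise ValueError(f"need at least {min_n} case days for stable percentiles, got {values.size}")
    qs = np.quantile(values, probs)
    return pd.Series(qs, index=list(probs), name="temp_c")


def or_at(fit: FitResult, design: Design, t: float, ref: float | None = None) -> ORRow:
    """Odds ratio at temperature ``t`` relative to the referent, with 95% CI."""
    if not fit.converged:
        raise ValueError("odds-ratio contrast requires a converged fit")
    ref = design.referent if ref is None else ref
    c = design.exposure_row(t) - design.exposure_row(ref)
    log_or = float(c @ fit.beta)
    se = float(np.sqrt(max(c @ fit.cov @ c, 0.0)))
    return ORRow(
        temperature=float(t),
        log_or=log_or,
        se=se,
        or_=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
    )


def or_table(fit: FitResult, design: Design, percentiles: pd.Series) -> pd.DataFrame:
    """OR rows at each named exposure percentile (referent from the design)."""
    rows = []
    for prob, t in percentiles.items():
        r = or_at(fit, design, t)
        rows.append(
            {
                "percentile": prob,
                "temp_c": r.temperature,
                "or": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "log_or": r.log_or,
                "se": r.se,
            }
        )
    return pd.DataFrame(rows)


def response_curve(fit: FitResult, design: Design, t_min: float, t_max: float, n: int = 200) -> pd.DataFrame:
    """Fine OR-vs-temperature grid for plotting the exposure-response curve."""
    grid = np.linspace(t_min, t_max, n)
    rows = [or_at(fit, design, t) for t in grid]
    return pd.DataFrame(
        {
            "temp_c": grid,
            "or": [r.or_ for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
        }
    )


def stratified_fits(linked: pd.DataFrame, labels: pd.Series, spec: ModelSpec) -> dict:
    """Refit the model independently within each stratum label.

    ``labels`` maps stratum_id -> label (e.g., the ICE tercile of the tract
    where the case occurred, or the census region).  Stratum-days whose
    stratum has no label are ignored.  Labels whose subset cannot be fitted
    (no informative strata, separation) are recorded with the exception and
    are excluded from downstream heterogeneity tests.
    """
    lab = linked["stratum_id"].map(labels)
    out: dict = {}
    for value in sorted(lab.dropna().unique()):
        subset = linked[lab == value]
        try:
            res, design = fit_model(subset, spec)
            out[value] = (res, design)
        except Exception as exc:  # noqa: BLE001
            logger.warning("stratified fit failed for label %r: %s", value, exc)
            out[value] = (exc, None)
    return out


def cochran_q(estimates, ses) -> QTestResult:
    """Cochran's Q heterogeneity test over stratum-specific estimates.

    With weights w_i = 1/se_i^2 and pooled = sum(w theta)/sum(w),
    Q = sum w_i (theta_i - pooled)^2 ~ chi-square(k-1) under homogeneity.
    """
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.size < 2:
        raise ValueError("Cochran's Q needs at least two strata")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = theta.size - 1
    p = float(stats.chi2.sf(q, df))
    return QTestResult(q=q, df=df, p_value=p, estimates=tuple(theta), ses=tuple(se))
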