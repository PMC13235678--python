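"""Conditional logistic regression for 1:M matched strata.

Each stratum contributes the probability that, among all its days, the case
day is the one on which the event occurred:

    loglik(beta) = sum_s [ eta_case(s) - log sum_j exp(eta_j(s)) ],
    eta = X beta.

The stratum-specific baseline odds cancel, so any column that is constant
within every stratum (an intercept, anything varying only between months or
locations) is non-identifiable and is rejected before fitting.

Estimation is guarded Newton-Raphson from beta = 0 with step-halving; the
conditional log-likelihood is concave, so this converges whenever a finite
maximum exists.  Monotone likelihood (separation) is reported as an error
naming the offending column.  The covariance is the inverse negative Hessian
at the optimum; AIC = -2 loglik + 2 p drives the choice between the linear
and spline exposure parameterizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spline import LinearBasis, NaturalCubicSplineBasis, natural_spline_basis

__all__ = [
    "ModelSpec",
    "FitResult",
    "Design",
    "SeparationError",
    "conditional_loglik",
    "fit",
    "build_design",
    "fit_model",
    "select_parameterization",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

MAX_ITER = 50
MAX_HALVINGS = 30
TOL_LOGLIK = 1e-10
TOL_GRAD = 1e-8
SEPARATION_BOUND = 50.0


class SeparationError(RuntimeError):
    """Monotone conditional likelihood: no finite maximum in some direction."""


@dataclass(frozen=True)
class ModelSpec:
    """Exposure parameterization and covariates for one conditional-logistic model.

    exposure : "dtmax" or "dtmean" (daily max / mean temperature, degC)
    form     : "linear" or "spline"
    df       : spline degrees of freedom (2-4); ignored for linear
    covariates : subset of {"holiday", "precip_cat"}
    referent : temperature (degC) at which the odds ratio is anchored to 1
    """

    exposure: str = "dtmax"
    form: str = "linear"
    df: int | None = None
    covariates: tuple = ()
    referent: float = 23.5

    def __post_init__(self):
        if self.exposure not in ("dtmax", "dtmean"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.form not in ("linear", "spline"):
            raise ValueError(f"unknown exposure form {self.form!r}")
        if self.form == "spline" and self.df not in (2, 3, 4):
            raise ValueError("spline form requires df in {2, 3, 4}")
        if not np.isfinite(self.referent):
            raise ValueError("referent must be finite")
        bad = set(self.covariates) - {"holiday", "precip_cat"}
        if bad:
            raise ValueError(f"unknown covariates {sorted(bad)}")

    @property
    def n_exposure_cols(self) -> int:
        return 1 if self.form == "linear" else int(self.df)

    def label(self) -> str:
        return "linear" if self.form == "linear" else f"spline(df={self.df})"


@dataclass
class FitResult:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    n_strata: int
    iterations: int
    converged: bool
    labels: list

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "beta": self.beta.tolist(),
            "covariance": self.cov.tolist(),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_strata": int(self.n_strata),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
        }


@dataclass
class Design:
    """Dense stacked design for the conditional likelihood.

    Rows are sorted by stratum; ``y`` flags the single case row of each
    stratum.  ``basis`` evaluates the exposure columns for an arbitrary
    temperature (on the centered scale ``t - referent``), which is what the
    odds-ratio contrasts need.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    labels: list
    basis: object
    referent: float
    spec: ModelSpec
    n_strata_dropped: int = 0

    def exposure_row(self, t: float) -> np.ndarray:
        """Full-width design row for temperature ``t`` with covariates zeroed."""
        row = np.zeros(self.X.shape[1])
        row[: self.basis.df] = self.basis.design(np.array([t - self.referent]))[0]
        return row


def _group_starts(groups: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])


def conditional_loglik(beta, X, y, groups):
    """Exact conditional log-likelihood with analytic gradient and Hessian.

    Rows must be sorted by ``groups`` and each stratum must contain exactly
    one case row (``y == 1``).  Returns ``(loglik, gradient, hessian)``.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    eta = X @ beta
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    starts = _group_starts(groups)
    sizes = np.diff(np.r_[starts, len(eta)])
    m = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - np.repeat(m, sizes))
    denom = np.add.reduceat(w, starts)
    ll = float(eta[y == 1].sum() - (np.log(denom) + m).sum())
    p = w / np.repeat(denom, sizes)
    xbar = np.add.reduceat(p[:, None] * X, starts, axis=0)  # per-stratum E[x]
    grad = X[y == 1].sum(axis=0) - xbar.sum(axis=0)
    hess = -((X * p[:, None]).T @ X - xbar.T @ xbar)
    return ll, grad, hess


def _validate_strata(X, y, groups, labels):
    """Sort by group, enforce one case per stratum, drop zero-control strata."""
    order = np.argsort(groups, kind="stable")
    X, y, groups = X[order], y[order], groups[order]
    starts = _group_starts(groups)
    sizes = np.diff(np.r_[starts, len(y)])
    cases = np.add.reduceat(y.astype(int), starts)
    if np.any(cases != 1):
        bad = np.unique(groups[np.repeat(cases != 1, sizes)])
        raise ValueError(f"strata without exactly one case row: {bad[:10].tolist()}")
    singleton = sizes < 2
    dropped = int(singleton.sum())
    if dropped:
        logger.warning("dropping %d strata with no control days (uninformative)", dropped)
        keep = np.repeat(~singleton, sizes)
        X, y, groups = X[keep], y[keep], groups[keep]
        starts = _group_starts(groups)
        sizes = np.diff(np.r_[starts, len(y)])
    # a column constant within every stratum is non-identifiable
    firsts = np.repeat(X[starts], sizes, axis=0)
    const = np.all(np.abs(X - firsts) < 1e-12, axis=0)
    if np.any(const):
        names = [labels[j] for j in np.flatnonzero(const)] if labels else np.flatnonzero(const).tolist()
        raise ValueError(f"stratum-constant (non-identifiable) design columns: {names}")
    return X, y, groups, len(starts), dropped


def fit(X, y, groups, labels: Sequence[str] | None = None) -> FitResult:
    """Maximize the conditional likelihood by guarded Newton-Raphson.

    Starts at beta = 0; each Newton step is halved (up to 30 times) until the
    log-likelihood does not decrease.  Convergence: |delta loglik| < 1e-10 or
    max |gradient| < 1e-8, within 50 iterations.  Any coefficient exceeding
    50 in absolute value during iteration is treated as separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups)
    labels = list(labels) if labels is not None else [f"x{j}" for j in range(X.shape[1])]
    if len(labels) != X.shape[1]:
        raise ValueError("labels length must match design width")
    X, y, groups, n_strata, dropped = _validate_strata(X, y, groups, labels)
    if n_strata == 0:
        raise ValueError("no informative strata")

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = conditional_loglik(beta, X, y, groups)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular Hessian in conditional logistic fit (collinear design?)"
            ) from None
        new_ll = -np.inf
        for _ in range(MAX_HALVINGS + 1):
            cand = beta + step
            new_ll, new_grad, new_hess = conditional_loglik(cand, X, y, groups)
            if new_ll >= ll - 1e-14:
                break
            step = step / 2.0
        if np.any(np.abs(cand) > SEPARATION_BOUND):
            j = int(np.argmax(np.abs(cand)))
            raise SeparationError(
                f"separation / monotone likelihood in column {labels[j]!r} "
                f"(|beta| > {SEPARATION_BOUND:g})"
            )
        delta = new_ll - ll
        beta, ll, grad, hess = cand, new_ll, new_grad, new_hess
        if abs(delta) < TOL_LOGLIK or np.max(np.abs(grad)) < TOL_GRAD:
            converged = True
            break
    cov = np.linalg.inv(-hess)
    cov = (cov + cov.T) / 2.0
    return FitResult(
        beta=beta,
        cov=cov,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * p,
        n_strata=n_strata,
        iterations=it,
        converged=converged,
        labels=labels,
    )


def build_design(linked: pd.DataFrame, spec: ModelSpec) -> Design:
    """Render linked stratum-days into a dense design matrix.

    Exposure columns come first (centered at the referent before basis
    construction; the conditional likelihood is translation-invariant so this
    only improves conditioning), followed by the holiday indicator and two
    precipitation dummies (categories 1 and 2 vs the dry category 0) as
    requested by ``spec.covariates``.
    """
    col = {"dtmax": "dtmax_c", "dtmean": "dtmean_c"}[spec.exposure]
    x = linked[col].to_numpy(dtype=float) - spec.referent
    if spec.form == "linear":
        basis = LinearBasis()
        labels = [spec.exposure]
    else:
        basis = natural_spline_basis(x, spec.df)
        labels = [f"{spec.exposure}_ns{j + 1}" for j in range(spec.df)]
    cols = [basis.design(x)]
    for cov in spec.covariates:
        if cov == "holiday":
            cols.append(linked["holiday"].to_numpy(dtype=float)[:, None])
            labels.append("holiday")
        elif cov == "precip_cat":
            pc = linked["precip_cat"].to_numpy()
            cols.append(np.column_stack([(pc == 1).astype(float), (pc == 2).astype(float)]))
            labels += ["precip_cat1", "precip_cat2"]
    X = np.hstack(cols)
    y = (linked["role"].to_numpy() == "case").astype(int)
    groups = linked["stratum_id"].to_numpy()
    order = np.argsort(groups, kind="stable")
    return Design(
        X=X[order],
        y=y[order],
        groups=groups[order],
        labels=labels,
        basis=basis,
        referent=spec.referent,
        spec=spec,
    )


def fit_model(linked: pd.DataFrame, spec: ModelSpec) -> tuple[FitResult, Design]:
    """Convenience: build the design from linked stratum-days and fit."""
    design = build_design(linked, spec)
    result = fit(design.X, design.y, design.groups, design.labels)
    return result, design


def select_parameterization(
    linked: pd.DataFrame, candidates: Sequence[ModelSpec]
) -> tuple[ModelSpec, dict]:
    """Fit every candidate exposure parameterization and keep the minimal-AIC one.

    Ties (within 1e-9) are broken toward fewer parameters, then linear over
    spline.  Candidates that fail to fit (separation, singular Hessian) are
    recorded with their exception and excluded.  Returns the winning spec and
    a dict label -> FitResult-or-exception.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate parameterizations")
    results: dict = {}
    ranked = []
    for spec in candidates:
        try:
            res, _ = fit_model(linked, spec)
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            results[spec.label()] = exc
            logger.warning("candidate %s failed: %s", spec.label(), exc)
            continue
        results[spec.label()] = res
        if res.converged:
            ranked.append((spec, res))
    if not ranked:
        raise RuntimeError("all candidate parameterizations failed to converge")
    return rank_candidates(ranked)[0][0], results


def rank_candidates(pairs):
    """Order (spec, FitResult) pairs by AIC; ties (within 1e-9) go to the
    model with fewer parameters, then linear over spline."""
    return sorted(
        pairs,
        key=lambda sr: (
            round(sr[1].aic / 1e-9) * 1e-9,
            len(sr[1].beta),
            0 if sr[0].form == "linear" else 1,
        ),
    )
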