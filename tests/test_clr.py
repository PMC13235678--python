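"""Conditional logistic likelihood, Newton fitting, and AIC selection."""

import numpy as np
import pandas as pd
import pytest

from casecross import (
    FitResult,
    ModelSpec,
    SeparationError,
    conditional_loglik,
    fit,
    fit_model,
    select_parameterization,
)
from casecross.clr import rank_candidates
from conftest import make_linked, simulate_matched_design


def one_one_strata(diffs):
    """1:1 strata where the case-minus-control exposure difference is given."""
    X, y, groups = [], [], []
    for i, d in enumerate(diffs):
        X += [[float(d)], [0.0]]
        y += [1, 0]
        groups += [i, i]
    return np.array(X), np.array(y), np.array(groups)


def test_loglik_at_zero_is_uniform_over_stratum_days(rng):
    X, y, groups = simulate_matched_design(rng, n_strata=20, n_controls=3)
    ll, _, _ = conditional_loglik(np.zeros(X.shape[1]), X, y, groups)
    assert ll == pytest.approx(20 * np.log(1 / 4))


def test_single_1to3_stratum_contribution_at_zero(rng):
    X, y, groups = simulate_matched_design(rng, n_strata=1, n_controls=3)
    ll, _, _ = conditional_loglik(np.zeros(1), X, y, groups)
    assert ll == pytest.approx(np.log(1 / 4))


def test_1to1_stratum_reduces_to_binary_logit():
    d = 1.7
    X, y, groups = one_one_strata([d])
    for beta in (-0.5, 0.0, 0.8, 2.0):
        ll, _, _ = conditional_loglik(np.array([beta]), X, y, groups)
        assert ll == pytest.approx(-np.log1p(np.exp(-beta * d)))


def test_gradient_matches_central_finite_differences(rng):
    X, y, groups = simulate_matched_design(rng, n_strata=30, n_controls=3, beta=(0.4, -0.2))
    beta = np.array([0.3, -0.1])
    _, grad, hess = conditional_loglik(beta, X, y, groups)
    eps = 1e-6
    for j in range(2):
        e = np.zeros(2)
        e[j] = eps
        up, *_ = conditional_loglik(beta + e, X, y, groups)
        dn, *_ = conditional_loglik(beta - e, X, y, groups)
        assert grad[j] == pytest.approx((up - dn) / (2 * eps), abs=1e-6)
        # Hessian column against gradient differences
        _, gu, _ = conditional_loglik(beta + e, X, y, groups)
        _, gd, _ = conditional_loglik(beta - e, X, y, groups)
        assert np.allclose(hess[:, j], (gu - gd) / (2 * eps), atol=1e-5)


def test_closed_form_log2():
    X, y, groups = one_one_strata([1.0, 1.0, -1.0])
    res = fit(X, y, groups)
    assert res.converged
    assert res.beta[0] == pytest.approx(np.log(2), abs=1e-8)


def test_symmetric_differences_give_zero():
    X, y, groups = one_one_strata([1.0, -1.0])
    res = fit(X, y, groups)
    assert res.beta[0] == pytest.approx(0.0, abs=1e-10)


def test_aic_definition_and_covariance_diagonal(rng):
    X, y, groups = simulate_matched_design(rng, n_strata=80, n_controls=3, beta=(0.5,))
    res = fit(X, y, groups)
    assert res.aic == pytest.approx(-2 * res.loglik + 2 * len(res.beta))
    assert (np.diag(res.cov) > 0).all()
    assert np.allclose(res.cov, res.cov.T)


def test_stratum_constant_column_rejected(rng):
    X, y, groups = simulate_matched_design(rng, n_strata=20, n_controls=3)
    X2 = np.column_stack([X, np.ones(len(X))])
    with pytest.raises(ValueError, match="non-identifiable"):
        fit(X2, y, groups, labels=["x", "intercept"])


def test_zero_control_strata_dropped_with_warning(rng, caplog):
    X, y, groups = simulate_matched_design(rng, n_strata=20, n_controls=3)
    X = np.vstack([X, [[0.3]]])
    y = np.r_[y, 1]
    groups = np.r_[groups, 999]
    with caplog.at_level("WARNING"):
        res = fit(X, y, groups)
    assert res.n_strata == 20
    assert "no control" in caplog.text


def test_separation_raises_naming_column():
    # case exposure always strictly larger -> monotone likelihood
    X, y, groups = one_one_strata([0.1] * 8)
    with pytest.raises(SeparationError, match="temp"):
        fit(X, y, groups, labels=["temp"])


def test_matches_statsmodels_conditional_logit():
    statsmodels = pytest.importorskip("statsmodels.discrete.conditional_models")
    linked, _, _ = make_linked(seed=3, n_cells=10)
    spec = ModelSpec(covariates=("holiday", "precip_cat"))
    res, design = fit_model(linked, spec)
    m = statsmodels.ConditionalLogit(
        design.y, design.X, groups=pd.factorize(design.groups)[0]
    ).fit(method="newton", tol=1e-12, disp=0)
    assert np.abs(res.beta - np.asarray(m.params)).max() < 1e-6
    assert np.abs(res.se - np.asarray(m.bse)).max() < 1e-4


def _fake(spec, loglik, p):
    return (
        spec,
        FitResult(
            beta=np.zeros(p), cov=np.eye(p), loglik=loglik, aic=-2 * loglik + 2 * p,
            n_strata=10, iterations=1, converged=True, labels=[f"x{i}" for i in range(p)],
        ),
    )


def test_equal_loglik_prefers_fewer_parameters():
    lin = ModelSpec(form="linear")
    spl = ModelSpec(form="spline", df=2)
    ranked = rank_candidates([_fake(spl, -100.0, 2), _fake(lin, -100.0, 1)])
    assert ranked[0][0] is lin


def test_equal_aic_prefers_linear():
    lin = ModelSpec(form="linear")
    spl = ModelSpec(form="spline", df=2)
    # spline has higher loglik by exactly the AIC penalty difference
    ranked = rank_candidates([_fake(spl, -99.0, 2), _fake(lin, -100.0, 1)])
    assert ranked[0][1].aic == ranked[1][1].aic
    assert ranked[0][0] is lin


def test_single_candidate_returned_unconditionally():
    linked, _, _ = make_linked(seed=5, n_cells=8)
    spec = ModelSpec()
    best, results = select_parameterization(linked, [spec])
    assert best is spec
    assert set(results) == {"linear"}


def test_loglik_invariant_to_stratum_constant_shift(rng):
    """Adding a stratum-constant amount to the exposure leaves the conditional
    likelihood surface unchanged (the fit rejects such *columns*, but shifts
    of an existing column must cancel)."""
    X, y, groups = simulate_matched_design(rng, n_strata=30, n_controls=3, beta=(0.4,))
    shift = np.repeat(rng.normal(0, 5, 30), 4)[:, None]
    beta = np.array([0.27])
    ll1, g1, h1 = conditional_loglik(beta, X, y, groups)
    ll2, g2, h2 = conditional_loglik(beta, X + shift, y, groups)
    assert ll1 == pytest.approx(ll2)
    assert np.allclose(g1, g2)
    assert np.allclose(h1, h2)
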