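import numpy as np
import pandas as pd
import pytest

from casecross import (
    ModelSpec,
    SyntheticConfig,
    build_strata,
    generate_all,
    link,
    us_federal_holidays,
)


def simulate_matched_design(rng, n_strata=50, n_controls=3, beta=(0.3,), exposure_sd=1.0):
    """Direct matched-set simulator at the design-matrix level.

    Draws stratum-day exposures, then picks the case day within each stratum
    with probability softmax(X beta) — exactly the conditional-logistic
    generative model.  Returns (X, y, groups).
    """
    beta = np.asarray(beta, dtype=float)
    p = beta.size
    size = n_controls + 1
    X = rng.normal(0.0, exposure_sd, size=(n_strata * size, p))
    groups = np.repeat(np.arange(n_strata), size)
    y = np.zeros(n_strata * size, dtype=int)
    eta = (X @ beta).reshape(n_strata, size)
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    cum = prob.cumsum(axis=1)
    u = rng.random((n_strata, 1))
    case = (u > cum).sum(axis=1)
    y[np.arange(n_strata) * size + case] = 1
    return X, y, groups


def make_linked(seed=1, **config_overrides):
    """Generate a synthetic dataset and carry it through matching and linkage."""
    cfg = SyntheticConfig(seed=seed, **config_overrides)
    bundle = generate_all(cfg)
    strata = build_strata(bundle["events"])
    cal = us_federal_holidays(range(cfg.date_start.year, cfg.date_end.year + 1))
    linked = link(strata, bundle["weather"], cal)
    return linked, bundle, cfg


@pytest.fixture(scope="session")
def bundle_small():
    """One modest synthetic dataset shared across read-only tests."""
    linked, bundle, cfg = make_linked(seed=11, n_cells=15, n_tracts=60)
    return {"linked": linked, "config": cfg, **bundle}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
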