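"""ICE values, national terciles, and pooled incidence rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casecross import (
    DIMENSIONS,
    SyntheticConfig,
    assign_tercile,
    compute_ice_table,
    generate_tracts,
    ice_value,
    tercile_cutpoints,
    tercile_rates,
)


@pytest.mark.parametrize(
    "A,P,T,expected",
    [(100, 0, 100, 1.0), (50, 50, 200, 0.0), (30, 50, 200, -0.1)],
)
def test_ice_formula(A, P, T, expected):
    assert ice_value(A, P, T) == pytest.approx(expected)


def test_ice_zero_total_raises():
    with pytest.raises(ValueError):
        ice_value(0, 0, 0)


@given(
    st.integers(min_value=0, max_value=1000),
    st.integers(min_value=0, max_value=1000),
    st.integers(min_value=1, max_value=1000),
)
@settings(derandomize=True, max_examples=200)
def test_ice_antisymmetry_and_bounds(a, p, extra):
    t = a + p + extra
    v = ice_value(a, p, t)
    assert -1.0 <= v <= 1.0
    assert ice_value(p, a, t) == pytest.approx(-v)
    # |ICE| = 1 only when one extreme holds the whole measured population
    if abs(v) == 1.0:
        assert a + p == t and min(a, p) == 0


def test_cutpoints_three_point_distribution():
    q1, q2 = tercile_cutpoints([-1.0, 0.0, 1.0])
    labels = assign_tercile([-1.0, 0.0, 1.0], (q1, q2))
    assert list(labels) == [1, 2, 3]


def test_cutpoints_match_sorting_oracle(rng):
    values = rng.uniform(-1, 1, 300)
    q1, q2 = tercile_cutpoints(values)
    s = np.sort(values)
    # order-statistic interpolation oracle at p = 1/3 and 2/3
    for q, p in [(q1, 1 / 3), (q2, 2 / 3)]:
        h = (len(s) - 1) * p
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        assert q == pytest.approx(s[lo] + (h - lo) * (s[hi] - s[lo]))


def test_cutpoints_require_three_values():
    with pytest.raises(ValueError):
        tercile_cutpoints([0.1, 0.2])


def test_degenerate_identical_values_all_tercile_one():
    q1, q2 = tercile_cutpoints([0.4] * 10)
    assert q1 == q2 == 0.4
    assert list(assign_tercile([0.4] * 10, (q1, q2))) == [1] * 10


def test_tercile_boundary_rule_and_monotonicity(rng):
    cp = (-0.2, 0.3)
    assert assign_tercile(-0.9, cp) == 1
    assert assign_tercile(-0.2, cp) == 1  # lower-closed boundary
    assert assign_tercile(0.0, cp) == 2
    assert assign_tercile(0.3, cp) == 2
    assert assign_tercile(0.31, cp) == 3
    values = np.sort(rng.uniform(-1, 1, 200))
    labels = assign_tercile(values, cp)
    assert (np.diff(labels) >= 0).all()


def test_tercile_labels_match_rank_oracle(rng):
    values = rng.uniform(-1, 1, 200)
    cp = tercile_cutpoints(values)
    labels = assign_tercile(values, cp)
    ranks = np.argsort(np.argsort(values))
    # away from ties, ranks and labels must order identically
    for i in range(len(values)):
        for j in range(len(values)):
            if labels[i] < labels[j]:
                assert ranks[i] < ranks[j]


def _tracts(rows):
    cols = ["tract_id", "pop_total"]
    for d in DIMENSIONS:
        cols += [f"{d}_priv", f"{d}_depr"]
    return pd.DataFrame(rows, columns=cols)


def test_single_event_rate_per_100k():
    rows = [
        ("T1", 20000) + (18000, 1000) * 4,
        ("T2", 10000) + (1000, 8000) * 4,
        ("T3", 10000) + (5000, 5000) * 4,
    ]
    tracts = compute_ice_table(_tracts(rows))
    events = pd.DataFrame({"event_id": ["E0"], "tract_id": ["T1"]})
    out = tercile_rates(events, tracts, "income")
    row = out[out["cases"] > 0].iloc[0]
    assert row["population"] == 20000
    assert row["rate_per_100k"] == pytest.approx(5.0)
    assert (out.loc[out["cases"] == 0, "rate_per_100k"] == 0).all()


def test_tercile_case_conservation(bundle_small):
    tracts = compute_ice_table(bundle_small["tracts"])
    events = bundle_small["events"]
    for dim in DIMENSIONS:
        out = tercile_rates(events, tracts, dim)
        assert out["cases"].sum() == len(events)
        assert out["population"].sum() == tracts["pop_total"].sum()


def test_unknown_tract_raises():
    tracts = compute_ice_table(generate_tracts(SyntheticConfig(seed=0, n_tracts=10)))
    events = pd.DataFrame({"event_id": ["E0"], "tract_id": ["T9999"]})
    with pytest.raises(ValueError, match="T9999"):
        tercile_rates(events, tracts, "income")


def test_generated_tracts_span_all_terciles():
    tracts = generate_tracts(SyntheticConfig(seed=4, n_tracts=300))
    table = compute_ice_table(tracts)
    for dim in DIMENSIONS:
        assert set(table[f"tercile_{dim}"]) == {1, 2, 3}
        assert table[f"ice_{dim}"].min() < -0.3
        assert table[f"ice_{dim}"].max() > 0.3
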