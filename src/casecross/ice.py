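"""Index of Concentration at the Extremes (ICE) and national terciles.

ICE quantifies spatial social polarization within a census tract:

    ICE = (A - P) / T

where A is the count of persons at the privileged extreme, P the count at
the deprived extreme, and T the total population whose privilege level was
measured.  ICE ranges from -1 (everyone at the deprived extreme) to +1
(everyone at the privileged extreme).  Four dimensions are carried:
household income, racialized income (non-Hispanic White high-income vs
non-Hispanic Black low-income), homeownership, and educational attainment.

Tracts are cut into terciles of the national tract-level ICE distribution;
tercile 1 is the most deprived (lowest ICE).  Incidence rates per tercile
pool cases and population: rate = 100000 * sum(cases) / sum(population).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "ice_value",
    "tercile_cutpoints",
    "assign_tercile",
    "compute_ice_table",
    "tercile_rates",
]

DIMENSIONS = ("income", "race_income", "homeownership", "education")


def ice_value(A, P, T):
    """(A - P) / T, elementwise; requires T > 0, A, P >= 0, A + P <= T."""
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("ICE undefined for non-positive total population")
    if np.any(A < 0) or np.any(P < 0):
        raise ValueError("extreme-group counts must be non-negative")
    if np.any(A + P > T * (1 + 1e-12)):
        raise ValueError("privileged + deprived counts exceed total population")
    out = (A - P) / T
    return float(out) if out.ndim == 0 else out


def tercile_cutpoints(values) -> tuple:
    """Empirical 1/3 and 2/3 quantiles (linear interpolation) of tract ICE values."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise ValueError("need at least 3 finite ICE values to define terciles")
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    return float(q1), float(q2)


def assign_tercile(ice, cutpoints) -> np.ndarray:
    """Tercile label: 1 (most deprived, ice <= q1/3), 2, or 3 (most privileged).

    Boundaries are lower-closed: a value exactly at a cutpoint falls in the
    lower tercile.
    """
    q1, q2 = cutpoints
    ice = np.asarray(ice, dtype=float)
    out = np.where(ice <= q1, 1, np.where(ice <= q2, 2, 3))
    return int(out) if out.ndim == 0 else out


def compute_ice_table(tracts: pd.DataFrame, cutpoints: dict | None = None) -> pd.DataFrame:
    """Add ``ice_<dim>`` and ``tercile_<dim>`` columns for every dimension.

    ``tracts`` must carry ``tract_id``, ``pop_total`` and, per dimension,
    ``<dim>_priv`` / ``<dim>_depr`` counts.  Cutpoints default to the
    national (whole-table, unweighted) tract distribution; a precomputed
    ``{dim: (q1, q2)}`` mapping can be supplied instead.
    """
    out = tracts.copy()
    for dim in DIMENSIONS:
        out[f"ice_{dim}"] = ice_value(
            out[f"{dim}_priv"], out[f"{dim}_depr"], out["pop_total"]
        )
        cp = cutpoints[dim] if cutpoints else tercile_cutpoints(out[f"ice_{dim}"])
        out[f"tercile_{dim}"] = assign_tercile(out[f"ice_{dim}"], cp)
    return out


def tercile_rates(events: pd.DataFrame, tracts: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Case counts and pooled incidence rates per tercile of one ICE dimension.

    Every tercile appears in the output (zero cases give rate 0); population
    sums over all tracts in the tercile, not only those with cases.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown ICE dimension {dimension!r}")
    tcol = f"tercile_{dimension}"
    if tcol not in tracts.columns:
        tracts = compute_ice_table(tracts)
    unknown = sorted(set(events["tract_id"]) - set(tracts["tract_id"]))
    if unknown:
        raise ValueError(f"events reference unknown tracts: {unknown[:10]}")
    cases_by_tract = events.groupby("tract_id").size()
    t = tracts.set_index("tract_id")
    t["cases"] = cases_by_tract.reindex(t.index, fill_value=0)
    g = t.groupby(tcol).agg(cases=("cases", "sum"), population=("pop_total", "sum"))
    g = g.reindex([1, 2, 3], fill_value=0)
    g["rate_per_100k"] = np.where(
        g["population"] > 0, 1e5 * g["cases"] / g["population"], 0.0
    )
    g.index.name = "tercile"
    out = g.reset_index()
    out.insert(0, "dimension", dimension)
    return out
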