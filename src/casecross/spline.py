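"""Natural cubic spline basis for exposure-response curves.

The temperature term in the conditional logistic model is either linear or a
natural cubic spline with 2-4 degrees of freedom.  The natural constraint
(zero second derivative at and beyond the boundary knots) makes the fitted
curve linear in the tails, where data are sparse.

Construction: boundary knots at the min/max of the observed exposure values,
df-1 interior knots at equally spaced quantiles, and the standard
truncated-power natural basis.  With knots k_1 < ... < k_K (K = df + 1),

    d_m(x) = [ (x - k_m)_+^3 - (x - k_K)_+^3 ] / (k_K - k_m)

and the df basis columns are  x, { d_m(x) - d_{K-1}(x) : m = 1..K-2 }.
The cubic and quadratic terms cancel beyond the boundary knots, so
extrapolation is exactly linear on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LinearBasis", "NaturalCubicSplineBasis", "natural_spline_basis"]


@dataclass(frozen=True)
class LinearBasis:
    """Single-column linear exposure term."""

    @property
    def df(self) -> int:
        return 1

    def design(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return x[:, None]


@dataclass(frozen=True)
class NaturalCubicSplineBasis:
    boundary_knots: tuple
    interior_knots: tuple

    @property
    def df(self) -> int:
        return len(self.interior_knots) + 1

    @property
    def knots(self) -> np.ndarray:
        return np.array([self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]])

    def design(self, x) -> np.ndarray:
        """Evaluate the basis: one row per value, ``df`` columns."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = self.knots
        K = len(k)

        def d(m):  # truncated-power differences, m is 0-based knot index
            num = np.clip(x - k[m], 0, None) ** 3 - np.clip(x - k[-1], 0, None) ** 3
            return num / (k[-1] - k[m])

        cols = [x] + [d(m) - d(K - 2) for m in range(K - 2)]
        return np.column_stack(cols)


def natural_spline_basis(values, df: int) -> NaturalCubicSplineBasis:
    """Build the basis from observed exposure values.

    Boundary knots sit at the min and max of ``values``; the df-1 interior
    knots at the 1/df, ..., (df-1)/df empirical quantiles.  Requires
    df in {2, 3, 4} and at least df + 2 distinct values.
    """
    if df not in (2, 3, 4):
        raise ValueError(f"spline df must be in {{2, 3, 4}}, got {df}")
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)
    if uniq.size < df + 2:
        raise ValueError(
            f"need at least {df + 2} distinct exposure values for df={df}, got {uniq.size}"
        )
    lo, hi = float(uniq[0]), float(uniq[-1])
    probs = np.arange(1, df) / df
    interior = np.quantile(values, probs)
    # knots must be strictly increasing; nudge degenerate quantiles off the boundaries
    interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    return NaturalCubicSplineBasis(boundary_knots=(lo, hi), interior_knots=tuple(interior))
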