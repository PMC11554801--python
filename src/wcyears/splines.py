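"""Natural cubic spline basis on age.

The trajectory model needs a smooth population age trend that can be
evaluated *outside* the range of observed exam ages, because yearly waist
circumference is predicted backwards from each participant's first exam down
to the cohort minimum entry age.  A natural cubic spline is the standard
choice: cubic between knots, constrained to be linear beyond the boundary
knots, so backward extrapolation is a straight line rather than a cubic
blow-up.

The basis here is the truncated-power construction: with interior knots
``k_1 < ... < k_K`` inside boundary knots ``(a, b)``, write

    d_j(x) = ((x - k_j)_+^3 - (x - b)_+^3) / (b - k_j)

and take ``{x, d_1(x) - d_K(x), ..., d_{K-1}(x) - d_K(x)}`` with the
boundary knots appended to the knot list.  Every basis function has zero
second and third derivative below ``a`` and above ``b``.  The span equals
that of R's ``splines::ns`` for the same knots (verified against an R
oracle in the test suite); the basis vectors themselves differ, which is
irrelevant for regression fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for a natural cubic spline on age.

    Parameters
    ----------
    knots : tuple of float
        Interior knot locations (years of age), strictly increasing.
    boundary : tuple of float
        (lower, upper) boundary knots; the fit is linear outside them.
    """

    knots: tuple[float, ...]
    boundary: tuple[float, float]

    def __post_init__(self) -> None:
        ks = tuple(float(k) for k in self.knots)
        if list(ks) != sorted(set(ks)):
            raise ValueError("interior knots must be strictly increasing")
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError("boundary knots must satisfy lower < upper")
        if ks and not (lo < ks[0] and ks[-1] < hi):
            raise ValueError("interior knots must lie inside the boundary knots")
        object.__setattr__(self, "knots", ks)
        object.__setattr__(self, "boundary", (float(lo), float(hi)))

    @property
    def n_basis(self) -> int:
        """Number of basis columns (excluding the intercept)."""
        return len(self.knots) + 1

    @classmethod
    def from_quantiles(
        cls, ages: np.ndarray, probs: tuple[float, ...] = (0.10, 0.50, 0.90)
    ) -> "SplineSpec":
        """Place interior knots at age quantiles, boundaries at the range."""
        ages = np.asarray(ages, dtype=float)
        ages = ages[np.isfinite(ages)]
        if ages.size < 2:
            raise ValueError("need at least two finite ages to place knots")
        lo, hi = float(ages.min()), float(ages.max())
        knots = tuple(float(q) for q in np.quantile(ages, probs))
        # degenerate quantiles (tiny samples) collapse to fewer unique knots
        knots = tuple(sorted({k for k in knots if lo < k < hi}))
        return cls(knots=knots, boundary=(lo, hi))


def natural_cubic_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic basis (no intercept column) at ``x``.

    Returns an array of shape ``(len(x), spec.n_basis)`` whose first column
    is ``x`` itself and whose remaining columns carry the curvature.  Valid
    for any real ``x``, with linear extrapolation beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spline basis requires finite inputs")
    lo, hi = spec.boundary
    all_knots = np.array([*spec.knots, hi], dtype=float)  # k_1..k_K, b
    if all_knots.size < 2:
        # no interior knots: the "spline" is just the linear term
        return x.reshape(-1, 1)

    def d(k: float) -> np.ndarray:
        return (
            np.maximum(x - k, 0.0) ** 3 - np.maximum(x - hi, 0.0) ** 3
        ) / (hi - k)

    d_last = d(all_knots[-2])  # d_K uses the last knot before the boundary
    cols = [x]
    for k in all_knots[:-2]:
        cols.append(d(k) - d_last)
    # lower-boundary knot contributes one more curvature column
    cols.append(d(lo) - d_last)
    out = np.column_stack(cols)
    return out
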