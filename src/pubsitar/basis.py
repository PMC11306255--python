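"""Natural cubic spline basis with analytic derivatives.

The basis is the standard natural (restricted) cubic spline construction:
for knots xi_1 < ... < xi_K the functions are

    N_1(x) = x,
    N_{k+1}(x) = d_k(x) - d_{K-1}(x),   k = 1..K-2,

with d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k).

Cubic and quadratic terms cancel outside the boundary knots, so every basis
function (hence any fitted curve) is linear beyond [xi_1, xi_K] and has zero
second derivative at the boundaries.  The intercept is deliberately excluded
and handled by the caller.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DataError

__all__ = ["NaturalCubicSpline", "build_natural_spline_basis"]


class NaturalCubicSpline:
    """Natural cubic spline design matrix builder.

    Parameters
    ----------
    knots
        Full strictly increasing knot vector, boundary knots included.
        ``len(knots) - 2`` internal knots; the design has ``len(knots) - 1``
        columns (intercept excluded).
    """

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 3:
            raise DataError("need at least 3 knots (2 boundary + 1 internal)")
        if not np.all(np.diff(knots) > 0):
            raise DataError("knots must be strictly increasing")
        self.knots = knots

    @classmethod
    def from_quantiles(cls, ages, n_internal: int) -> "NaturalCubicSpline":
        """Boundary knots at the data range, internal knots at equally
        spaced quantiles i/(n_internal+1) of the age distribution."""
        ages = np.asarray(ages, dtype=float)
        distinct = np.unique(ages)
        if distinct.size < n_internal + 2:
            raise DataError(
                f"need at least {n_internal + 2} distinct ages for "
                f"{n_internal} internal knots, got {distinct.size}"
            )
        probs = np.arange(1, n_internal + 1) / (n_internal + 1)
        internal = np.quantile(ages, probs)
        knots = np.concatenate([[ages.min()], internal, [ages.max()]])
        if np.any(np.diff(knots) <= 0):
            raise DataError("quantile knots are not distinct; too few distinct ages")
        return cls(knots)

    @property
    def n_columns(self) -> int:
        return self.knots.size - 1

    def _d(self, x, k: int, order: int):
        """d_k(x) (or its derivative) for 0-based knot index k."""
        xi = self.knots
        K = xi.size
        denom = xi[-1] - xi[k]

        def pplus(t, order):
            u = np.maximum(x - t, 0.0)
            if order == 0:
                return u**3
            if order == 1:
                return 3.0 * u**2
            if order == 2:
                return 6.0 * u
            raise ValueError("order must be 0, 1 or 2")

        return (pplus(xi[k], order) - pplus(xi[K - 1], order)) / denom

    def design(self, x, order: int = 0) -> np.ndarray:
        """Design matrix of the basis (order=0) or its derivative.

        Parameters
        ----------
        x
            Evaluation points; extrapolation beyond the boundary knots is
            linear by construction.
        order
            0 for values, 1 for first derivative, 2 for second derivative.
        """
        x = np.asarray(x, dtype=float)
        flat = x.ravel()
        K = self.knots.size
        out = np.empty((flat.size, K - 1))
        if order == 0:
            out[:, 0] = flat
        elif order == 1:
            out[:, 0] = 1.0
        else:
            out[:, 0] = 0.0
        dK1 = self._d(flat, K - 2, order)
        for k in range(K - 2):
            out[:, k + 1] = self._d(flat, k, order) - dK1
        return out.reshape(x.shape + (K - 1,))


def build_natural_spline_basis(ages, n_knots: int) -> np.ndarray:
    """Natural cubic spline basis matrix for `ages` with `n_knots` internal
    knots placed at equally spaced quantiles of the age distribution.

    Returns a matrix with ``n_knots + 1`` columns (intercept excluded).
    """
    spline = NaturalCubicSpline.from_quantiles(ages, n_knots)
    return spline.design(ages)
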