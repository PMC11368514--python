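"""Restricted (natural) cubic spline basis.

The basis is Harrell's truncated-power restricted cubic spline: for knots
``k_1 < ... < k_K`` the represented function is a cubic spline that is
constrained to be *linear* beyond the boundary knots. With the conventional
normalisation by ``(k_K - k_1)**2`` the K-1 columns are

    B_0(x) = x
    B_j(x) = [ (x-k_j)_+^3
               - (x-k_{K-1})_+^3 (k_K-k_j)/(k_K-k_{K-1})
               + (x-k_K)_+^3   (k_{K-1}-k_j)/(k_K-k_{K-1}) ] / (k_K-k_1)^2

for j = 1..K-2, where ``(u)_+ = max(u, 0)``. Each nonlinear column is zero
at and below the first knot and exactly linear above the last knot, so any
linear combination has continuous value, first and second derivative
everywhere and linear tails.
"""

from __future__ import annotations

import numpy as np

from .errors import KnotSpecError


def validate_knots(knots) -> np.ndarray:
    """Return knots as a float array after checking the spline preconditions."""
    k = np.asarray(knots, dtype=float)
    if k.ndim != 1 or k.size < 3:
        raise KnotSpecError(
            f"restricted cubic splines need >=3 knots, got {k.size}"
        )
    if not np.all(np.isfinite(k)):
        raise KnotSpecError("knots must be finite")
    if not np.all(np.diff(k) > 0):
        raise KnotSpecError(f"knots must be strictly increasing, got {k.tolist()}")
    return k


def rcs_basis(x, knots) -> np.ndarray:
    """Evaluate the restricted-cubic-spline basis.

    Parameters
    ----------
    x : array-like
        Finite values at which to evaluate the basis.
    knots : array-like
        Strictly increasing knot locations, at least 3.

    Returns
    -------
    ndarray of shape (len(x), K-1)
        Column 0 is ``x`` itself; columns 1..K-2 are the restricted
        nonlinear terms (zero at/below the first knot, linear beyond the
        last knot).
    """
    k = validate_knots(knots)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise KnotSpecError("x must be finite to evaluate the spline basis")

    K = k.size
    tau = (k[-1] - k[0]) ** 2
    cols = [x]
    d_last = k[-1] - k[-2]
    for j in range(K - 2):
        term = (
            np.clip(x - k[j], 0.0, None) ** 3
            - np.clip(x - k[-2], 0.0, None) ** 3 * (k[-1] - k[j]) / d_last
            + np.clip(x - k[-1], 0.0, None) ** 3 * (k[-2] - k[j]) / d_last
        )
        cols.append(term / tau)
    return np.column_stack(cols)


def n_basis_columns(knots) -> int:
    """Number of basis columns (K-1) for a validated knot vector."""
    return validate_knots(knots).size - 1
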