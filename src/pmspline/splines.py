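"""Cubic B-spline bases for within-shift temporal trends.

The smooth within-shift trend term uses a clamped (open uniform) cubic
B-spline basis on the shift time axis.  The basis is a partition of unity
on the interior of its domain, which makes a per-day trend coefficient
vector directly interpretable on the log10 concentration scale.

A column-centred variant is provided for use inside the hierarchical
model: centring each basis column removes the constant function from the
column space, so the per-day trend has exactly zero mean over the day's
records and is identifiable next to the day intercept.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

from .errors import ExtrapolationError

__all__ = ["knot_vector", "bspline_basis", "centered_basis", "n_basis_functions"]

#: absolute slack (minutes) allowed beyond the nominal domain before an
#: evaluation is treated as extrapolation
DOMAIN_TOL = 1e-9


def knot_vector(lo: float, hi: float, n_interior: int, degree: int = 3) -> np.ndarray:
    """Clamped knot vector on [lo, hi] with equally spaced interior knots."""
    if hi <= lo:
        raise ValueError(f"empty spline domain [{lo}, {hi}]")
    if n_interior < 0:
        raise ValueError("n_interior must be >= 0")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])


def n_basis_functions(n_interior: int, degree: int = 3) -> int:
    return n_interior + degree + 1


def bspline_basis(
    t: np.ndarray | float,
    lo: float,
    hi: float,
    n_interior: int,
    degree: int = 3,
) -> np.ndarray:
    """Evaluate the clamped B-spline basis at times ``t`` (minutes).

    Returns an array of shape ``(len(t), n_interior + degree + 1)``.
    Rows sum to 1 for any t inside [lo, hi].  Times outside the domain
    (beyond a small tolerance) raise :class:`ExtrapolationError`.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < lo - DOMAIN_TOL) or np.any(t > hi + DOMAIN_TOL):
        bad = t[(t < lo - DOMAIN_TOL) | (t > hi + DOMAIN_TOL)]
        raise ExtrapolationError(
            f"spline basis evaluated outside [{lo}, {hi}]: e.g. t={bad[0]!r}"
        )
    kv = knot_vector(lo, hi, n_interior, degree)
    # design_matrix is exclusive of the right endpoint; clip into the domain
    tc = np.clip(t, lo, np.nextafter(hi, lo))
    return BSpline.design_matrix(tc, kv, degree).toarray()


def centered_basis(
    t: np.ndarray, lo: float, hi: float, n_interior: int, degree: int = 3
) -> np.ndarray:
    """Column-centred basis: each column has zero mean over the given times.

    For any coefficient vector z, (centered_basis @ z) averages to exactly
    zero over the evaluation times, removing the intercept direction.
    """
    B = bspline_basis(t, lo, hi, n_interior, degree)
    return B - B.mean(axis=0, keepdims=True)
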