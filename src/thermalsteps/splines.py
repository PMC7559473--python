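"""Natural (restricted) cubic spline basis for temperature interactions.

The basis is the standard no-intercept natural cubic spline design used
throughout regression modelling: piecewise cubic between its boundary knots,
constrained to be linear beyond them, with ``df`` columns spanned by
``df + 1`` knots (two boundary knots plus ``df - 1`` interior knots).

The construction follows the classic recipe: build the cubic B-spline design
on the knot sequence, then project out the two second-derivative constraints
at the boundary knots via a QR decomposition, and drop the intercept column.
Evaluation outside the boundary knots extrapolates linearly (first-order
Taylor expansion at the nearest boundary knot), which is what makes the
spline "natural".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import ConfigurationError

#: df values admitted by default; mirrors the 2-3 knot constraint used to
#: keep nonlinear temperature interactions from overfitting.
ALLOWED_DF = (2, 3)


@dataclass(frozen=True)
class NaturalSplineBasis:
    """A fitted natural cubic spline basis, evaluable at arbitrary points.

    Attributes
    ----------
    boundary
        (lo, hi) boundary knots; the basis is linear outside this interval.
    interior
        Interior knots, strictly inside ``boundary``.
    projection
        (n_bsplines, df) matrix mapping the raw B-spline design onto the
        natural, intercept-free basis. Fixed by the knots alone.
    """

    boundary: tuple[float, float]
    interior: tuple[float, ...]
    projection: np.ndarray

    @property
    def df(self) -> int:
        return self.projection.shape[1]

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(([lo] * 4, self.interior, [hi] * 4))

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at ``x`` -> array of shape (len(x), df)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.boundary
        t = self.knot_vector
        n_b = len(t) - 4
        design = np.zeros((x.size, n_b))
        inner = (x >= lo) & (x <= hi)
        if inner.any():
            design[inner] = BSpline.design_matrix(x[inner], t, 3).toarray()
        for outside, knot in (((x < lo), lo), ((x > hi), hi)):
            if outside.any():
                b0 = BSpline.design_matrix(np.array([knot]), t, 3).toarray()[0]
                b1 = _bspline_derivative_row(t, knot, order=1)
                design[outside] = b0 + np.outer(x[outside] - knot, b1)
        return design @ self.projection


def _bspline_derivative_row(t: np.ndarray, x: float, order: int) -> np.ndarray:
    """Row of ``order``-th derivatives of every B-spline basis function at x."""
    n_b = len(t) - 4
    eye = np.eye(n_b)
    spl = BSpline(t, eye, 3, extrapolate=True)
    return spl.derivative(order)(x)


def natural_spline_basis(
    x: np.ndarray,
    df: int,
    boundary: tuple[float, float] | None = None,
    interior: tuple[float, ...] | None = None,
    *,
    boundary_quantiles: tuple[float, float] = (0.025, 0.975),
    allow_any_df: bool = False,
) -> tuple[np.ndarray, NaturalSplineBasis]:
    """Build a natural cubic spline basis from data and evaluate it at ``x``.

    Parameters
    ----------
    x
        Values the basis is anchored to (typically stratum temperatures).
    df
        Number of basis columns; restricted to {2, 3} unless
        ``allow_any_df`` is set.
    boundary
        Explicit boundary knots; default = the 2.5th/97.5th percentiles
        of ``x``.
    interior
        Explicit interior knots (``df - 1`` of them); default = equally
        spaced quantiles of ``x`` between the boundary quantiles.

    Returns
    -------
    (design, basis)
        The (len(x), df) design matrix and the reusable basis object.
    """
    x = np.asarray(x, dtype=float)
    if df not in ALLOWED_DF and not allow_any_df:
        raise ConfigurationError(
            f"spline df must be one of {ALLOWED_DF} (got {df}); pass allow_any_df=True to override"
        )
    if df < 1:
        raise ConfigurationError(f"spline df must be >= 1, got {df}")
    if boundary is None:
        lo, hi = np.quantile(x, boundary_quantiles)
    else:
        lo, hi = map(float, boundary)
    if not lo < hi:
        raise ConfigurationError(f"boundary knots must satisfy lo < hi, got ({lo}, {hi})")
    if interior is None:
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior = tuple(np.quantile(x[(x >= lo) & (x <= hi)], probs)) if df > 1 else ()
    interior = tuple(float(k) for k in interior)
    if len(interior) != df - 1:
        raise ConfigurationError(f"df={df} needs {df - 1} interior knots, got {len(interior)}")
    if any(not lo < k < hi for k in interior):
        raise ConfigurationError("interior knots must lie strictly inside the boundary knots")

    basis = NaturalSplineBasis(
        boundary=(lo, hi), interior=interior, projection=_projection(lo, hi, interior)
    )
    return basis.transform(x), basis


def _projection(lo: float, hi: float, interior: tuple[float, ...]) -> np.ndarray:
    """Natural-constraint + intercept-removal map for the B-spline design."""
    t = np.concatenate(([lo] * 4, interior, [hi] * 4))
    n_b = len(t) - 4
    # second derivative of each B-spline at the two boundary knots
    const = np.vstack(
        [_bspline_derivative_row(t, lo, order=2), _bspline_derivative_row(t, hi, order=2)]
    )
    # drop the intercept column, then project onto the null space of const
    const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    null = q[:, 2:]  # (n_b - 1, n_b - 3) -> df columns
    proj = np.zeros((n_b, null.shape[1]))
    proj[1:, :] = null
    return proj
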