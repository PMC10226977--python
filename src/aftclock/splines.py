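"""Monotone (integrated) spline basis for common progression curves.

A nondecreasing curve on an adjusted-age support [lo, hi] is represented as

    g(t) = intercept + sum_j w_j * I_j(t),    w_j >= 0,

where the I_j are I-splines: each is 0 at the left boundary, 1 at the
right, and nondecreasing in between.  They are built as reversed cumulative
sums of a clamped B-spline basis (the classic identity that the integral of
an M-spline is a partial sum of higher-order B-splines).  Outside the
support the basis extends flat (0 below, 1 above), so the curve is constant
beyond its support — the boundary policy used for extreme adjusted ages.

The derivative basis (an M-spline density) is exposed alongside the value
basis because the model's gradients need d g / d t.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class MonotoneBasis:
    """Shared I-spline basis on a fixed support.

    Parameters
    ----------
    lo, hi : float
        Support of the curve on the adjusted-age axis, in years.
    n_interior : int
        Number of equally spaced interior knots (default 5).
    degree : int
        Polynomial degree of the underlying B-splines (default 3, cubic).
    """

    lo: float = 40.0
    hi: float = 110.0
    n_interior: int = 5
    degree: int = 3

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("support must have hi > lo")
        if self.n_interior < 0 or self.degree < 1:
            raise ValueError("need n_interior >= 0 and degree >= 1")

    @property
    def knots(self) -> np.ndarray:
        interior = np.linspace(self.lo, self.hi, self.n_interior + 2)[1:-1]
        return np.concatenate([
            np.repeat(self.lo, self.degree + 1),
            interior,
            np.repeat(self.hi, self.degree + 1),
        ])

    @property
    def n_bspline(self) -> int:
        return self.n_interior + self.degree + 1

    @property
    def n_basis(self) -> int:
        """Number of I-spline functions (the all-ones first B-spline
        cumulative is dropped; the intercept plays that role)."""
        return self.n_bspline - 1

    @cached_property
    def _bspline(self) -> BSpline:
        return BSpline(self.knots, np.eye(self.n_bspline), self.degree,
                       extrapolate=False)

    @cached_property
    def _dbspline(self) -> BSpline:
        return self._bspline.derivative()

    def _eval_banded(self, t: np.ndarray, deriv: bool) -> np.ndarray:
        """B-spline design matrix with flat extension outside the support."""
        t = np.asarray(t, dtype=float)
        inside = np.clip(t, self.lo, np.nextafter(self.hi, self.lo))
        spl = self._dbspline if deriv else self._bspline
        vals = np.atleast_2d(spl(inside.ravel()))
        vals = np.nan_to_num(vals, nan=0.0)
        return vals

    def design(self, t) -> np.ndarray:
        """I-spline value basis, shape (len(t), n_basis); in [0, 1]."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        b = self._eval_banded(t, deriv=False)
        # I_j(t) = sum_{m >= j} B_m(t); drop j = 0 (identically 1 on support)
        design = np.cumsum(b[:, ::-1], axis=1)[:, ::-1][:, 1:]
        below = t < self.lo
        above = t >= self.hi
        design[below] = 0.0
        design[above] = 1.0
        return design

    def deriv_design(self, t) -> np.ndarray:
        """M-spline derivative basis dI_j/dt; zero outside the support."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        b = self._eval_banded(t, deriv=True)
        design = np.cumsum(b[:, ::-1], axis=1)[:, ::-1][:, 1:]
        outside = (t < self.lo) | (t >= self.hi)
        design[outside] = 0.0
        return design

    def design_pair(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Value and derivative design matrices in one pass (hot path)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        inside = np.clip(t, self.lo, np.nextafter(self.hi, self.lo))
        below = t < self.lo
        above = t >= self.hi
        v = self._bspline(inside)
        dv = self._dbspline(inside)
        np.nan_to_num(v, copy=False, nan=0.0)
        np.nan_to_num(dv, copy=False, nan=0.0)
        design = np.cumsum(v[:, ::-1], axis=1)[:, ::-1][:, 1:]
        ddesign = np.cumsum(dv[:, ::-1], axis=1)[:, ::-1][:, 1:]
        design[below] = 0.0
        design[above] = 1.0
        outside = below | above
        ddesign[outside] = 0.0
        return design, ddesign

    def shifted(self, delta: float) -> "MonotoneBasis":
        """Same basis with all knots translated by ``delta`` years."""
        return MonotoneBasis(self.lo + delta, self.hi + delta,
                             self.n_interior, self.degree)
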