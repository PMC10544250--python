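"""Shared spline machinery: B-spline design matrices and a penalized
smoothing spline with an effective-degrees-of-freedom target.

The smoother is a P-spline (cubic B-spline basis on equally spaced knots with
a second-order difference penalty). Because linear functions lie in the
penalty null space and are exactly representable by the basis, the smoother
reproduces linear signals exactly at any penalty level. The penalty is solved
so that trace of the hat matrix equals the requested effective df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import brentq

__all__ = [
    "BSplineBasis",
    "NaturalSplineBasis",
    "SmoothingSpline",
    "PenalizedSplineBasis",
]


def _augment_knots(interior: np.ndarray, lo: float, hi: float, degree: int) -> np.ndarray:
    return np.concatenate([np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)])


@dataclass
class BSplineBasis:
    """Cubic B-spline regression basis with ``df`` columns (no intercept).

    Interior knots are placed at quantiles of the data used to build the
    basis, boundary knots at its extremes, mirroring the usual regression
    spline construction. Evaluation outside the boundary clamps to the
    boundary (no polynomial extrapolation).
    """

    knots: np.ndarray
    degree: int = 3
    drop_first: bool = True

    @classmethod
    def from_data(cls, x: np.ndarray, df: int, degree: int = 3) -> "BSplineBasis":
        x = np.asarray(x, dtype=float)
        if df < 1:
            raise ValueError("df must be >= 1")
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError("basis requires non-degenerate x range")
        # df columns after dropping the first basis function (intercept overlap):
        # need df+1 basis functions = n_interior + degree + 1.
        n_interior = max(df - degree, 0)
        if n_interior > 0:
            probs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, probs)
        else:
            interior = np.array([])
        # if df < degree, lower the degree so the column count matches
        degree_eff = min(degree, df)
        return cls(knots=_augment_knots(interior, lo, hi, degree_eff), degree=degree_eff)

    @property
    def lo(self) -> float:
        return float(self.knots[0])

    @property
    def hi(self) -> float:
        return float(self.knots[-1])

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        D = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return D[:, 1:] if self.drop_first else D


@dataclass
class NaturalSplineBasis:
    """Natural cubic regression spline basis with ``df`` columns (no intercept).

    Standard truncated-power construction with linearity constraints beyond
    the boundary knots, so evaluation outside the data range extrapolates
    linearly instead of swinging like an unconstrained cubic. Knots sit at
    quantiles of the training data (boundary knots at its extremes); columns
    are standardized by their training moments for optimizer conditioning.
    """

    knots: np.ndarray
    col_mean: np.ndarray = None
    col_sd: np.ndarray = None

    @classmethod
    def from_data(cls, x: np.ndarray, df: int) -> "NaturalSplineBasis":
        x = np.asarray(x, dtype=float)
        if df < 1:
            raise ValueError("df must be >= 1")
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError("basis requires non-degenerate x range")
        if df == 1:
            knots = np.array([lo, hi])
        else:
            probs = np.linspace(0, 1, df + 1)
            knots = np.unique(np.quantile(x, probs))
            knots[0], knots[-1] = lo, hi
        basis = cls(knots=knots)
        raw = basis._raw_design(x)
        basis.col_mean = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=1)
        basis.col_sd = np.where(sd > 0, sd, 1.0)
        return basis

    def _raw_design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k = self.knots
        K = len(k)
        cols = [x]
        if K > 2:

            def d(j):
                return ((np.maximum(x - k[j], 0.0) ** 3 - np.maximum(x - k[-1], 0.0) ** 3)
                        / (k[-1] - k[j]))

            dK1 = d(K - 2)
            for j in range(K - 2):
                cols.append(d(j) - dK1)
        return np.column_stack(cols)

    def design(self, x: np.ndarray) -> np.ndarray:
        raw = self._raw_design(x)
        return (raw - self.col_mean) / self.col_sd


@dataclass
class PenalizedSplineBasis:
    """Cubic P-spline basis with a second-difference penalty and a weighted
    effective-df calibration.

    Used for smooth parameter curves inside distributional regression: the
    basis spans equally spaced knots over the data range, the penalty pulls
    toward linearity, and ``calibrate`` solves the penalty level so the
    weighted linear smoother has the requested effective df — so the curve
    behaves like a smoothing spline rather than an unconstrained regression
    spline, staying tame where data are sparse or down-weighted.
    """

    knots: np.ndarray
    degree: int = 3
    lam: float = 1.0

    @classmethod
    def from_data(cls, x: np.ndarray, n_basis: int = 12, degree: int = 3
                  ) -> "PenalizedSplineBasis":
        x = np.asarray(x, dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError("basis requires non-degenerate x range")
        n_interior = max(n_basis - degree - 1, 0)
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return cls(knots=_augment_knots(interior, lo, hi, degree), degree=degree)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[-1])
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def penalty(self) -> np.ndarray:
        D2 = np.diff(np.eye(self.n_basis), n=2, axis=0)
        return D2.T @ D2

    def calibrate(self, x: np.ndarray, w: np.ndarray, target_df: float) -> float:
        """Set ``lam`` so the weighted smoother has ~``target_df`` edf."""
        B = self.design(x)
        W = np.asarray(w, dtype=float)
        BtWB = B.T @ (B * W[:, None])
        P = self.penalty()
        p = B.shape[1]
        jitter = 1e-10 * np.trace(BtWB) / p

        def edf(log_lam):
            A = BtWB + (10.0**log_lam) * P + jitter * np.eye(p)
            return float(np.trace(np.linalg.solve(A, BtWB)))

        lo_l, hi_l = -8.0, 14.0
        if target_df >= edf(lo_l):
            log_lam = lo_l
        elif target_df <= edf(hi_l):
            log_lam = hi_l
        else:
            log_lam = brentq(lambda t: edf(t) - target_df, lo_l, hi_l, xtol=1e-8)
        self.lam = 10.0**log_lam
        return self.lam


def _curvature_penalty(knots: np.ndarray, degree: int) -> np.ndarray:
    """Gram matrix of basis second derivatives, int B_i'' B_j'' dx.

    For cubic B-splines the second derivatives are piecewise linear, so
    two-point Gauss quadrature per knot interval is exact.
    """
    p = len(knots) - degree - 1
    spl2 = BSpline(knots, np.eye(p), degree).derivative(2)
    breaks = np.unique(knots)
    P = np.zeros((p, p))
    g = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        for gx in g:
            D = np.atleast_2d(spl2(mid + half * gx))[0]
            P += half * np.outer(D, D)
    return P


@dataclass
class SmoothingSpline:
    """Cubic smoothing spline solved to a target effective df.

    Fit minimizes ||y - B c||^2 + lam * int f''(x)^2 dx over B-spline
    coefficients c (exact curvature penalty), with lam chosen by root
    finding so that the smoother's trace hits ``df``. Linear signals lie in
    the penalty null space and are reproduced exactly at any lam.
    """

    df: float = 3.0
    n_basis: int = 30
    degree: int = 3
    knots_: np.ndarray = field(default=None, repr=False)
    coef_: np.ndarray = field(default=None, repr=False)
    edf_: float = field(default=None)
    lam_: float = field(default=None)
    x_range_: tuple = field(default=None)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SmoothingSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        n_distinct = np.unique(x).size
        if n_distinct < self.df + 1:
            raise ValueError(
                f"need at least {int(self.df) + 1} distinct x values, got {n_distinct}"
            )
        lo, hi = float(x.min()), float(x.max())
        self.x_range_ = (lo, hi)
        K = int(min(self.n_basis, n_distinct))
        # equally spaced interior knots keep linear functions in the penalty
        # null space exactly
        n_interior = max(K - self.degree - 1, 0)
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        self.knots_ = _augment_knots(interior, lo, hi, self.degree)
        B = BSpline.design_matrix(x, self.knots_, self.degree).toarray()
        p = B.shape[1]
        P = _curvature_penalty(self.knots_, self.degree)
        BtB = B.T @ B
        # normalize the penalty scale so the lam search range is
        # data-independent and large lam stays numerically benign
        P = P * (np.trace(BtB) / np.trace(P))
        Bty = B.T @ y
        # ridge jitter guards rank deficiency when knots outnumber support
        jitter = 1e-10 * np.trace(BtB) / p

        def edf(log_lam: float) -> float:
            A = BtB + (10.0**log_lam) * P + jitter * np.eye(p)
            return float(np.trace(np.linalg.solve(A, BtB)))

        target = float(self.df)
        lo_l, hi_l = -8.0, 14.0
        e_lo, e_hi = edf(lo_l), edf(hi_l)
        if target >= e_lo:  # unpenalized fit already at/below target df
            log_lam = lo_l
        elif target <= e_hi:
            log_lam = hi_l
        else:
            log_lam = brentq(lambda t: edf(t) - target, lo_l, hi_l, xtol=1e-8)
        lam = 10.0**log_lam
        A = BtB + lam * P + jitter * np.eye(p)
        self.coef_ = np.linalg.solve(A, Bty)
        self.lam_ = lam
        self.edf_ = float(np.trace(np.linalg.solve(A, BtB)))
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("SmoothingSpline is not fitted")
        x = np.clip(np.asarray(x, dtype=float), *self.x_range_)
        B = BSpline.design_matrix(x, self.knots_, self.degree).toarray()
        return B @ self.coef_
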