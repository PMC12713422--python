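"""Penalized regression splines with automatic smoothness selection.

Implements the P-spline approach of Eilers & Marx: a cubic B-spline basis of
moderate dimension combined with a second-order difference penalty on the
coefficients.  The penalty weight is chosen by generalized cross-validation
(GCV), which makes the smoother parameter-free from the caller's point of
view apart from the basis dimension.  The fitted curve is an honest
:class:`scipy.interpolate.BSpline`, so its derivative is available
analytically rather than by finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import InsufficientDataError

__all__ = ["PenalizedSplineSmoother"]


def _bspline_knots(lo: float, hi: float, n_basis: int, degree: int = 3) -> np.ndarray:
    """Clamped uniform knot vector giving exactly ``n_basis`` basis functions."""
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError(f"n_basis must be >= {degree + 1}, got {n_basis}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _second_difference_penalty(n_basis: int) -> np.ndarray:
    d = np.diff(np.eye(n_basis), n=2, axis=0)
    return d.T @ d


@dataclass
class PenalizedSplineSmoother:
    """Cubic penalized regression spline of y on x.

    Parameters
    ----------
    n_basis:
        Dimension of the B-spline basis (number of coefficients).
    lam:
        Penalty weight.  ``None`` (default) selects it by GCV over
        ``lam_grid``.
    lam_grid:
        Candidate penalty weights searched by GCV.  The default spans
        twelve decades, which is wide enough for trajectories whose x
        range is O(100) and y range is O(1).
    """

    n_basis: int = 20
    lam: float | None = None
    lam_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 8, 49), repr=False
    )
    degree: int = 3

    # set by fit()
    knots_: np.ndarray | None = None
    coef_: np.ndarray | None = None
    lam_: float | None = None
    gcv_: float | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "PenalizedSplineSmoother":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 10:
            raise InsufficientDataError(
                f"need >= 10 finite observations to fit the smoother, got {x.size}"
            )
        self.knots_ = _bspline_knots(float(x.min()), float(x.max()), self.n_basis, self.degree)
        X = BSpline.design_matrix(x, self.knots_, self.degree).toarray()
        P = _second_difference_penalty(self.n_basis)
        XtX = X.T @ X
        Xty = X.T @ y

        if self.lam is not None:
            self.lam_ = float(self.lam)
            self.coef_ = np.linalg.solve(XtX + self.lam_ * P, Xty)
            self.gcv_ = None
            return self

        n = x.size
        best = (np.inf, None, None)
        for lam in self.lam_grid:
            A = XtX + lam * P
            try:
                coef = np.linalg.solve(A, Xty)
                # effective degrees of freedom: tr(X (X'X + lam P)^-1 X')
                edf = float(np.trace(np.linalg.solve(A, XtX)))
            except np.linalg.LinAlgError:  # pragma: no cover - defensive
                continue
            resid = y - X @ coef
            denom = max(n - edf, 1e-8)
            gcv = n * float(resid @ resid) / denom**2
            if gcv < best[0]:
                best = (gcv, lam, coef)
        self.gcv_, self.lam_, self.coef_ = best
        return self

    # -- prediction ---------------------------------------------------------
    def _check_fitted(self) -> None:
        if self.coef_ is None:
            raise RuntimeError("smoother is not fitted")

    def spline(self) -> BSpline:
        self._check_fitted()
        return BSpline(self.knots_, self.coef_, self.degree, extrapolate=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.spline()(np.asarray(x, dtype=float))

    def derivative(self, x: np.ndarray) -> np.ndarray:
        """Analytic first derivative of the fitted spline at x."""
        return self.spline().derivative(1)(np.asarray(x, dtype=float))

    # -- uncertainty --------------------------------------------------------
    def bootstrap_band(
        self,
        x: np.ndarray,
        y: np.ndarray,
        eval_x: np.ndarray,
        n_boot: int = 200,
        seed: int | None = None,
        z: float = 1.959964,
    ) -> tuple[np.ndarray, np.ndarray] | None:
        """Pointwise 95% band by case-resampling bootstrap.

        Refits at the GCV-selected penalty of the full-data fit, evaluates each
        replicate at ``eval_x`` and returns ``fit ± z·SD`` so the band is
        centered on (and always contains) the full-data fitted curve.  Returns
        ``None`` when ``n_boot`` is 0.
        """
        self._check_fitted()
        if n_boot <= 0:
            return None
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        rng = np.random.default_rng(seed)
        preds = np.empty((n_boot, np.asarray(eval_x).size))
        for b in range(n_boot):
            idx = rng.integers(0, x.size, size=x.size)
            sm = PenalizedSplineSmoother(
                n_basis=self.n_basis, lam=self.lam_, degree=self.degree
            )
            try:
                sm.fit(x[idx], y[idx])
            except InsufficientDataError:  # pragma: no cover - n >= 10 resamples
                preds[b] = np.nan
                continue
            # points outside a resample's x-span evaluate to NaN and are
            # ignored by nanstd
            preds[b] = sm.predict(eval_x)
        sd = np.nanstd(preds, axis=0)
        center = self.predict(eval_x)
        return center - z * sd, center + z * sd
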