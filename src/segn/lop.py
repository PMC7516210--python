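"""Legendre orthogonal polynomial (LOP) curves.

Nonparametric time-course curves are represented in the Legendre basis on
[-1, 1], with observed time (possibly unevenly spaced) mapped affinely onto
that interval.  The same basis doubles as the representation of the
component functions of the regulatory ODE, where the argument is an
expression value rather than time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["legendre_basis", "AffineMap", "LopCurve", "fit_lop_curve", "select_lop_order"]


def legendre_basis(x, order: int) -> np.ndarray:
    """Evaluate Legendre polynomials L_0..L_order at ``x`` in [-1, 1].

    Parameters
    ----------
    x : float or array-like
        Evaluation points; must lie in [-1, 1].
    order : int
        Highest polynomial degree (>= 0).

    Returns
    -------
    ndarray with trailing dimension ``order + 1``.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    x = np.asarray(x, dtype=float)
    if np.any(x < -1.0 - 1e-12) or np.any(x > 1.0 + 1e-12):
        raise ValueError("Legendre basis argument outside [-1, 1]")
    out = npleg.legvander(np.clip(x, -1.0, 1.0), order)
    return out[0] if x.ndim == 0 else out


@dataclass(frozen=True)
class AffineMap:
    """Affine map [lo, hi] -> [-1, 1]; degenerate ranges map to 0."""

    lo: float
    hi: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.hi <= self.lo:
            return np.zeros_like(t)
        return 2.0 * (t - self.lo) / (self.hi - self.lo) - 1.0

    @property
    def scale(self) -> float:
        """d(mapped)/dt, used for chain-rule derivatives."""
        if self.hi <= self.lo:
            return 0.0
        return 2.0 / (self.hi - self.lo)


@dataclass
class LopCurve:
    """A Legendre-series curve over a real domain.

    ``coefficients[k]`` multiplies L_k of the affinely mapped argument.
    """

    coefficients: np.ndarray
    domain: tuple[float, float]
    mapper: AffineMap = field(init=False, repr=False)

    def __post_init__(self):
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        self.mapper = AffineMap(*self.domain)

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t, extrapolate: bool = False):
        x = self.mapper(t)
        if not extrapolate:
            if np.any(x < -1.0 - 1e-9) or np.any(x > 1.0 + 1e-9):
                raise ValueError(f"evaluation outside domain {self.domain}")
            x = np.clip(x, -1.0, 1.0)
        return npleg.legval(x, self.coefficients)

    def derivative(self) -> "LopCurve":
        """Analytic derivative with respect to the *unmapped* argument."""
        dcoef = npleg.legder(self.coefficients) if self.order > 0 else np.zeros(1)
        out = LopCurve(np.atleast_1d(dcoef) * self.mapper.scale, self.domain)
        return out

    def grid(self, n: int) -> np.ndarray:
        return np.linspace(self.domain[0], self.domain[1], n)


def fit_lop_curve(times, values, order: int, domain=None) -> LopCurve:
    """Least-squares LOP fit of ``values`` observed at ``times``.

    Requires at least ``order + 1`` observations; the time domain defaults
    to [min(times), max(times)].
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have the same shape")
    if len(times) < order + 1:
        raise ValueError(
            f"under-determined fit: order {order} needs >= {order + 1} points, got {len(times)}"
        )
    if domain is None:
        domain = (float(times.min()), float(times.max()))
    mapper = AffineMap(*domain)
    basis = legendre_basis(mapper(times), order)
    coef, *_ = np.linalg.lstsq(basis, values, rcond=None)
    return LopCurve(coef, domain)


def select_lop_order(times, values, orders=range(2, 7)) -> LopCurve:
    """Fit each candidate order and return the AIC-minimizing curve.

    AIC = n log(RSS/n) + 2 (r + 1), with a small RSS floor to keep exact
    interpolation finite.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(times)
    best, best_aic = None, np.inf
    for r in orders:
        if r + 1 > n:
            continue
        curve = fit_lop_curve(times, values, r)
        rss = float(np.sum((curve(times) - values) ** 2))
        aic = n * np.log(max(rss, 1e-300) / n) + 2.0 * (r + 1)
        if aic < best_aic:
            best, best_aic = curve, aic
    if best is None:
        raise ValueError("no candidate order is identifiable with this many points")
    return best
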