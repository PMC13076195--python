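"""Per-person penalized-spline smooths and instantaneous rates of change.

Each participant's daily SRBAI composite is smoothed with a cubic B-spline
basis (basis dimension set by the observation-count knot rule: 5, 10 or 15
for <=10, <=20 and >20 observations), penalized by the integrated squared
second derivative, with the smoothing parameter chosen by generalized
cross-validation. The instantaneous rate of change is the analytic first
derivative of the fitted spline; weekly rates average it over integer days
0-6 (week 1) and 7-13 (week 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .preprocess import PersonSeries

__all__ = [
    "GamFit",
    "WeeklyRate",
    "knot_count",
    "has_sufficient_data",
    "fit_gam",
    "instantaneous_rate",
    "weekly_rate",
]

_DEGREE = 3
_RIDGE = 1e-9
_LAMBDA_GRID = np.logspace(-5, 7, 49)


def knot_count(n_obs: int) -> int:
    """Basis dimension from the observation-count rule (5 / 10 / 15)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if n_obs <= 10:
        return 5
    if n_obs <= 20:
        return 10
    return 15


def has_sufficient_data(series) -> bool:
    """True iff observations exist in week 1 (t 0-6), week 2 (t 7-13) and after."""
    t = series.t if isinstance(series, PersonSeries) else np.asarray(series)
    t = np.asarray(t, dtype=float)
    return bool(((t >= 0) & (t <= 6)).any() and ((t >= 7) & (t <= 13)).any() and (t >= 14).any())


@dataclass
class GamFit:
    participant_id: str
    knots: int                   # basis dimension from the knot rule
    sufficient_data: bool
    edf: float = math.nan        # effective degrees of freedom
    lam: float = math.nan        # selected smoothing parameter
    spline: BSpline | None = None
    t_min: float = math.nan
    t_max: float = math.nan

    def predict(self, t):
        self._check_range(t)
        return self.spline(np.asarray(t, dtype=float))

    def derivative(self, t):
        self._check_range(t)
        return self.spline.derivative(1)(np.asarray(t, dtype=float))

    def _check_range(self, t):
        if self.spline is None:
            raise ValueError(f"no fitted smooth for {self.participant_id}")
        t = np.asarray(t, dtype=float)
        if (t < self.t_min - 1e-9).any() or (t > self.t_max + 1e-9).any():
            raise ValueError(
                f"t outside fitted range [{self.t_min}, {self.t_max}] for {self.participant_id}"
            )


@dataclass
class WeeklyRate:
    week1_rate: float
    week2_rate: float


def _knot_vector(t: np.ndarray, n_basis: int) -> np.ndarray:
    """Clamped cubic knot vector on [0, max t] with quantile interior knots."""
    a, b = 0.0, float(t.max())
    n_interior = n_basis - _DEGREE - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(t), qs)
        # keep knots strictly inside and strictly increasing
        interior = np.clip(interior, a + 1e-6, b - 1e-6)
        interior = np.maximum.accumulate(interior + np.arange(n_interior) * 1e-9)
    else:
        interior = np.array([])
    return np.concatenate([[a] * (_DEGREE + 1), interior, [b] * (_DEGREE + 1)])


def _design(knots: np.ndarray, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    n_basis = len(knots) - _DEGREE - 1
    if deriv == 0:
        return BSpline.design_matrix(x, knots, _DEGREE).toarray()
    D = np.empty((len(x), n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        D[:, j] = BSpline(knots, c, _DEGREE)(x, nu=deriv)
    return D


def _penalty(knots: np.ndarray) -> np.ndarray:
    """Exact integral of products of second derivatives (2-pt Gauss per span)."""
    breaks = np.unique(knots)
    gauss = np.array([-1.0, 1.0]) / math.sqrt(3.0)
    n_basis = len(knots) - _DEGREE - 1
    S = np.zeros((n_basis, n_basis))
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        pts = 0.5 * (a + b) + half * gauss
        D2 = _design(knots, pts, deriv=2)
        S += half * (D2.T @ D2)  # equal Gauss weights of 1
    return S


def fit_gam(series, *, lam: float | None = None) -> GamFit:
    """Fit one participant's penalized spline smooth.

    ``lam`` overrides the GCV-selected smoothing parameter (``0`` gives the
    unpenalized regression spline). Series failing the sufficiency rule, or
    with a degenerate time axis, come back flagged insufficient.
    """
    if isinstance(series, PersonSeries):
        pid, t, y = series.participant_id, series.t.astype(float), series.srbai.astype(float)
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
        pid = ""
    k = knot_count(len(t))
    if not has_sufficient_data(t) or len(np.unique(t)) < 2:
        return GamFit(pid, k, False)

    knots = _knot_vector(t, k)
    X = _design(knots, t)
    S = _penalty(knots)
    XtX, Xty = X.T @ X, X.T @ y
    n = len(y)
    eye = np.eye(XtX.shape[0])

    def solve(lam_val):
        A = XtX + lam_val * S + _RIDGE * eye
        beta = np.linalg.solve(A, Xty)
        edf = float(np.trace(np.linalg.solve(A, XtX)))
        rss = float(((y - X @ beta) ** 2).sum())
        return beta, edf, rss

    if lam is None:
        best = (math.inf, None)
        for lam_val in _LAMBDA_GRID:
            beta, edf, rss = solve(lam_val)
            denom = n - edf
            if denom < 1e-3:
                continue
            gcv = n * rss / denom**2
            if gcv < best[0]:
                best = (gcv, lam_val)
        lam = best[1] if best[1] is not None else float(_LAMBDA_GRID[-1])
    beta, edf, _ = solve(lam)
    spline = BSpline(knots, beta, _DEGREE)
    return GamFit(pid, k, True, edf=edf, lam=float(lam), spline=spline,
                  t_min=0.0, t_max=float(t.max()))


def instantaneous_rate(fit: GamFit, t):
    """Analytic first derivative of the fitted smooth at ``t`` (score/day)."""
    return fit.derivative(t)


def weekly_rate(fit: GamFit, *, grid: str = "integer") -> WeeklyRate:
    """Average instantaneous rate over week 1 (t 0-6) and week 2 (t 7-13).

    ``grid="integer"`` (default) averages over the integer days the diary
    design samples; ``grid="dense"`` averages over a 0.01-day grid. Windows
    truncated by the fitted range use only covered days; an uncovered window
    is missing.
    """
    if not fit.sufficient_data or fit.spline is None:
        return WeeklyRate(math.nan, math.nan)
    step = 1.0 if grid == "integer" else 0.01
    if grid not in ("integer", "dense"):
        raise ValueError(f"unknown grid {grid!r}")

    def window(lo, hi):
        pts = np.arange(lo, min(hi, fit.t_max) + step / 2, step)
        pts = pts[pts <= fit.t_max + 1e-9]
        if len(pts) == 0:
            return math.nan
        return float(np.mean(fit.derivative(pts)))

    return WeeklyRate(window(0.0, 6.0), window(7.0, 13.0))
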