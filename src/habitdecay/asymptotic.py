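"""Per-person asymptotic decay model of habit strength.

The trajectory is the three-parameter negative-exponential curve

    y(t) = asym + (r0 - asym) * exp(-exp(lrc) * t)

with r0 the response at centered time 0, asym the lower asymptote, and lrc
the natural-log rate constant (per day). Fitting is nonlinear least squares
with a deterministic multi-start: for each rate constant on a log-spaced
grid the two linear parameters are solved in closed form, and the best
start is polished with a bounded trust-region solver. Validity follows the
preregistered criteria (decreasing trend, RMSE <= 0.33, no observation gap
longer than 21 days), and the time to reach 95% of the total decline has
the closed form t95 = ln(20) / exp(lrc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import latent_srbai
from .preprocess import PersonSeries

__all__ = [
    "AsymptoticFit",
    "AsymptoteOutcome",
    "fit_asymptotic",
    "assess_validity",
    "time_to_95",
    "asymptote_outcome",
]

RMSE_MAX = 0.33          # model-accuracy validity bound
MAX_GAP_DAYS = 21        # longest tolerated gap between observations
_LEVEL_BOUNDS = (-1.0, 5.0)   # soft bounds for r0/asym, slightly beyond 0-4
_LRC_BOUNDS = (math.log(1e-4), math.log(10.0))
_LN20 = math.log(20.0)
#: Minimum r0 - asym (score units) counting as a decreasing trend; guards
#: against flat fits where the optimizer leaves a sub-numerical decline.
_DECREASE_EPS = 1e-6


@dataclass
class AsymptoticFit:
    r0: float
    asym: float
    lrc: float
    rmse: float
    n_obs: int
    max_gap_days: int
    converged: bool


@dataclass
class AsymptoteOutcome:
    valid: bool
    reached95: int
    t95_days: float  # nan unless valid and reached95 == 1
    reasons: list = field(default_factory=list)


def _linear_solve(t: np.ndarray, y: np.ndarray, k: float):
    """Closed-form (asym, r0) for fixed rate constant k, with SSE."""
    e = np.exp(-k * t)
    X = np.column_stack([1.0 - e, e])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    asym, r0 = np.clip(coef, *_LEVEL_BOUNDS)
    sse = float(((y - (asym * (1 - e) + r0 * e)) ** 2).sum())
    return asym, r0, sse


def _max_gap(t: np.ndarray) -> int:
    if len(t) < 2:
        return 0
    return int(np.diff(np.sort(t)).max() - 1)


def fit_asymptotic(series) -> AsymptoticFit:
    """Least-squares asymptotic fit of one cleaned series.

    Accepts a :class:`PersonSeries` or a ``(t, y)`` pair. Fewer than three
    observations yield a non-converged fit.
    """
    if isinstance(series, PersonSeries):
        t, y = series.t.astype(float), series.srbai.astype(float)
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
    n = len(t)
    gap = _max_gap(t.astype(int))
    if n < 3:
        return AsymptoticFit(math.nan, math.nan, math.nan, math.nan, n, gap, False)

    # deterministic multi-start over the rate constant
    starts = []
    for lk in np.linspace(math.log(0.01), 0.0, 25):
        k = math.exp(lk)
        asym, r0, sse = _linear_solve(t, y, k)
        starts.append((sse, asym, r0, lk))
    starts.sort(key=lambda s: s[0])

    def resid(p):
        return latent_srbai(t, p[0], p[1], p[2]) - y

    lo = [_LEVEL_BOUNDS[0], _LEVEL_BOUNDS[0], _LRC_BOUNDS[0]]
    hi = [_LEVEL_BOUNDS[1], _LEVEL_BOUNDS[1], _LRC_BOUNDS[1]]
    best = None
    for sse, asym, r0, lk in starts[:3]:
        x0 = [np.clip(r0, *_LEVEL_BOUNDS), np.clip(asym, *_LEVEL_BOUNDS), lk]
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if sol.x is None or not np.isfinite(sol.cost):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return AsymptoticFit(math.nan, math.nan, math.nan, math.nan, n, gap, False)

    r0, asym, lrc = best.x
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return AsymptoticFit(float(r0), float(asym), float(lrc), rmse, n, gap, True)


def assess_validity(fit: AsymptoticFit, *, rmse_max: float = RMSE_MAX,
                    max_gap_days: int = MAX_GAP_DAYS):
    """Validity flag and the list of failed criteria.

    Valid iff the fit converged, approaches a lower asymptote (asym < r0
    strictly), RMSE <= ``rmse_max`` and the longest observation gap is at
    most ``max_gap_days``.
    """
    reasons = []
    if not fit.converged:
        return False, ["non-converged"]
    if not (fit.r0 - fit.asym > _DECREASE_EPS):
        reasons.append("non-decreasing")
    if fit.rmse > rmse_max:
        reasons.append("rmse")
    if fit.max_gap_days > max_gap_days:
        reasons.append("gap")
    return (not reasons), reasons


def time_to_95(fit: AsymptoticFit) -> float:
    """Days until 95% of the total decline (r0 - asym) is realized.

    Solves asym + (r0 - asym) * exp(-k t) = asym + 0.05 (r0 - asym), i.e.
    t95 = ln(20) / exp(lrc). Missing when the fit does not decrease.
    """
    if not fit.converged or not (fit.asym < fit.r0):
        return math.nan
    return _LN20 / math.exp(fit.lrc)


def asymptote_outcome(fit: AsymptoticFit, series) -> AsymptoteOutcome:
    """Reached-95%-asymptote dummy and days-to-95% for one participant.

    Non-valid models are scored 0. A valid model scores 1 iff t95 falls
    within the participant's observed series (t95 <= last observed t), and
    only then is t95 reported.
    """
    valid, reasons = assess_validity(fit)
    if isinstance(series, PersonSeries):
        last_t = float(series.t.max()) if not series.is_empty else -math.inf
    else:
        t = np.asarray(series, dtype=float)
        last_t = float(t.max()) if t.size else -math.inf
    if not valid:
        return AsymptoteOutcome(False, 0, math.nan, reasons)
    t95 = time_to_95(fit)
    if t95 <= last_t:
        return AsymptoteOutcome(True, 1, t95, reasons)
    return AsymptoteOutcome(True, 0, math.nan, reasons)
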