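"""SESOIs, ROPEs, TOST equivalence tests and simulation-based power.

Each trial outcome carries a smallest effect size of interest (SESOI):
0.5 SRBAI points for magnitude of change, an odds-ratio band of 0.80-1.25
for reaching the asymptote, +/-0.034 score/day for the weekly rate (95% of
the 0.5-point SESOI spread over 14 days), and +/-1 day for days-to-95%.
ROPEs live on the analysis scale (identity, log odds, or log days anchored
at a reference mean). Equivalence uses two one-sided t tests paired with a
90% CI three-way decision rule; power-detection simulates the design with
a true effect equal to the SESOI and reports the rejection rate of the
matching group analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import inference

__all__ = [
    "SesoiSpec",
    "TostResult",
    "PowerEstimate",
    "sesoi_registry",
    "rate_sesoi_from_magnitude",
    "magnitude_from_rate",
    "rope_bounds",
    "tost",
    "classify_equivalence",
    "power_detection",
]

BASELINE_ASYMPTOTE_PREVALENCE = 0.22  # observed share reaching 95% asymptote previously


@dataclass(frozen=True)
class SesoiSpec:
    outcome: str
    sesoi: float | tuple[float, float]
    scale: str  # "identity" | "log-odds" | "log"


@dataclass
class TostResult:
    estimate: float
    ci90: tuple[float, float]
    p_tost: float
    decision: str  # "accepted" | "rejected" | "undecided"


@dataclass
class PowerEstimate:
    label: str
    power: float
    mc_se: float
    nsim: int
    alpha: float
    design: dict
    seed: int


def rate_sesoi_from_magnitude(magnitude: float = 0.5, coverage: float = 0.95,
                              window_days: float = 14.0) -> float:
    """Rate SESOI: the mean daily rate realizing ``coverage`` of the
    magnitude SESOI within ``window_days`` ([0.5 x 0.95] / 14 ~= 0.034)."""
    return round(magnitude * coverage / window_days, 3)


def magnitude_from_rate(rate: float, days: float) -> float:
    """Score change implied by a constant daily rate over ``days`` days."""
    return rate * days


def sesoi_registry() -> list[SesoiSpec]:
    """The four outcome SESOIs on their analysis scales."""
    return [
        SesoiSpec("magnitude", 0.5, "identity"),
        SesoiSpec("asymptote_likelihood", (0.80, 1.25), "log-odds"),
        SesoiSpec("rate", rate_sesoi_from_magnitude(), "identity"),
        SesoiSpec("days_to_95", 1.0, "log"),
    ]


def rope_bounds(spec: SesoiSpec, reference_mean: float | None = None,
                ndigits: int | None = None) -> tuple[float, float]:
    """Region of practical equivalence on the analysis scale.

    Identity: +/- sesoi. Log-odds: log of the odds-ratio band. Log days:
    [ln((m-1)/m), ln((m+1)/m)] anchored at the reference group's
    back-transformed adjusted mean ``m`` (the +/-1 day SESOI on the log
    scale). ``ndigits`` optionally rounds the bounds for display.
    """
    if spec.scale == "identity":
        lo, hi = -float(spec.sesoi), float(spec.sesoi)
    elif spec.scale == "log-odds":
        lo, hi = math.log(spec.sesoi[0]), math.log(spec.sesoi[1])
    elif spec.scale == "log":
        if reference_mean is None:
            raise ValueError("log-days ROPE needs a reference mean")
        m, d = float(reference_mean), float(spec.sesoi)
        if m <= d:
            raise ValueError(f"reference mean {m} must exceed the {d}-day SESOI")
        lo, hi = math.log((m - d) / m), math.log((m + d) / m)
    else:
        raise ValueError(f"unknown scale {spec.scale!r}")
    if ndigits is not None:
        lo, hi = round(lo, ndigits), round(hi, ndigits)
    return lo, hi


def classify_equivalence(ci90, rope) -> str:
    """Three-way decision: accepted if the 90% CI lies completely within
    the ROPE (inclusive); otherwise rejected when the CI excludes 0,
    undecided when it contains 0."""
    lo, hi = ci90
    rlo, rhi = rope
    if lo > hi or rlo > rhi:
        raise ValueError("intervals must be ordered")
    if rlo <= lo and hi <= rhi:
        return "accepted"
    if lo > 0 or hi < 0:
        return "rejected"
    return "undecided"


def tost(estimate: float, se: float, df: float, rope) -> TostResult:
    """Two one-sided t tests of ``estimate`` against the ROPE bounds.

    p_tost is the larger of the two one-sided p values; the 90% CI is
    estimate +/- t(0.95, df) * se, and the decision follows the CI rule.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    rlo, rhi = rope
    if rlo > rhi:
        raise ValueError("rope must be ordered")
    p_lower = float(stats.t.sf((estimate - rlo) / se, df))   # H0: effect <= lower bound
    p_upper = float(stats.t.cdf((estimate - rhi) / se, df))  # H0: effect >= upper bound
    crit = stats.t.ppf(0.95, df)
    ci90 = (estimate - crit * se, estimate + crit * se)
    p_tost = max(p_lower, p_upper)
    return TostResult(estimate, ci90, p_tost, classify_equivalence(ci90, rope))


def _pooled_t_power(effect, arm_ns, arm_sds, alpha, nsim, rng):
    """Vectorized two-arm pooled t-test rejection rate (group B shifted)."""
    n1, n2 = arm_ns
    s1, s2 = arm_sds
    a = rng.normal(0.0, s1, (nsim, n1))
    b = rng.normal(effect, s2, (nsim, n2))
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    crit = stats.t.ppf(1 - alpha / 2, n1 + n2 - 2)
    return np.abs(t) > crit


def _logistic_two_arm_power(log_or, arm_ns, p0, alpha, nsim, rng):
    """Vectorized Wald test from 2x2 counts (saturated logistic MLE)."""
    n1, n2 = arm_ns
    p1 = 1.0 / (1.0 + math.exp(-(math.log(p0 / (1 - p0)) + log_or)))
    a = rng.binomial(n1, p0, nsim).astype(float)
    b = rng.binomial(n2, p1, nsim).astype(float)
    # continuity: degenerate margins cannot reject
    ok = (a > 0) & (a < n1) & (b > 0) & (b < n2)
    beta = np.zeros(nsim)
    se = np.full(nsim, np.inf)
    beta[ok] = np.log(b[ok] / (n2 - b[ok])) - np.log(a[ok] / (n1 - a[ok]))
    se[ok] = np.sqrt(1 / a[ok] + 1 / (n1 - a[ok]) + 1 / b[ok] + 1 / (n2 - b[ok]))
    crit = stats.norm.ppf(1 - alpha / 2)
    return np.abs(beta / se) > crit


_STRATEGIES = ("inhibition", "substitution", "reduced-accessibility")
_REWARDS = ("no", "yes")


def _cell_shifted(cell, effect_on) -> bool:
    """Whether a factorial cell receives the SESOI shift.

    ``effect_on`` is ``("strategy", level)``, ``("reward", level)`` or
    ``("cell", (strategy, reward))``.
    """
    s, r = cell
    kind, target = effect_on
    if kind == "strategy":
        return s == target
    if kind == "reward":
        return r == target
    if kind == "cell":
        return (s, r) == tuple(target)
    raise ValueError(f"unknown effect_on {effect_on!r}")


def _factorial_cells(cell_ns):
    return [((s, r), cell_ns.get((s, r), 0)) for s in _STRATEGIES for r in _REWARDS]


def _factorial_anova_power(effect, cell_ns, cell_sds, effect_on, test_effect,
                           alpha, nsim, rng):
    """Loop simulation of the 3x2 factorial ANOVA; rejects on ``test_effect``."""
    import pandas as pd

    cells = _factorial_cells(cell_ns)
    reject = np.zeros(nsim, dtype=bool)
    for i in range(nsim):
        frames = []
        for cell, n in cells:
            mu = effect if _cell_shifted(cell, effect_on) else 0.0
            y = rng.normal(mu, cell_sds.get(cell, 1.0), n)
            frames.append(pd.DataFrame({"y": y, "strategy": cell[0], "reward": cell[1]}))
        df = pd.concat(frames, ignore_index=True)
        res = inference.anova_rate(df, "y", ["strategy", "reward"])
        reject[i] = res.effect(test_effect).p < alpha
    return reject


def _factorial_logistic_power(log_or, cell_ns, p0, effect_on, test_effect,
                              alpha, nsim, rng):
    """Loop simulation of the factorial logistic regression (LR tests)."""
    import pandas as pd

    eta0 = math.log(p0 / (1 - p0))
    cells = _factorial_cells(cell_ns)
    reject = np.zeros(nsim, dtype=bool)
    for i in range(nsim):
        frames = []
        for cell, n in cells:
            p = 1.0 / (1.0 + math.exp(-(eta0 + (log_or if _cell_shifted(cell, effect_on) else 0.0))))
            frames.append(pd.DataFrame({
                "y": rng.binomial(1, p, n), "strategy": cell[0], "reward": cell[1]}))
        df = pd.concat(frames, ignore_index=True)
        try:
            res = inference.logistic_asymptote(df, "y", ["strategy", "reward"], covariate=None)
            eff = res.effect(test_effect)
            reject[i] = eff.estimable and eff.p < alpha
        except Exception:
            reject[i] = False
    return reject


def power_detection(sesoi: float, design: dict, analysis: str, nsim: int = 10000,
                    alpha: float = 0.05, seed: int = 0, label: str = "") -> PowerEstimate:
    """Simulation-based power to detect a true effect equal to the SESOI.

    ``analysis`` selects the matching group analysis:

    * ``"t_two_arm"`` -- continuous outcome, two groups (pooled-variance t,
      identical to the one-way ANOVA F); ``design`` needs ``arm_ns`` and
      ``arm_sds``.
    * ``"logistic_two_arm"`` -- binary outcome, two groups; ``sesoi`` is a
      log odds ratio; ``design`` needs ``arm_ns`` and optionally
      ``baseline_prevalence`` (default 0.22).
    * ``"anova_factorial"`` -- strategy x reward factorial ANOVA; ``design``
      needs ``cell_ns``, ``cell_sds``, ``effect_on`` (the margin or cell
      receiving the SESOI shift) and ``test_effect``.
    * ``"logistic_factorial"`` -- factorial logistic regression with LR
      tests; ``design`` as above plus optional ``baseline_prevalence``.

    Deterministic for a fixed seed; Monte-Carlo SE is reported.
    """
    if nsim < 100:
        raise ValueError("nsim must be >= 100")
    rng = np.random.default_rng(seed)
    if analysis == "t_two_arm":
        rejects = _pooled_t_power(sesoi, design["arm_ns"], design["arm_sds"], alpha, nsim, rng)
    elif analysis == "logistic_two_arm":
        p0 = design.get("baseline_prevalence", BASELINE_ASYMPTOTE_PREVALENCE)
        rejects = _logistic_two_arm_power(sesoi, design["arm_ns"], p0, alpha, nsim, rng)
    elif analysis == "anova_factorial":
        rejects = _factorial_anova_power(sesoi, design["cell_ns"], design["cell_sds"],
                                         design["effect_on"], design["test_effect"],
                                         alpha, nsim, rng)
    elif analysis == "logistic_factorial":
        p0 = design.get("baseline_prevalence", BASELINE_ASYMPTOTE_PREVALENCE)
        rejects = _factorial_logistic_power(sesoi, design["cell_ns"], p0,
                                            design["effect_on"], design["test_effect"],
                                            alpha, nsim, rng)
    else:
        raise ValueError(f"unknown analysis kind {analysis!r}")
    power = float(np.mean(rejects))
    mc_se = math.sqrt(max(power * (1 - power), 1e-12) / nsim)
    return PowerEstimate(label or analysis, power, mc_se, nsim, alpha, dict(design), seed)
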