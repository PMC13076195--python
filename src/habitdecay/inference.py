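"""Group-level inference on the per-person outcome table.

Implements the trial's preregistered analysis plan: ANCOVA on final habit
strength (covariate: initial SRBAI), ANOVA on aggregated weekly rates of
change, logistic regression on the reached-95%-asymptote dummy, ANCOVA on
log days-to-95%, with generalized eta squared effect sizes, covariate-
adjusted marginal means (back-transformed where the outcome is modelled on
a log or logit scale, delta-method SEs), step-down Holm multiplicity
adjustment, and logistic missingness checks.

Type III sums of squares under sum-to-zero contrasts are used for the
unbalanced factorial; marginal means weight factor levels equally with the
covariate at its grand mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.special import expit

__all__ = [
    "EffectTest",
    "AnalysisResult",
    "build_outcome_table",
    "ancova",
    "anova_rate",
    "logistic_asymptote",
    "ancova_log_days",
    "holm_adjust",
    "missingness_check",
    "adjusted_difference",
]


@dataclass
class EffectTest:
    name: str
    stat_name: str          # "F" | "chi2" | "z"
    statistic: float
    df: tuple
    p: float
    ges: float | None = None
    p_adjusted: float | None = None
    estimable: bool = True


@dataclass
class AnalysisResult:
    kind: str
    outcome: str
    effects: list[EffectTest]
    adjusted_means: pd.DataFrame
    nobs: int
    df_resid: float
    factors: list[str] = field(default_factory=list)
    covariate: str | None = None
    model: object = None

    def effect(self, name: str) -> EffectTest:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def _split_arm(arm: str) -> tuple[str, str]:
    if arm == "control":
        return "control", "n/a"
    if arm.endswith("+reward"):
        return arm[: -len("+reward")], "yes"
    return arm, "no"


def build_outcome_table(series_list, endpoints, asym_outcomes, rates, covariates=None) -> pd.DataFrame:
    """One row per participant: factors, the four outcomes, covariates.

    ``endpoints``, ``asym_outcomes`` and ``rates`` are mappings keyed by
    participant id (values may be missing for participants whose stage
    criteria failed; the corresponding outcomes stay missing -- no
    imputation). Non-valid asymptotic models still score ``reached95 = 0``.
    """
    rows = []
    seen = set()
    for s in series_list:
        pid = s.participant_id
        if pid in seen:
            raise ValueError(f"duplicate participant id {pid}")
        seen.add(pid)
        strategy, reward = _split_arm(s.arm)
        ep = endpoints.get(pid)
        ao = asym_outcomes.get(pid)
        wr = rates.get(pid)
        rows.append(
            {
                "participant_id": pid,
                "arm": s.arm,
                "group": "control" if s.arm == "control" else "intervention",
                "strategy": strategy,
                "reward": reward,
                "initial_srbai": ep.initial if ep is not None else math.nan,
                "final_srbai": ep.final if ep is not None else math.nan,
                "reached95": ao.reached95 if ao is not None else 0,
                "t95_days": ao.t95_days if ao is not None else math.nan,
                "week1_rate": wr.week1_rate if wr is not None else math.nan,
                "week2_rate": wr.week2_rate if wr is not None else math.nan,
            }
        )
    table = pd.DataFrame(rows)
    if covariates is not None:
        keep = [c for c in ("participant_id", "intention", "bmi", "desirable_responding", "age", "gender")
                if c in covariates.columns]
        table = table.merge(covariates[keep], on="participant_id", how="left")
    return table


def _terms(factors, covariate):
    terms = [f"C({f}, Sum)" for f in factors]
    if len(factors) == 2:
        terms.append(f"C({factors[0]}, Sum):C({factors[1]}, Sum)")
    if covariate:
        terms.append(covariate)
    return terms


def _friendly(term: str) -> str:
    return term.replace("C(", "").replace(", Sum)", "").replace(")", "")


def _check_levels(df, factors):
    for f in factors:
        counts = df[f].value_counts()
        empty = [lv for lv in df[f].unique() if counts.get(lv, 0) == 0]
        if (counts < 1).any() or df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 non-empty levels; got {dict(counts)}")


def _adjusted_means_ols(res, df, factors, covariate, level=0.95):
    design_info = res.model.data.design_info
    combos = df[factors].drop_duplicates().sort_values(factors)
    grid = combos.copy()
    if covariate:
        grid[covariate] = df[covariate].mean()
    (X,) = patsy.build_design_matrices([design_info], grid)
    X = np.asarray(X)
    mu = X @ res.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, res.cov_params().to_numpy(), X))
    crit = stats.t.ppf(0.5 + level / 2, res.df_resid)
    out = combos.reset_index(drop=True)
    counts = df.groupby(factors, sort=False).size()
    out["n"] = [counts.get(tuple(r) if len(factors) > 1 else r[0], 0)
                for r in combos.itertuples(index=False)]
    out["mean"], out["se"] = mu, se
    out["ci_lo"], out["ci_hi"] = mu - crit * se, mu + crit * se
    return out


def ancova(df: pd.DataFrame, outcome: str, factors, covariate: str | None = None) -> AnalysisResult:
    """Linear-model ANCOVA/ANOVA with Type III SS under sum contrasts.

    Returns per-effect F tests with generalized eta squared
    (SS_effect / (SS_effect + SS_error)) and covariate-adjusted marginal
    means per factor-level combination.
    """
    factors = list(factors)
    cols = [outcome, *factors] + ([covariate] if covariate else [])
    data = df.dropna(subset=cols).copy()
    _check_levels(data, factors)
    formula = f"{outcome} ~ " + " + ".join(_terms(factors, covariate))
    res = smf.ols(formula, data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(res, typ=3)
    ss_err = float(table.loc["Residual", "sum_sq"])
    effects = []
    for term in table.index:
        if term in ("Intercept", "Residual"):
            continue
        ss = float(table.loc[term, "sum_sq"])
        effects.append(
            EffectTest(
                name=_friendly(term),
                stat_name="F",
                statistic=float(table.loc[term, "F"]),
                df=(float(table.loc[term, "df"]), float(res.df_resid)),
                p=float(table.loc[term, "PR(>F)"]),
                ges=ss / (ss + ss_err),
            )
        )
    means = _adjusted_means_ols(res, data, factors, covariate)
    return AnalysisResult("ancova" if covariate else "anova", outcome, effects, means,
                          int(res.nobs), float(res.df_resid), factors, covariate, res)


def anova_rate(df: pd.DataFrame, outcome: str, factors) -> AnalysisResult:
    """ANOVA on an aggregated rate of change (ANCOVA without covariate)."""
    return ancova(df, outcome, factors, covariate=None)


def ancova_log_days(df: pd.DataFrame, outcome: str = "t95_days", factors=("group",),
                    covariate: str | None = "initial_srbai") -> AnalysisResult:
    """ANCOVA on log days-to-95%, back-transformed to the day scale.

    Rows with non-positive days are excluded. Adjusted means are
    exponentiated; SE_back = exp(mean_log) * SE_log (delta method) and CIs
    are the exponentiated log-scale CIs (asymmetric).
    """
    data = df[df[outcome] > 0].copy()
    data["_log_days"] = np.log(data[outcome])
    res = ancova(data, "_log_days", factors, covariate)
    m = res.adjusted_means
    back = m.copy()
    back["mean_log"], back["se_log"] = m["mean"], m["se"]
    back["mean"] = np.exp(m["mean"])
    back["se"] = back["mean"] * m["se"]
    back["ci_lo"], back["ci_hi"] = np.exp(m["ci_lo"]), np.exp(m["ci_hi"])
    res.adjusted_means = back
    res.outcome = outcome
    res.kind = "ancova-log-days"
    return res


def _wald_or_lr_effects(data, outcome, factors, covariate):
    terms = _terms(factors, covariate)
    formula = f"{outcome} ~ " + " + ".join(terms)
    full = smf.glm(formula, data=data, family=sm.families.Binomial()).fit()
    if np.abs(full.params).max() > 15:  # complete/quasi separation
        return full, None
    effects = []
    for term in terms:
        name = _friendly(term)
        if covariate and term == covariate:
            continue
        # single-df terms: Wald z; otherwise LR chi-square dropping the term
        term_cols = [c for c in full.params.index
                     if c.split("[")[0] == term or c == term]
        if len(term_cols) == 1 and ":" not in term:
            z = float(full.params[term_cols[0]] / full.bse[term_cols[0]])
            effects.append(EffectTest(name, "z", z, (1,), float(2 * stats.norm.sf(abs(z)))))
        else:
            reduced_terms = [t2 for t2 in terms if t2 != term]
            red = smf.glm(f"{outcome} ~ " + " + ".join(reduced_terms) if reduced_terms else f"{outcome} ~ 1",
                          data=data, family=sm.families.Binomial()).fit()
            lr = float(2 * (full.llf - red.llf))
            ddf = int(round(red.df_resid - full.df_resid))
            effects.append(EffectTest(name, "chi2", lr, (ddf,), float(stats.chi2.sf(lr, ddf))))
    return full, effects


def logistic_asymptote(df: pd.DataFrame, outcome: str = "reached95", factors=("group",),
                       covariate: str | None = "initial_srbai") -> AnalysisResult:
    """Logistic regression for the reached-95%-asymptote dummy.

    Two-level effects report Wald z; multi-level effects and the
    interaction report likelihood-ratio chi-square (dropping the term under
    sum contrasts). Adjusted means are inverse-logit predicted
    probabilities at the covariate grand mean; SEs use the delta method
    (p(1-p) * SE of the linear predictor) and CIs are back-transformed from
    the logit scale.
    """
    factors = list(factors)
    cols = [outcome, *factors] + ([covariate] if covariate else [])
    data = df.dropna(subset=cols).copy()
    _check_levels(data, factors)
    full, effects = _wald_or_lr_effects(data, outcome, factors, covariate)
    if effects is None:
        eff = [EffectTest(f, "z", math.nan, (1,), math.nan, estimable=False) for f in factors]
        return AnalysisResult("logistic", outcome, eff, pd.DataFrame(), int(full.nobs),
                              float(full.df_resid), factors, covariate, full)

    design_info = full.model.data.design_info
    combos = data[factors].drop_duplicates().sort_values(factors)
    grid = combos.copy()
    if covariate:
        grid[covariate] = data[covariate].mean()
    (X,) = patsy.build_design_matrices([design_info], grid)
    X = np.asarray(X)
    eta = X @ full.params.to_numpy()
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, full.cov_params().to_numpy(), X))
    p = expit(eta)
    crit = stats.norm.ppf(0.975)
    means = combos.reset_index(drop=True)
    counts = data.groupby(factors, sort=False).size()
    means["n"] = [counts.get(tuple(r) if len(factors) > 1 else r[0], 0)
                  for r in combos.itertuples(index=False)]
    means["mean"] = p
    means["se"] = p * (1 - p) * se_eta
    means["ci_lo"] = expit(eta - crit * se_eta)
    means["ci_hi"] = expit(eta + crit * se_eta)
    return AnalysisResult("logistic", outcome, effects, means, int(full.nobs),
                          float(full.df_resid), factors, covariate, full)


def adjusted_difference(result: AnalysisResult, factor: str, level_a, level_b):
    """Adjusted-mean contrast level_a - level_b on the model's link scale.

    Averages the design over the other factor's levels with equal weights,
    covariate at its grand mean. Returns ``(estimate, se, df_resid)``.
    """
    res = result.model
    data = res.model.data.frame
    design_info = res.model.data.design_info
    others = [f for f in result.factors if f != factor]

    def row(level):
        if others:
            grid = data[others].drop_duplicates().copy()
        else:
            grid = pd.DataFrame(index=[0])
        grid[factor] = level
        if result.covariate:
            grid[result.covariate] = data[result.covariate].mean()
        (X,) = patsy.build_design_matrices([design_info], grid)
        return np.asarray(X).mean(axis=0)

    d = row(level_a) - row(level_b)
    est = float(d @ res.params.to_numpy())
    se = float(np.sqrt(d @ res.cov_params().to_numpy() @ d))
    return est, se, float(res.df_resid)


def holm_adjust(p_values, family_size: int | None = None):
    """Step-down Holm (sequentially rejective Bonferroni) adjusted p values.

    ``family_size`` may exceed the number of observed p values; unobserved
    family members count toward the multiplier (they are treated as 1 and
    can never be overtaken). Adjusted values are monotone in the sorted
    order and capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size must be >= number of p values")
    order = np.argsort(p, kind="stable")
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min((m - rank) * p[idx], 1.0))
        adj[idx] = running
    return adj


def missingness_check(df: pd.DataFrame, indicator: str, terms) -> AnalysisResult:
    """Logistic regression of an outcome-missingness indicator on predictors.

    ``terms`` are model formula terms (e.g. ``["C(group)", "intention"]``).
    A constant indicator is degenerate and reported as such.
    """
    data = df.dropna(subset=[indicator]).copy()
    vals = data[indicator].unique()
    if len(vals) < 2:
        eff = [EffectTest(t, "z", math.nan, (1,), math.nan, estimable=False) for t in terms]
        return AnalysisResult("missingness", indicator, eff, pd.DataFrame(), len(data), math.nan)
    formula = f"{indicator} ~ " + " + ".join(terms)
    res = smf.glm(formula, data=data, family=sm.families.Binomial()).fit()
    effects = []
    for name in res.params.index:
        if name == "Intercept":
            continue
        z = float(res.params[name] / res.bse[name])
        effects.append(EffectTest(name, "z", z, (1,), float(2 * stats.norm.sf(abs(z)))))
    return AnalysisResult("missingness", indicator, effects, pd.DataFrame(),
                          int(res.nobs), float(res.df_resid), model=res)
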