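"""File-based pipeline: simulate -> preprocess -> trajectories -> outcomes
-> inference -> equivalence -> power.

Every stage reads and writes plain CSV/JSON artifacts so that any single
stage can be re-run bit-for-bit from its persisted inputs. A run manifest
records the configuration hash, master seed and library versions.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymptotic, equivalence, gam, inference, preprocess, simulate
from .config import CohortConfig, default_config

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "validate_inputs",
    "stage_simulate",
    "stage_preprocess",
    "stage_asymptotic",
    "stage_gam",
    "stage_outcomes",
    "stage_infer",
    "stage_equivalence",
    "stage_power",
]

_DEFAULT_FAMILY_SIZES = {"magnitude": 3, "asymptote": 3, "rate": 6, "days": 3}
_STRATEGY_REF = "reduced-accessibility"
_REWARD_REF = "no"


@dataclass
class PipelineConfig:
    outdir: str = "habitdecay_run"
    cohort: CohortConfig = field(default_factory=default_config)
    alpha: float = 0.05
    nsim: int = 1000                      # power-simulation replicates
    derivative_grid: str = "integer"
    family_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_FAMILY_SIZES))
    seed: int = 0                         # master seed; propagates to all stages

    def __post_init__(self):
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "cohort"}
        d["cohort"] = self.cohort.to_dict()
        return d


def _sanitize(obj):
    """Make an object JSON-clean: numpy scalars to native, NaN to null."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_sanitize(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _nan_to_none(x):
    return None if (isinstance(x, float) and math.isnan(x)) else x


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: CohortConfig, outdir) -> dict:
    records, truths = simulate.generate_cohort(cfg)
    paths = simulate.write_cohort(records, truths, outdir)
    _write_json(cfg.to_dict(), Path(outdir) / "cohort_config.json")
    return {k: str(v) for k, v in paths.items()}


def stage_preprocess(diary_csv, covariates_csv, outdir) -> dict:
    outdir = Path(outdir)
    records = pd.read_csv(diary_csv, parse_dates=["timestamp"])
    cov = preprocess.prepare_covariates(pd.read_csv(covariates_csv))
    series_list = preprocess.build_all_series(records, cov)

    rows, excl, ep_rows = [], [], []
    for s in series_list:
        for t, y in zip(s.t, s.srbai):
            rows.append({"participant_id": s.participant_id, "arm": s.arm, "t": int(t), "srbai": y})
        for ts, reason in s.exclusions:
            excl.append({"participant_id": s.participant_id, "timestamp": ts, "reason": reason})
        if not s.is_empty:
            ep = preprocess.extract_magnitude_endpoints(s)
            ep_rows.append({"participant_id": s.participant_id,
                            "initial_srbai": ep.initial, "final_srbai": ep.final,
                            "final_source": ep.final_source})
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["participant_id", "arm", "t", "srbai"]).to_csv(
        outdir / "series.csv", index=False)
    pd.DataFrame(excl, columns=["participant_id", "timestamp", "reason"]).to_csv(
        outdir / "exclusions.csv", index=False)
    pd.DataFrame(ep_rows, columns=["participant_id", "initial_srbai", "final_srbai",
                                   "final_source"]).to_csv(outdir / "endpoints.csv", index=False)
    cov.to_csv(outdir / "covariates_clean.csv", index=False)
    return {"series": str(outdir / "series.csv"),
            "endpoints": str(outdir / "endpoints.csv"),
            "exclusions": str(outdir / "exclusions.csv"),
            "covariates": str(outdir / "covariates_clean.csv")}


def _series_from_csv(series_csv) -> list[preprocess.PersonSeries]:
    df = pd.read_csv(series_csv)
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("t")
        s = preprocess.PersonSeries(
            participant_id=pid, arm=grp["arm"].iloc[0],
            t=grp["t"].to_numpy(int), srbai=grp["srbai"].to_numpy(float))
        if (s.t == 0).any():
            s.initial_srbai = float(s.srbai[s.t == 0][0])
        out.append(s)
    return out


def stage_asymptotic(series_csv, outdir) -> dict:
    rows = []
    for s in _series_from_csv(series_csv):
        fit = asymptotic.fit_asymptotic(s)
        valid, reasons = asymptotic.assess_validity(fit)
        out = asymptotic.asymptote_outcome(fit, s)
        rows.append({
            "participant_id": s.participant_id, "r0": fit.r0, "asym": fit.asym,
            "lrc": fit.lrc, "rmse": fit.rmse, "n_obs": fit.n_obs,
            "max_gap_days": fit.max_gap_days, "converged": fit.converged,
            "valid": valid, "reasons": ";".join(reasons),
            "reached95": out.reached95, "t95_days": out.t95_days,
        })
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "asymptotic_fits.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return {"asymptotic": str(path)}


def stage_gam(series_csv, outdir, grid: str = "integer") -> dict:
    rows = []
    for s in _series_from_csv(series_csv):
        fit = gam.fit_gam(s)
        wr = gam.weekly_rate(fit, grid=grid) if fit.sufficient_data else gam.WeeklyRate(math.nan, math.nan)
        rows.append({
            "participant_id": s.participant_id, "knots": fit.knots,
            "sufficient": fit.sufficient_data, "edf": fit.edf,
            "week1_rate": wr.week1_rate, "week2_rate": wr.week2_rate,
        })
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "weekly_rates.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return {"rates": str(path)}


def stage_outcomes(series_csv, covariates_csv, asymptotic_csv, rates_csv, outdir) -> dict:
    series_list = _series_from_csv(series_csv)
    cov = pd.read_csv(covariates_csv)
    asy = pd.read_csv(asymptotic_csv).set_index("participant_id")
    rates = pd.read_csv(rates_csv).set_index("participant_id")

    endpoints, asym_out, weekly = {}, {}, {}
    for s in series_list:
        if not s.is_empty:
            endpoints[s.participant_id] = preprocess.extract_magnitude_endpoints(s)
        if s.participant_id in asy.index:
            r = asy.loc[s.participant_id]
            asym_out[s.participant_id] = asymptotic.AsymptoteOutcome(
                bool(r["valid"]), int(r["reached95"]),
                float(r["t95_days"]) if pd.notna(r["t95_days"]) else math.nan)
        if s.participant_id in rates.index:
            r = rates.loc[s.participant_id]
            weekly[s.participant_id] = gam.WeeklyRate(
                float(r["week1_rate"]) if pd.notna(r["week1_rate"]) else math.nan,
                float(r["week2_rate"]) if pd.notna(r["week2_rate"]) else math.nan)
    table = inference.build_outcome_table(series_list, endpoints, asym_out, weekly, cov)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "outcomes.csv"
    table.to_csv(path, index=False)
    return {"outcomes": str(path)}


def _effects_to_json(res: inference.AnalysisResult) -> dict:
    return {
        "kind": res.kind,
        "nobs": res.nobs,
        "effects": [
            {"name": e.name, "stat": e.stat_name, "statistic": _nan_to_none(e.statistic),
             "df": list(e.df), "p_raw": _nan_to_none(e.p),
             "p_adjusted": _nan_to_none(e.p_adjusted) if e.p_adjusted is not None else None,
             "ges": _nan_to_none(e.ges) if e.ges is not None else None,
             "estimable": e.estimable}
            for e in res.effects
        ],
        "adjusted_means": res.adjusted_means.to_dict("records"),
    }


def _fit_main_analyses(table: pd.DataFrame, alpha: float) -> dict:
    """All preregistered group analyses on the outcome table."""
    intv = table[table["group"] == "intervention"]
    analyses = {
        "H1.1": inference.ancova(table, "final_srbai", ["group"], "initial_srbai"),
        "H1.2-3": inference.ancova(intv, "final_srbai", ["strategy", "reward"], "initial_srbai"),
        "H1.4": inference.logistic_asymptote(table, "reached95", ["group"], "initial_srbai"),
        "H1.5-6": inference.logistic_asymptote(intv, "reached95", ["strategy", "reward"], "initial_srbai"),
        "H2.1-w1": inference.anova_rate(table, "week1_rate", ["group"]),
        "H2.1-w2": inference.anova_rate(table, "week2_rate", ["group"]),
        "H2.2-3-w1": inference.anova_rate(intv, "week1_rate", ["strategy", "reward"]),
        "H2.2-3-w2": inference.anova_rate(intv, "week2_rate", ["strategy", "reward"]),
        "H2.4": inference.ancova_log_days(table, "t95_days", ["group"], "initial_srbai"),
        "H2.5-6": inference.ancova_log_days(intv, "t95_days", ["strategy", "reward"], "initial_srbai"),
    }
    return analyses


_FAMILIES = {
    "magnitude": [("H1.1", "group"), ("H1.2-3", "strategy"), ("H1.2-3", "reward")],
    "asymptote": [("H1.4", "group"), ("H1.5-6", "strategy"), ("H1.5-6", "reward")],
    "rate": [("H2.1-w1", "group"), ("H2.2-3-w1", "strategy"), ("H2.2-3-w1", "reward"),
             ("H2.1-w2", "group"), ("H2.2-3-w2", "strategy"), ("H2.2-3-w2", "reward")],
    "days": [("H2.4", "group"), ("H2.5-6", "strategy"), ("H2.5-6", "reward")],
}


def _apply_holm(analyses: dict, family_sizes: dict) -> None:
    for family, members in _FAMILIES.items():
        effs = [analyses[key].effect(name) for key, name in members]
        ps = [e.p for e in effs if e.estimable and not math.isnan(e.p)]
        if not ps:
            continue
        adj = inference.holm_adjust(ps, max(family_sizes.get(family, len(ps)), len(ps)))
        it = iter(adj)
        for e in effs:
            if e.estimable and not math.isnan(e.p):
                e.p_adjusted = float(next(it))


def stage_infer(outcomes_csv, outdir, alpha: float = 0.05,
                family_sizes: dict | None = None) -> dict:
    table = pd.read_csv(outcomes_csv)
    analyses = _fit_main_analyses(table, alpha)
    _apply_holm(analyses, family_sizes or _DEFAULT_FAMILY_SIZES)
    results = {key: _effects_to_json(res) for key, res in analyses.items()}

    # missingness checks: outcome-missing indicators vs group and covariates
    for out_col, label in [("final_srbai", "magnitude"), ("week1_rate", "rate"),
                           ("t95_days", "days")]:
        ind = table[out_col].isna().astype(int)
        sub = table.copy()
        sub["_missing"] = ind
        chk = inference.missingness_check(sub, "_missing", ["C(group)", "intention"])
        results[f"missingness-{label}"] = _effects_to_json(chk)

    outdir = Path(outdir)
    path = outdir / "results.json"
    _write_json(results, path)
    return {"results": str(path)}


def _equivalence_tests(table: pd.DataFrame) -> dict:
    """Table-6-style TOST battery for the group and factor contrasts."""
    analyses = _fit_main_analyses(table, alpha=0.05)
    registry = {s.outcome: s for s in equivalence.sesoi_registry()}
    out = {}

    def add(label, res_key, factor, level_a, level_b, spec, rope=None):
        res = analyses[res_key]
        try:
            est, se, df = inference.adjusted_difference(res, factor, level_a, level_b)
        except Exception as err:
            out[label] = {"error": str(err)}
            return
        if rope is None:
            rope = equivalence.rope_bounds(spec)
        tr = equivalence.tost(est, se, df, rope)
        out[label] = {"estimate": tr.estimate, "se": se, "df": df,
                      "ci90": list(tr.ci90), "rope": list(rope),
                      "p_tost": tr.p_tost, "decision": tr.decision}

    mag, asy = registry["magnitude"], registry["asymptote_likelihood"]
    rate, days = registry["rate"], registry["days_to_95"]

    add("H1.1", "H1.1", "group", "intervention", "control", mag)
    add("H1.2-inhibition", "H1.2-3", "strategy", "inhibition", _STRATEGY_REF, mag)
    add("H1.2-substitution", "H1.2-3", "strategy", "substitution", _STRATEGY_REF, mag)
    add("H1.3", "H1.2-3", "reward", "yes", _REWARD_REF, mag)

    add("H1.4", "H1.4", "group", "intervention", "control", asy)
    add("H1.5-inhibition", "H1.5-6", "strategy", "inhibition", _STRATEGY_REF, asy)
    add("H1.5-substitution", "H1.5-6", "strategy", "substitution", _STRATEGY_REF, asy)
    add("H1.6", "H1.5-6", "reward", "yes", _REWARD_REF, asy)

    for wk in ("w1", "w2"):
        add(f"H2.1-{wk}", f"H2.1-{wk}", "group", "intervention", "control", rate)
        add(f"H2.2-{wk}-inhibition", f"H2.2-3-{wk}", "strategy", "inhibition", _STRATEGY_REF, rate)
        add(f"H2.2-{wk}-substitution", f"H2.2-3-{wk}", "strategy", "substitution", _STRATEGY_REF, rate)
        add(f"H2.3-{wk}", f"H2.2-3-{wk}", "reward", "yes", _REWARD_REF, rate)

    # days ROPE anchored at the reference level's back-transformed mean
    def days_rope(res_key, factor, ref_level):
        means = analyses[res_key].adjusted_means
        m = float(means.loc[means[factor] == ref_level, "mean"].mean())
        return equivalence.rope_bounds(days, reference_mean=m)

    try:
        add("H2.4", "H2.4", "group", "intervention", "control", days,
            rope=days_rope("H2.4", "group", "control"))
        add("H2.5-inhibition", "H2.5-6", "strategy", "inhibition", _STRATEGY_REF, days,
            rope=days_rope("H2.5-6", "strategy", _STRATEGY_REF))
        add("H2.5-substitution", "H2.5-6", "strategy", "substitution", _STRATEGY_REF, days,
            rope=days_rope("H2.5-6", "strategy", _STRATEGY_REF))
        add("H2.6", "H2.5-6", "reward", "yes", _REWARD_REF, days,
            rope=days_rope("H2.5-6", "reward", _REWARD_REF))
    except ValueError as err:
        out["days-rope"] = {"error": str(err)}
    return out


def stage_equivalence(outcomes_csv, outdir) -> dict:
    table = pd.read_csv(outcomes_csv)
    results = _equivalence_tests(table)
    outdir = Path(outdir)
    path = outdir / "equivalence.json"
    _write_json(results, path)
    return {"equivalence": str(path)}


def _power_battery(table: pd.DataFrame, nsim: int, alpha: float, seed: int) -> dict:
    """Design-aware power for each outcome's SESOI, condition-specific n/SD."""
    registry = {s.outcome: s for s in equivalence.sesoi_registry()}
    intv = table[table["group"] == "intervention"]
    out = {}
    seeds = iter(np.random.SeedSequence(seed).generate_state(32) % (2**31))

    def two_arm(label, col, sesoi):
        sub = table.dropna(subset=[col])
        g = sub.groupby("group")[col]
        if g.ngroups < 2 or (g.size() < 3).any():
            return
        ns, sds = g.size(), g.std(ddof=1)
        pe = equivalence.power_detection(
            sesoi, {"arm_ns": (int(ns["control"]), int(ns["intervention"])),
                    "arm_sds": (float(sds["control"]), float(sds["intervention"]))},
            "t_two_arm", nsim=nsim, alpha=alpha, seed=int(next(seeds)), label=label)
        out[label] = {"power": pe.power, "mc_se": pe.mc_se, "nsim": pe.nsim,
                      "arm_ns": list(pe.design["arm_ns"]), "arm_sds": list(pe.design["arm_sds"])}

    def factorial(label, col, sesoi, effect_on, test_effect):
        sub = intv.dropna(subset=[col])
        cell_ns = {k: int(v) for k, v in sub.groupby(["strategy", "reward"]).size().items()}
        cell_sds = {k: float(v) for k, v in sub.groupby(["strategy", "reward"])[col].std(ddof=1).items()}
        if len(cell_ns) < 6 or min(cell_ns.values()) < 3:
            return
        pe = equivalence.power_detection(
            sesoi, {"cell_ns": cell_ns, "cell_sds": cell_sds,
                    "effect_on": effect_on, "test_effect": test_effect},
            "anova_factorial", nsim=nsim, alpha=alpha, seed=int(next(seeds)), label=label)
        out[label] = {"power": pe.power, "mc_se": pe.mc_se, "nsim": pe.nsim}

    mag_sesoi = registry["magnitude"].sesoi
    rate_sesoi = registry["rate"].sesoi
    log_or = math.log(registry["asymptote_likelihood"].sesoi[1])

    two_arm("H1.1", "final_srbai", mag_sesoi)
    factorial("H1.2", "final_srbai", mag_sesoi, ("strategy", "substitution"), "strategy")
    factorial("H1.3", "final_srbai", mag_sesoi, ("reward", "yes"), "reward")

    nc = int((table["group"] == "control").sum())
    ni = int((table["group"] == "intervention").sum())
    pe = equivalence.power_detection(log_or, {"arm_ns": (nc, ni)}, "logistic_two_arm",
                                     nsim=nsim, alpha=alpha, seed=int(next(seeds)), label="H1.4")
    out["H1.4"] = {"power": pe.power, "mc_se": pe.mc_se, "nsim": pe.nsim}
    cell_ns = {k: int(v) for k, v in intv.groupby(["strategy", "reward"]).size().items()}
    for label, effect_on, test in [("H1.5", ("strategy", "substitution"), "strategy"),
                                   ("H1.6", ("reward", "yes"), "reward")]:
        pe = equivalence.power_detection(
            log_or, {"cell_ns": cell_ns, "effect_on": effect_on, "test_effect": test},
            "logistic_factorial", nsim=min(nsim, 1000), alpha=alpha,
            seed=int(next(seeds)), label=label)
        out[label] = {"power": pe.power, "mc_se": pe.mc_se, "nsim": pe.nsim}

    for wk, col in (("w1", "week1_rate"), ("w2", "week2_rate")):
        two_arm(f"H2.1-{wk}", col, rate_sesoi)
        factorial(f"H2.2-{wk}", col, rate_sesoi, ("strategy", "substitution"), "strategy")
        factorial(f"H2.3-{wk}", col, rate_sesoi, ("reward", "yes"), "reward")

    # days outcome: +/-1 day on the log scale, anchored at the control mean
    sub = table[table["t95_days"] > 0].copy()
    if (sub["group"] == "control").sum() >= 3 and (sub["group"] == "intervention").sum() >= 3:
        logd = np.log(sub["t95_days"])
        m = float(np.exp(logd[sub["group"] == "control"].mean()))
        if m > 1:
            sesoi_log = math.log((m + 1) / m)
            g = sub.assign(_ld=logd).groupby("group")["_ld"]
            pe = equivalence.power_detection(
                sesoi_log,
                {"arm_ns": (int(g.size()["control"]), int(g.size()["intervention"])),
                 "arm_sds": (float(g.std(ddof=1)["control"]), float(g.std(ddof=1)["intervention"]))},
                "t_two_arm", nsim=nsim, alpha=alpha, seed=int(next(seeds)), label="H2.4")
            out["H2.4"] = {"power": pe.power, "mc_se": pe.mc_se, "nsim": pe.nsim}
    return out


def stage_power(outcomes_csv, outdir, nsim: int = 1000, alpha: float = 0.05,
                seed: int = 0) -> dict:
    table = pd.read_csv(outcomes_csv)
    results = _power_battery(table, nsim, alpha, seed)
    outdir = Path(outdir)
    path = outdir / "power.json"
    _write_json(results, path)
    return {"power": str(path)}


# ------------------------------------------------------------- pipeline

def validate_inputs(diary_csv) -> dict:
    """Schema/range/timestamp validation report for a raw diary CSV."""
    df = pd.read_csv(diary_csv, dtype=str)
    required = set(simulate.RECORD_COLUMNS)
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise ValueError(f"diary CSV missing columns: {missing_cols}")
    n_valid = n_out_of_range = n_unparseable = 0
    for _, row in df.iterrows():
        ok = True
        try:
            ts = pd.to_datetime(row["timestamp"])
            if ts.minute is None:
                ok = False
        except (ValueError, TypeError):
            n_unparseable += 1
            continue
        if not ("T" in str(row["timestamp"]) or ":" in str(row["timestamp"])):
            n_unparseable += 1
            continue
        for c in ("item1", "item2", "item3", "item4"):
            try:
                v = float(row[c])
            except (TypeError, ValueError):
                ok = False
                break
            if not (0 <= v <= 4):
                ok = False
                break
        if ok:
            n_valid += 1
        else:
            n_out_of_range += 1
    return {"n_rows": len(df), "n_valid": n_valid,
            "n_out_of_range": n_out_of_range, "n_unparseable": n_unparseable}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact-path mapping."""
    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    stage = "simulate"
    try:
        artifacts.update(stage_simulate(config.cohort, outdir))
        stage = "preprocess"
        artifacts.update(stage_preprocess(artifacts["diary"], artifacts["covariates"], outdir))
        stage = "asymptotic"
        artifacts.update(stage_asymptotic(artifacts["series"], outdir))
        stage = "gam"
        artifacts.update(stage_gam(artifacts["series"], outdir, config.derivative_grid))
        stage = "outcomes"
        artifacts.update(stage_outcomes(artifacts["series"], artifacts["covariates"],
                                        artifacts["asymptotic"], artifacts["rates"], outdir))
        stage = "infer"
        artifacts.update(stage_infer(artifacts["outcomes"], outdir, config.alpha,
                                     config.family_sizes))
        stage = "equivalence"
        artifacts.update(stage_equivalence(artifacts["outcomes"], outdir))
        stage = "power"
        artifacts.update(stage_power(artifacts["outcomes"], outdir, config.nsim,
                                     config.alpha, config.seed))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"habitdecay": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "artifacts": artifacts,
    }
    _write_json(manifest, outdir / "manifest.json")
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
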