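"""SRBAI diary preprocessing.

Maps raw timestamped item records to per-person daily composite series on
centered time t = day - 7 (0..84), extracts the magnitude-of-change
endpoints, prepares covariates, and estimates multilevel (generalizability)
reliability coefficients from a person x day x item variance decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time

import numpy as np
import pandas as pd

from .config import STUDY_START_DATE

__all__ = [
    "EXCLUDED",
    "PersonSeries",
    "MagnitudeEndpoints",
    "assign_study_day",
    "composite_srbai",
    "build_person_series",
    "build_all_series",
    "extract_magnitude_endpoints",
    "prepare_covariates",
    "reliability_coefficients",
]

#: Sentinel for responses in the midday exclusion band (10:30, 19:00).
EXCLUDED = "excluded"

_EVENING_START = time(19, 0)
_MORNING_CUTOFF = time(10, 30)


@dataclass
class PersonSeries:
    """One participant's cleaned daily composite series on t in [0, 84]."""

    participant_id: str
    arm: str
    t: np.ndarray                  # unique, sorted integer days
    srbai: np.ndarray              # composite scores in [0, 4]
    initial_srbai: float = math.nan  # composite at t = 0 when observed
    covariates: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.t)

    @property
    def is_empty(self) -> bool:
        return len(self.t) == 0


@dataclass
class MagnitudeEndpoints:
    initial: float
    final: float
    final_source: str  # "last-week-mean" | "locf"


def assign_study_day(timestamp, start_date: date = STUDY_START_DATE):
    """Map a response timestamp to its study day, or exclude it.

    Evening responses (19:00-23:59) refer to that calendar day; early-morning
    responses (00:00-10:30 inclusive) are recoded to the previous day; the
    midday band (10:30, 19:00) exclusive is excluded. Returns a 1-based study
    day integer or :data:`EXCLUDED`. Raises ValueError on unparseable input.
    """
    if isinstance(timestamp, str):
        try:
            timestamp = datetime.fromisoformat(timestamp)
        except ValueError as err:
            raise ValueError(f"unparseable timestamp {timestamp!r}") from err
    if isinstance(timestamp, pd.Timestamp):
        timestamp = timestamp.to_pydatetime()
    if not isinstance(timestamp, datetime):
        raise ValueError(f"unparseable timestamp {timestamp!r}")

    tod = timestamp.time()
    if tod >= _EVENING_START:
        day_date = timestamp.date()
    elif tod <= _MORNING_CUTOFF:
        day_date = timestamp.date() - pd.Timedelta(days=1)
    else:
        return EXCLUDED
    return (day_date - start_date).days + 1


def composite_srbai(item_scores) -> float:
    """Mean of the four SRBAI items; missing if any item is missing."""
    arr = np.asarray(item_scores, dtype=float)
    if arr.shape != (4,) or np.isnan(arr).any():
        return math.nan
    return float(arr.mean())


def build_person_series(
    records: pd.DataFrame,
    covariates: dict | None = None,
    *,
    srbai_start_day: int = 7,
    study_days: int = 91,
    start_date: date = STUDY_START_DATE,
) -> PersonSeries:
    """Clean one participant's raw records into a daily composite series.

    Applies the timestamp recoding/exclusion window, computes the item-mean
    composite, keeps study days ``srbai_start_day..study_days``, re-indexes
    to t = day - srbai_start_day, and resolves duplicate valid responses for
    one day by keeping the earliest timestamp.
    """
    if records.empty:
        raise ValueError("no records supplied")
    pids = records["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"records span multiple participants: {pids}")
    pid = pids[0]
    arm = records["arm"].iloc[0] if "arm" in records else ""

    exclusions: list[tuple[str, str]] = []
    rows = []
    for _, row in records.iterrows():
        try:
            day = assign_study_day(row["timestamp"], start_date)
        except ValueError:
            exclusions.append((str(row["timestamp"]), "unparseable"))
            continue
        if day == EXCLUDED:
            exclusions.append((str(row["timestamp"]), "midday-window"))
            continue
        if not (srbai_start_day <= day <= study_days):
            exclusions.append((str(row["timestamp"]), "outside-study-window"))
            continue
        score = composite_srbai([row["item1"], row["item2"], row["item3"], row["item4"]])
        if math.isnan(score):
            exclusions.append((str(row["timestamp"]), "missing-item"))
            continue
        rows.append((day, pd.Timestamp(row["timestamp"]), score))

    cov = dict(covariates or {})
    if not rows:
        return PersonSeries(pid, arm, np.array([], int), np.array([], float),
                            covariates=cov, exclusions=exclusions)

    df = pd.DataFrame(rows, columns=["day", "ts", "srbai"])
    df = df.sort_values(["day", "ts"]).drop_duplicates("day", keep="first")
    t = (df["day"].to_numpy() - srbai_start_day).astype(int)
    y = df["srbai"].to_numpy(float)
    initial = float(y[t == 0][0]) if (t == 0).any() else math.nan
    return PersonSeries(pid, arm, t, y, initial_srbai=initial,
                        covariates=cov, exclusions=exclusions)


def build_all_series(
    records: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    **kwargs,
) -> list[PersonSeries]:
    """Build one :class:`PersonSeries` per participant in a raw diary table."""
    cov_map: dict[str, dict] = {}
    if covariates is not None:
        cov_map = {
            r["participant_id"]: {k: v for k, v in r.items() if k != "participant_id"}
            for r in covariates.to_dict("records")
        }
    out = []
    for pid, grp in records.groupby("participant_id", sort=True):
        out.append(build_person_series(grp, cov_map.get(pid), **kwargs))
    return out


def extract_magnitude_endpoints(
    series: PersonSeries, last_week: tuple[int, int] = (78, 84)
) -> MagnitudeEndpoints:
    """Initial (t = 0) and final habit strength.

    Final is the mean over the last week (t in [78, 84]) when any such
    observation exists, otherwise the last observation carried forward.
    """
    if series.is_empty:
        raise ValueError(f"empty series for {series.participant_id}")
    mask = (series.t >= last_week[0]) & (series.t <= last_week[1])
    if mask.any():
        final = float(series.srbai[mask].mean())
        source = "last-week-mean"
    else:
        final = float(series.srbai[-1])
        source = "locf"
    return MagnitudeEndpoints(initial=series.initial_srbai, final=final, final_source=source)


def prepare_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Clean baseline covariates.

    BMI = weight / height^2 (kg/m^2); values above mean + 3 SD (SD on the
    pre-replacement sample) are winsorized to mean + 3 SD. Intention is the
    mean of its two items.
    """
    out = raw.copy()
    h = pd.to_numeric(out.get("height_cm"), errors="coerce") / 100.0
    w = pd.to_numeric(out.get("weight_kg"), errors="coerce")
    bmi = w / h**2
    bmi[(h <= 0) | (w <= 0)] = np.nan
    mean, sd = bmi.mean(), bmi.std(ddof=1)
    cap = mean + 3.0 * sd
    out["bmi"] = bmi.clip(upper=cap)
    out["intention"] = out[["intention_item1", "intention_item2"]].mean(axis=1)
    return out


def reliability_coefficients(long: pd.DataFrame):
    """Generalizability coefficients from a person x day x item decomposition.

    ``long`` must have columns ``participant_id``, ``t`` (or ``day``) and
    ``item`` (label) and ``score``. Variance components (person, item,
    day-within-person, residual) are estimated by the ANOVA method of
    moments using average per-stratum counts, then combined into

    * between-person reliability of person means over n days and k items:
      ``R_between = s2_p / (s2_p + s2_pd/n + s2_e/(n*k))``
    * within-person (day-level change) reliability:
      ``R_within = s2_pd / (s2_pd + s2_e/k)``

    Returns ``(R_between, R_within)``; ``(nan, nan)`` when the total
    variance is degenerate.
    """
    df = long.rename(columns={"day": "t"}).dropna(subset=["score"])
    persons = df["participant_id"].unique()
    items = df["item"].unique()
    if len(persons) < 2 or len(items) < 2 or df.groupby("participant_id")["t"].nunique().min() < 2:
        raise ValueError("need >= 2 persons, >= 2 items and >= 2 days per person")

    y = df["score"].to_numpy(float)
    if np.allclose(y, y[0]):
        return math.nan, math.nan

    grand = y.mean()
    k = len(items)
    pd_means = df.groupby(["participant_id", "t"])["score"].mean()
    p_means = df.groupby("participant_id")["score"].mean()
    i_means = df.groupby("item")["score"].mean()
    n_days = df.groupby("participant_id")["t"].nunique()
    n_bar = float(n_days.mean())
    n_persons = len(persons)

    # mean squares (balanced-design expectations, average counts)
    ms_p = n_bar * k * float(((p_means - grand) ** 2).sum()) / (n_persons - 1)
    ms_pd = (
        k
        * float(((pd_means - p_means.reindex(pd_means.index.get_level_values(0)).to_numpy()) ** 2).sum())
        / float((n_days - 1).sum())
    )
    ms_i = n_persons * n_bar * float(((i_means - grand) ** 2).sum()) / (k - 1)

    # residual: additive person-day + item fit
    fitted = (
        pd_means.reindex(pd.MultiIndex.from_frame(df[["participant_id", "t"]])).to_numpy()
        + i_means.reindex(df["item"]).to_numpy()
        - grand
    )
    resid = y - fitted
    df_e = len(y) - len(pd_means) - (k - 1)
    ms_e = float((resid**2).sum()) / max(df_e, 1)

    s2_e = max(ms_e, 0.0)
    s2_pd = max((ms_pd - s2_e) / k, 0.0)
    s2_p = max((ms_p - ms_pd) / (n_bar * k), 0.0)
    s2_i = max((ms_i - s2_e) / (n_persons * n_bar), 0.0)  # noqa: F841  (reported via components)

    denom_b = s2_p + s2_pd / n_bar + s2_e / (n_bar * k)
    denom_w = s2_pd + s2_e / k
    r_between = s2_p / denom_b if denom_b > 0 else math.nan
    r_within = s2_pd / denom_w if denom_w > 0 else math.nan
    return r_between, r_within
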