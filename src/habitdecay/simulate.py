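"""Synthetic diary-cohort generator.

Emits raw end-of-day SRBAI item records (with realistic response timestamps
and missingness) plus the ground-truth person-level parameters that the
trajectory-recovery tests need.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    ARM_LABELS,
    STUDY_START_DATE,
    CohortConfig,
    PersonTruth,
    latent_srbai,
)

__all__ = [
    "generate_cohort",
    "generate_person_series",
    "records_to_frame",
    "truths_to_frame",
    "write_cohort",
]

_GENDER_LEVELS = ("female", "male", "other")
_GENDER_P = (0.84, 0.15, 0.01)

RECORD_COLUMNS = ["participant_id", "arm", "timestamp", "item1", "item2", "item3", "item4"]


def _draw_truth(pid: str, arm: str, cfg: CohortConfig, rng: np.random.Generator) -> PersonTruth:
    # joint truncation: resample (r0, asym) until 0 <= asym <= r0 <= 4
    while True:
        r0 = rng.normal(cfg.initial_mean, cfg.initial_sd)
        asym = rng.normal(cfg.asym_mean, cfg.asym_sd)
        if 0.0 <= asym <= r0 <= 4.0:
            break
    lrc = rng.normal(
        cfg.log_rate_mean + cfg.arm_log_rate_shift.get(arm, 0.0), cfg.log_rate_sd
    )
    height = rng.normal(168.0, 8.0)
    bmi = rng.normal(26.0, 4.5)
    return PersonTruth(
        participant_id=pid,
        arm=arm,
        r0_true=r0,
        asym_true=asym,
        lrc_true=lrc,
        age=float(np.clip(round(rng.normal(32.0, 8.0)), 18, 75)),
        gender=str(rng.choice(_GENDER_LEVELS, p=_GENDER_P)),
        weight_kg=round(max(bmi, 14.0) * (height / 100.0) ** 2, 1),
        height_cm=round(height, 1),
        intention_item1=float(np.clip(round(rng.normal(3.27, 0.7)), 0, 4)),
        intention_item2=float(np.clip(round(rng.normal(3.27, 0.7)), 0, 4)),
        desirable_responding=round(float(np.clip(rng.normal(3.0, 0.8), 0.0, 6.0)), 2),
    )


def _timestamp_for(day: int, kind: int, rng: np.random.Generator) -> datetime:
    """Response timestamp for scheduled study day ``day`` (1-based).

    kind 0: same evening 19:00-23:59; kind 1: next morning 00:00-10:30
    (recoded back to ``day`` downstream); kind 2: midday 10:31-18:59 of the
    next day (falls in the exclusion band).
    """
    base = datetime.combine(STUDY_START_DATE, datetime.min.time()) + timedelta(days=day - 1)
    if kind == 0:
        minutes = int(rng.integers(19 * 60, 24 * 60))
        return base + timedelta(minutes=minutes)
    if kind == 1:
        minutes = int(rng.integers(0, 10 * 60 + 30 + 1))
        return base + timedelta(days=1, minutes=minutes)
    minutes = int(rng.integers(10 * 60 + 31, 19 * 60))
    return base + timedelta(days=1, minutes=minutes)


def generate_person_series(
    truth: PersonTruth, config: CohortConfig, seed
) -> pd.DataFrame:
    """Raw diary records for one participant.

    ``seed`` may be an int, :class:`numpy.random.SeedSequence` or Generator.
    With both noise sds equal to 0 and ``miss_intercept`` large (no
    missingness), the emitted items equal the latent curve exactly (no
    Likert rounding), which makes noiseless pipeline tests exact.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exact = config.item_noise_sd == 0.0 and config.obs_noise_sd == 0.0

    days = np.arange(config.srbai_start_day, config.study_days + 1)
    t = days - config.srbai_start_day
    latent = latent_srbai(t, truth.r0_true, truth.asym_true, truth.lrc_true)

    p_respond = expit(config.miss_intercept + config.miss_slope * t)
    respond = rng.random(len(days)) < p_respond
    # the first diary day doubles as the randomization-day initial habit
    # measurement, which every enrolled participant provides
    if len(respond):
        respond[0] = True
    kinds = rng.choice(3, size=len(days), p=config.timestamp_mix)
    day_noise = rng.normal(0.0, config.obs_noise_sd, len(days)) if not exact else 0.0
    item_noise = rng.normal(0.0, config.item_noise_sd, (len(days), 4))

    rows = []
    for j, day in enumerate(days):
        if not respond[j]:
            continue
        mu = latent[j] + (day_noise[j] if not exact else 0.0)
        if exact:
            items = np.full(4, mu)
        else:
            items = np.clip(np.round(mu + item_noise[j]), 0, 4).astype(int)
        rows.append(
            {
                "participant_id": truth.participant_id,
                "arm": truth.arm,
                "timestamp": _timestamp_for(int(day), int(kinds[j]), rng),
                "item1": items[0],
                "item2": items[1],
                "item3": items[2],
                "item4": items[3],
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def generate_cohort(config: CohortConfig | None = None):
    """Generate the full cohort.

    Returns ``(records, truths)``: a long DataFrame of raw diary records and
    a list of :class:`PersonTruth`. Deterministic for a fixed config seed.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    arm_order = [a for a in ARM_LABELS if a in cfg.n_per_arm] + [
        a for a in cfg.n_per_arm if a not in ARM_LABELS
    ]
    n_total = cfg.n_participants
    truth_rng = np.random.default_rng(root.spawn(1)[0])
    person_seeds = root.spawn(n_total)

    truths: list[PersonTruth] = []
    frames: list[pd.DataFrame] = []
    idx = 0
    for arm in arm_order:
        for _ in range(cfg.n_per_arm[arm]):
            pid = f"P{idx + 1:04d}"
            truth = _draw_truth(pid, arm, cfg, truth_rng)
            truths.append(truth)
            frames.append(generate_person_series(truth, cfg, np.random.default_rng(person_seeds[idx])))
            idx += 1
    frames = [f for f in frames if not f.empty]
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=RECORD_COLUMNS)
    return records, truths


def truths_to_frame(truths: list[PersonTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(tr) for tr in truths])


def records_to_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Records with ISO-8601 minute-resolution timestamps, ready for CSV."""
    out = records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    return out


def write_cohort(records: pd.DataFrame, truths: list[PersonTruth], outdir) -> dict[str, Path]:
    """Write diary, covariates and ground-truth CSVs; return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "diary": outdir / "diary.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "ground_truth.csv",
    }
    records_to_frame(records).to_csv(paths["diary"], index=False)
    tf = truths_to_frame(truths)
    cov_cols = [
        "participant_id",
        "arm",
        "age",
        "gender",
        "weight_kg",
        "height_cm",
        "intention_item1",
        "intention_item2",
        "desirable_responding",
    ]
    tf[cov_cols].to_csv(paths["covariates"], index=False)
    tf.to_csv(paths["truth"], index=False)
    return paths
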