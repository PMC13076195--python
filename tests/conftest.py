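import math

import numpy as np
import pytest

from habitdecay.config import CohortConfig, PersonTruth, default_config


def make_truth(pid="P0001", arm="control", r0=2.6, asym=1.2, lrc=math.log(0.1)):
    return PersonTruth(
        participant_id=pid, arm=arm, r0_true=r0, asym_true=asym, lrc_true=lrc,
        age=30.0, gender="female", weight_kg=70.0, height_cm=170.0,
        intention_item1=3.0, intention_item2=4.0, desirable_responding=3.0,
    )


def noiseless_config(**overrides) -> CohortConfig:
    """Exact-evaluation config: no noise, no missingness, evening-only."""
    cfg = default_config()
    cfg.item_noise_sd = 0.0
    cfg.obs_noise_sd = 0.0
    cfg.miss_intercept = 50.0
    cfg.miss_slope = 0.0
    cfg.timestamp_mix = (1.0, 0.0, 0.0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def default_cohort():
    """One full 313-person cohort, shared across tests."""
    from habitdecay.simulate import generate_cohort

    cfg = default_config(seed=20240604)
    records, truths = generate_cohort(cfg)
    return cfg, records, truths


@pytest.fixture(scope="session")
def default_series(default_cohort):
    from habitdecay import preprocess, simulate

    cfg, records, truths = default_cohort
    cov = preprocess.prepare_covariates(simulate.truths_to_frame(truths))
    return cfg, preprocess.build_all_series(records, cov), truths


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
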