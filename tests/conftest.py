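import numpy as np
import pandas as pd
import pytest

from ema_rt.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale cohort (49 subjects x 28 days) under the default regime."""
    cfg = SimConfig(seed=20240901)
    records, scales, truth = generate_cohort(cfg)
    return cfg, records, scales, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast hierarchical-model structure tests."""
    cfg = SimConfig(n_subjects=12, n_days=10, seed=7, outlier_rate=0.0,
                    missing_rate=0.0)
    records, scales, truth = generate_cohort(cfg)
    labels = truth["subjects"][["subject_id", "is_responder"]]
    return cfg, records, labels, truth


def toy_records(rts, item="feeling", subject="s01", likert=None):
    """Long-format records from a list of RTs for one subject and item."""
    n = len(rts)
    return pd.DataFrame({
        "subject_id": subject,
        "item": item,
        "day_index": np.arange(n),
        "likert": likert if likert is not None else np.full(n, 4, dtype=int),
        "rt_seconds": np.asarray(rts, dtype=float),
    })
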