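import numpy as np
import pandas as pd
import pytest

from edanoise import (
    CarrierConfig,
    build_protocol,
    generate_feature_table,
    paper2024_config,
    synthesize_traces,
)


@pytest.fixture(scope="session")
def five_level_protocol():
    """The graded 70-90 dB protocol: 5 s stimuli, 60 s rests, 60 s baseline."""
    return build_protocol((70, 75, 80, 85, 90))


@pytest.fixture(scope="session")
def small_cohort(five_level_protocol):
    """Four subjects' features + truth from the calibrated preset, seed 3."""
    cfg = paper2024_config(seed=3, n_subjects=4)
    features, truth = generate_feature_table(cfg, five_level_protocol)
    return cfg, features, truth


@pytest.fixture(scope="session")
def rendered_subject(five_level_protocol, small_cohort):
    """One subject's truth rendered to 20 Hz component traces (no drift)."""
    cfg, _, truth = small_cohort
    rows = truth[truth.subject_id == 0]
    return synthesize_traces(five_level_protocol, rows, cfg), rows


@pytest.fixture(scope="session")
def noise_free_long_table():
    """Noise-free long table: y = 2 + 1.2 x for every subject and level."""
    rows = [
        {"subject_id": s, "level_db": lv, "scr_amp_uS": 2.0 + 1.2 * (lv - 70) / 5}
        for s in range(6)
        for lv in (70, 75, 80, 85, 90)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def carrier():
    return CarrierConfig()
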