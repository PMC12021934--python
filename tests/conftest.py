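import numpy as np
import pandas as pd
import pytest

from actiscan.synthetic_data import SimConfig, simulate_cohort, simulate_feature_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Minute-level cohort with default (noisy) study conditions."""
    return simulate_cohort(SimConfig(n_participants=30, seed=101))


@pytest.fixture(scope="session")
def clean_cohort():
    """Minute-level cohort with clean bouts: no fragmentation or non-wear."""
    cfg = SimConfig(n_participants=30, seed=102, fragmentation_prob=0.0, nonwear_prob=0.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def feature_cohort():
    return simulate_feature_cohort(SimConfig(n_participants=800, seed=103))


def minute_frame(records):
    """Build a minute table from (pid, iso_timestamp, mims, wear, flag) tuples."""
    df = pd.DataFrame(records, columns=["participant_id", "timestamp", "mims", "wear_class", "quality_flag"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def full_day(pid, date, mims=10.0, wear="wake_wear"):
    """One fully-observed midnight-to-midnight day of constant minutes."""
    ts = pd.date_range(date, periods=1440, freq="min")
    return pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp": ts,
            "mims": float(mims),
            "wear_class": wear,
            "quality_flag": False,
        }
    )
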