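import numpy as np
import pandas as pd
import pytest

from microdemog.data_model import CountTable, SampleMetadata
from microdemog.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort used across tests: fast but structurally faithful."""
    return SimConfig(n_samples=30, n_otus=80, depth_min=800, depth_max=2000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def tiny_table():
    df = pd.DataFrame(
        [[5, 3, 0, 1], [2, 0, 4, 4], [1, 1, 1, 7]],
        index=["S1", "S2", "S3"],
        columns=["O1", "O2", "O3", "O4"],
    )
    return CountTable(df)


@pytest.fixture()
def tiny_meta():
    df = pd.DataFrame(
        {
            "age": [34.0, 55.0, 41.0],
            "sex": ["F", "M", "F"],
            "race": ["white", "white", "non-white"],
            "bmi": [27.2, 31.0, 24.5],
            "alcohol": ["Y", "N", "Y"],
            "tobacco": ["N", "N", "Y"],
            "batch": ["batch1", "batch1", "batch2"],
        },
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
    )
    return SampleMetadata(df)


def two_group_metadata(n, rng, n_batches=2):
    """Random metadata for association tests: balanced binary X, two batches."""
    ids = [f"S{i:04d}" for i in range(n)]
    half = n // 2
    batch = ["batch1"] * half + ["batch2"] * (n - half)
    df = pd.DataFrame(
        {
            "age": rng.uniform(20, 80, n).round(1),
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["white", "non-white"], n, p=[0.85, 0.15]),
            "bmi": rng.uniform(18, 40, n).round(1),
            "alcohol": rng.choice(["Y", "N"], n),
            "tobacco": rng.choice(["Y", "N"], n, p=[0.15, 0.85]),
            "batch": batch[: n],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return SampleMetadata(df)
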