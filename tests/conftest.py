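"""Shared fixtures: small cohorts and shards for fast end-to-end tests."""

import numpy as np
import pandas as pd
import pytest

from fedcopd.cohort import CohortConfig, generate_cohort, train_test_split_shard
from fedcopd.federation import FLConfig
from fedcopd.network import NetworkArchitecture, TrainConfig, init_params


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (published structure, seed 0)."""
    return generate_cohort(CohortConfig())


@pytest.fixture()
def small_config():
    """A reduced cohort for fast pipeline tests (structure preserved)."""
    return CohortConfig(
        n_mild=30, n_severe=26, male_counts={0: 25, 1: 22}, seed=7
    )


@pytest.fixture()
def tiny_shards(small_config):
    """Three client shards of 18 records each, split 7:3."""
    from fedcopd.cohort import partition

    cohort = generate_cohort(small_config)
    parts = partition(cohort, k=3, samples_per_client=18, seed=3)
    return [
        train_test_split_shard(p, (7, 3), seed=10 + i, client_id=i)
        for i, p in enumerate(parts)
    ]


@pytest.fixture()
def tiny_fl_config():
    return FLConfig(
        n_clients=3,
        rounds=3,
        train=TrainConfig(eta=0.01, epochs=2, batch_size=4),
        hidden=(4,),
        seed=11,
    )


@pytest.fixture()
def tiny_params():
    return init_params(NetworkArchitecture(input_width=40, hidden=(4,)), seed=5)


def toy_cohort(values: dict[str, list], labels: list[int]) -> pd.DataFrame:
    """Hand-built cohort frame for filter tests."""
    n = len(labels)
    frame = pd.DataFrame(
        {
            "record_id": [f"T{i:03d}" for i in range(n)],
            "label": labels,
            "sex": ["male"] * n,
        }
    )
    for name, col in values.items():
        frame[name] = col
    return frame
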