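import numpy as np
import pandas as pd
import pytest

from spotboot.io import SpotVolumeTable, load_table1_fixture
from spotboot.rng import MinimalStandardRNG


@pytest.fixture
def rng():
    return MinimalStandardRNG(1)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


def make_long_table(volumes: dict, group_labels=("C", "D")) -> SpotVolumeTable:
    """Build a long-format table from {spot_id: {group: [volumes...]}}."""
    records = []
    for spot_id, groups in volumes.items():
        for group, vals in groups.items():
            for j, v in enumerate(vals):
                records.append((spot_id, "", group, f"r{j + 1}", float(v)))
    df = pd.DataFrame(
        records, columns=["spot_id", "protein", "group", "replicate", "volume"]
    )
    return SpotVolumeTable(data=df, group_labels=group_labels)


def lcg_oracle(seed: int, steps: int) -> int:
    """Big-integer reference for the minimal-standard recurrence."""
    s = seed
    for _ in range(steps):
        s = (16807 * s) % (2**31 - 1)
    return s


def lcg_oracle_uniforms(seed: int, k: int) -> np.ndarray:
    m = 2**31 - 1
    out = np.empty(k)
    s = seed
    for i in range(k):
        s = (16807 * s) % m
        out[i] = s / m
    return out
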