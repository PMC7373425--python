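import dataclasses

import numpy as np
import pandas as pd
import pytest

from acini3d import RunConfig, SyntheticConfig
from acini3d.cohort_cli import run_pipeline


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    """A small but fully featured synthetic run (6 acini)."""
    cfg = RunConfig(seed=11)
    cfg.synthetic = dataclasses.replace(cfg.synthetic, n_acini=6, seed=11)
    return cfg


@pytest.fixture(scope="session")
def small_report(small_config):
    return run_pipeline(small_config, write=False)


@pytest.fixture(scope="session")
def features_table(small_report) -> pd.DataFrame:
    return small_report.features


def make_cells(coords, transduced, acinus_id="a1", diameter=None) -> pd.DataFrame:
    """Build a canonical cell table from raw coordinates for hand-geometry tests."""
    coords = np.asarray(coords, dtype=float)
    df = pd.DataFrame(
        {
            "acinus_id": acinus_id,
            "cell_id": [f"c{i:03d}" for i in range(len(coords))],
            "timepoint": "start",
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "transduced": list(transduced),
        }
    )
    if diameter is not None:
        df["diameter"] = diameter
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
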