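"""Shared fixtures: small, fast synthetic datasets.

The full-scale study conditions (320 s at 5000 Hz) are exercised in the
acceptance tests; unit tests run on shorter recordings with the same
structure so the suite stays quick.
"""

import numpy as np
import pytest

from artonset import SimConfig, gen_dataset
from artonset.synthetic import SyntheticDataset


def small_gs_config(**overrides) -> SimConfig:
    """Short gradient-switch protocol: 20 volumes + 5 dummies at TR 500 ms."""
    base = dict(
        duration_s=16.0,
        tr_ms=500.0,
        n_volumes=20,
        n_dummy=5,
        n_channels=4,
        gs_start_s=1.0,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


def small_cb_config(**overrides) -> SimConfig:
    """One-minute cardiac-only recording (gradient train omitted, as after
    gradient-artefact correction)."""
    base = dict(duration_s=60.0, n_channels=4, include_gs=False, seed=3)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def gs_dataset() -> SyntheticDataset:
    return gen_dataset(small_gs_config())


@pytest.fixture(scope="session")
def cb_dataset() -> SyntheticDataset:
    return gen_dataset(small_cb_config())


@pytest.fixture(scope="session")
def background_only_dataset() -> SyntheticDataset:
    """10 s of plain background EEG: no artefacts of any kind."""
    return gen_dataset(
        SimConfig(
            duration_s=10.0,
            n_channels=4,
            include_gs=False,
            include_cb=False,
            include_ecg=False,
            seed=7,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
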