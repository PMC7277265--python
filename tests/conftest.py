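import numpy as np
import pandas as pd
import pytest

from semdepth import RoiSpec, SimulationConfig, generate_dataset


def make_events(onsets, words, categories, run_id="run00",
                condition="deep", is_catch=None, duration=1.0):
    n = len(onsets)
    return pd.DataFrame({
        "onset": onsets, "duration": [duration] * n, "word": words,
        "category": categories, "condition": [condition] * n,
        "run_id": [run_id] * n,
        "is_catch": is_catch if is_catch is not None else [False] * n,
    })


@pytest.fixture(scope="session")
def small_config():
    """A fast 2-run, 12-trial design used across the unit tests."""
    return SimulationConfig(
        n_runs=2, trials_per_run=12, n_words_per_category=6,
        volumes_per_run=200, max_catch_per_run=0,
        roi_specs=[RoiSpec("A", n_voxels=20)], seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
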