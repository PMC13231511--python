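import warnings

import numpy as np
import pytest

from fightdyn import CaptureDataset, FishRecord, JerkTrace, SimScenario, simulate_dataset
from fightdyn.errors import ConvergenceWarning

warnings.filterwarnings("ignore", category=ConvergenceWarning)
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 14 fish, seed 42."""
    dataset, truth = simulate_dataset(SimScenario(seed=42))
    return dataset, truth


@pytest.fixture
def small_trace():
    """Hand-built 9-sample trace with known channel values."""
    t = np.arange(9) * 2.0
    x = np.array([0.3, 0.5, 0.4, 0.9, 1.1, 0.7, 0.5, 0.4, 0.3])
    y = np.array([0.2, 0.6, 0.5, 1.0, 1.2, 0.8, 0.6, 0.5, 0.4])
    z = np.array([0.1, 0.4, 0.3, 0.8, 1.0, 0.6, 0.4, 0.3, 0.2])
    act = np.sqrt(x**2 + y**2 + z**2)
    return JerkTrace("f1", t, x, y, z, np.clip(act, 0, 2), cadence=2.0)


def make_dataset_from_actvsum(act_by_fish, cadence=2.0, records=None):
    """Dataset whose traces carry prescribed ActVSum (axes set to act/sqrt(3))."""
    ds = CaptureDataset()
    for fid, act in act_by_fish.items():
        act = np.asarray(act, dtype=float)
        ax = act / np.sqrt(3.0)
        ds.traces[fid] = JerkTrace(
            fid, np.arange(len(act)) * cadence, ax, ax, ax, act, cadence=cadence
        )
        if records is None:
            ds.records[fid] = FishRecord(
                fish_id=fid, species="chinook", fork_length=75.0, girth=38.0,
                water_temp=14.0, blood_ph=7.6, lactate=15.0,
            )
    if records is not None:
        ds.records = records
    return ds.validate()
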