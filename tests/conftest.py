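import dataclasses

import numpy as np
import pandas as pd
import pytest

import tntmvpa as t


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest non-degenerate experiment: fast enough for per-test reuse."""
    return t.ExperimentConfig(
        n_items_per_condition=4, n_voxels=10, iti_test=5.0, rating_duration=1.0,
        tnt_blocks=2, localizer_blocks_per_class=3, localizer_inter_block=6.0,
        n_nuisance=3, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_design(tiny_config):
    return t.generate_design(tiny_config)


def noiseless_truth(config, amplitude=1.0, item_amplitude=0.0, **kw):
    """Truth with flat category amplitudes and all noise terms off."""
    truth = t.default_truth(
        config, item_amplitude=item_amplitude, noise_sd=0.0, drift_amplitude=0.0, **kw
    )
    truth.category_amplitude = {k: amplitude for k in truth.category_amplitude}
    return truth


@pytest.fixture(scope="session")
def noiseless_subject(tiny_config, tiny_design):
    """Noiseless pretest series + events, shared across GLM tests."""
    truth = noiseless_truth(tiny_config)
    ev = tiny_design["pretest"]
    ts = t.simulate_timeseries(ev, truth, tiny_config, seed=1)
    return ts, ev, truth


def make_events(onsets, durations, phase="pretest", condition="recall"):
    onsets = np.atleast_1d(onsets).astype(float)
    durations = np.broadcast_to(np.atleast_1d(durations).astype(float), onsets.shape)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": durations,
            "phase": phase,
            "condition": condition,
            "item_id": [f"item{i:03d}" for i in range(len(onsets))],
            "block": 0,
            "run": 0,
        }
    )
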