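import numpy as np
import pandas as pd
import pytest

from pev import synthetic_data as sd


def null_ground_truth(n_neurons: int) -> pd.DataFrame:
    """Population with no planted signal at all."""
    return pd.DataFrame(
        {
            "neuron_id": np.arange(n_neurons),
            "class_label": "null",
            "amplitude": 0.0,
        }
    )


def planted_ground_truth(classes_amplitudes) -> pd.DataFrame:
    """Explicit per-neuron (class, amplitude) assignment."""
    classes, amps = zip(*classes_amplitudes)
    return pd.DataFrame(
        {
            "neuron_id": np.arange(len(classes)),
            "class_label": list(classes),
            "amplitude": list(amps),
        }
    )


@pytest.fixture
def interleaved_config():
    return sd.SessionConfig(
        "interleaved1",
        n_trials=40,
        pair_a=("A", (50,)),
        pair_b=("B", (30, 50, 70)),
        mismatch_sound="A",
    )


@pytest.fixture
def pairing_config():
    return sd.SessionConfig("pairing", n_trials=10)


@pytest.fixture
def single_trial_table(pairing_config):
    cfg = sd.SessionConfig("pairing", n_trials=1)
    return sd.build_trial_table(cfg, seed=0), cfg.frames()
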