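"""Shared fixtures: small synthetic datasets with known ground truth.

Session-scoped so expensive generation is amortised across tests; every
fixture is seeded, so the whole suite is deterministic.
"""

import numpy as np
import pytest

from histbias import BehaviourParams, NeuralParams, generate_neural_dataset


@pytest.fixture(scope="session")
def behav_params():
    return BehaviourParams()


@pytest.fixture(scope="session")
def tuned_sessions():
    """Sessions with S1/colour/previous-S2 tuning and an adaptive history shift."""
    sessions, truth = generate_neural_dataset(
        6,
        240,
        BehaviourParams(),
        NeuralParams(n_neurons=8),
        seed=101,
    )
    return sessions


@pytest.fixture(scope="session")
def nosignal_sessions():
    """Sessions with no tuning at all: homogeneous single-state Poisson."""
    sessions, _ = generate_neural_dataset(
        4,
        150,
        BehaviourParams(),
        NeuralParams(
            n_neurons=6,
            n_states_true=1,
            s1_gain=1.0,
            colour_gain=1.0,
            prev_s2_gain=1.0,
            history_shift_eta=0.0,
        ),
        seed=202,
    )
    return sessions
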