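"""Shared construction helpers for the test suite."""
import numpy as np
import pandas as pd

from locomod.datatypes import (
    DIRECTIONS,
    STATE_RUNNING,
    STATE_STATIONARY,
    SessionBundle,
    TrialMatrix,
)

STATES = (STATE_RUNNING, STATE_STATIONARY)


def make_trial_matrix(value_fn, n_per=6, n_neurons=4, noise_sd=0.0, seed=0):
    """Balanced TrialMatrix with responses = value_fn(direction, state, neuron)."""
    rng = np.random.default_rng(seed)
    rows, labels, states = [], [], []
    for d in DIRECTIONS:
        for s in STATES:
            for _ in range(n_per):
                row = np.array([value_fn(float(d), s, j) for j in range(n_neurons)], dtype=float)
                if noise_sd:
                    row = row + rng.normal(0.0, noise_sd, n_neurons)
                rows.append(row)
                labels.append(float(d))
                states.append(s)
    return TrialMatrix(
        responses=np.array(rows),
        class_label=np.array(labels),
        state=np.array(states),
        neuron_ids=np.arange(n_neurons),
    )


def tiny_bundle(speed, dff=None, stim_rows=None, n_neurons=2):
    """Minimal SessionBundle around a given speed trace."""
    speed = np.asarray(speed, dtype=float)
    n = speed.size
    if stim_rows is None:
        stim_rows = [("drifting_grating", 0, n, 0.0, 2.0)]
    stim = pd.DataFrame(
        stim_rows,
        columns=["epoch_type", "start_frame", "end_frame", "direction", "temporal_frequency"],
    )
    if dff is None:
        dff = np.zeros((n_neurons, n))
    return SessionBundle(dff=dff, speed=speed, pupil=np.ones(n), stim_table=stim)
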