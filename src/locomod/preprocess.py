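"""ΔF/F baselining, trial extraction, locomotor-state labels, balancing.

The ΔF/F baseline follows the rolling-window scheme used for large-scale
two-photon surveys: the baseline at each frame is a centered rolling mean
(default 3000 frames) of a centered rolling mode (default 5400 frames) of
the raw trace, with windows truncated at the edges.  Trials are labelled
``running`` when the window-mean speed exceeds 3 cm/s without ever
dropping below 0.5 cm/s, ``stationary`` when the mean is below 0.5 cm/s
and the maximum never exceeds 3 cm/s, and ``ambiguous`` otherwise
(ambiguous trials are excluded from all state-conditioned analyses).
"""
from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    STATE_AMBIGUOUS,
    STATE_RUNNING,
    STATE_STATIONARY,
    SessionBundle,
    TrialMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compute_dff",
    "classify_trial_state",
    "extract_trial_responses",
    "balance_trials",
    "MODE_KERNEL_FRAMES",
    "MEAN_KERNEL_FRAMES",
]

#: Default rolling-window widths (frames at 30 Hz: 3 min and 100 s).
MODE_KERNEL_FRAMES = 5400
MEAN_KERNEL_FRAMES = 3000


def _rolling_mode(x: np.ndarray, width: int, resolution: float) -> np.ndarray:
    """Centered rolling mode with edge truncation.

    The mode of a real-valued trace is taken after discretising to a fixed
    amplitude resolution; ties resolve to the smallest value.
    """
    bins = np.round(x / resolution).astype(np.int64)
    bins -= bins.min()
    half = width // 2
    n = x.size
    out = np.empty(n, dtype=np.int64)
    nbin = bins.max() + 1
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.bincount(bins[lo:hi], minlength=nbin).argmax()
    return (out + np.round(x / resolution).astype(np.int64).min()) * resolution


def _rolling_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Centered rolling mean with edge truncation (window clipped, not padded)."""
    half = width // 2
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_dff(
    raw: np.ndarray,
    mode_kernel_frames: int = MODE_KERNEL_FRAMES,
    mean_kernel_frames: int = MEAN_KERNEL_FRAMES,
    resolution_frac: float = 1e-3,
) -> np.ndarray:
    """ΔF/F of a raw fluorescence trace against a rolling mean-of-mode baseline.

    ``resolution_frac`` sets the amplitude resolution of the mode filter as
    a fraction of the trace median, which makes the result invariant to
    multiplicative rescaling of the raw trace.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw must be a 1-D trace")
    if raw.size <= mode_kernel_frames:
        raise ValueError("trace must be longer than the mode kernel")
    med = np.median(raw)
    if med <= 0:
        raise ValueError("non-positive median fluorescence")
    baseline = _rolling_mean(
        _rolling_mode(raw, mode_kernel_frames, resolution_frac * med), mean_kernel_frames
    )
    if np.any(baseline <= 0):
        raise ValueError("baseline is non-positive somewhere; degenerate fluorescence")
    return (raw - baseline) / baseline


def classify_trial_state(
    speed_window: np.ndarray,
    run_mean: float = 3.0,
    run_min: float = 0.5,
    stat_mean: float = 0.5,
    stat_max: float = 3.0,
) -> str:
    """Locomotor-state label for one trial window of speeds (cm/s)."""
    w = np.asarray(speed_window, dtype=float)
    if w.size == 0:
        raise ValueError("empty speed window")
    if np.any(w < 0):
        raise ValueError("negative speeds")
    m = w.mean()
    if m > run_mean and w.min() >= run_min:
        return STATE_RUNNING
    if m < stat_mean and w.max() <= stat_max:
        return STATE_STATIONARY
    return STATE_AMBIGUOUS


def extract_trial_responses(
    bundle: SessionBundle,
    window_s: float = 2.0,
    offset_frames: int = 10,
) -> TrialMatrix:
    """One response row per grating presentation.

    The response is the mean ΔF/F over a ``window_s`` window starting
    ``offset_frames`` after stimulus onset (the window may extend into the
    following blank); the state label comes from the speed trace over the
    same frames.  Trials whose window runs past the end of the recording
    are dropped with a warning.
    """
    win = int(round(window_s * bundle.frame_rate))
    rows, labels, states = [], [], []
    n_dropped = 0
    for _, ep in bundle.grating_epochs().iterrows():
        a = int(ep["start_frame"]) + offset_frames
        b = a + win
        if b > bundle.n_frames:
            n_dropped += 1
            continue
        rows.append(bundle.dff[:, a:b].mean(axis=1))
        labels.append(ep["direction"])
        states.append(classify_trial_state(bundle.speed[a:b]))
    if n_dropped:
        logger.warning("dropped %d trials whose window ran past the recording", n_dropped)
    return TrialMatrix(
        responses=np.array(rows),
        class_label=np.array(labels),
        state=np.array(states),
        neuron_ids=np.arange(bundle.n_neurons),
        window_s=window_s,
        offset_frames=offset_frames,
        source_session=bundle.session_id,
    )


def balance_trials(tm: TrialMatrix, seed: int = 0) -> TrialMatrix:
    """Equalise trial counts across every (class, state) cell.

    Ambiguous trials are removed, then each running/stationary cell is
    subsampled without replacement to the global minimum cell count.
    Raises if any cell is empty (the session should be excluded upstream).
    """
    rng = np.random.default_rng(seed)
    keep = tm.state != STATE_AMBIGUOUS
    tm = tm.select_trials(np.flatnonzero(keep))
    classes = np.unique(tm.class_label)
    cells = {}
    for d in classes:
        for s in (STATE_RUNNING, STATE_STATIONARY):
            idx = tm.cell_index(d, s)
            if idx.size == 0:
                raise ValueError(f"empty (class={d}, state={s}) cell; session not balanceable")
            cells[(d, s)] = idx
    n_star = min(idx.size for idx in cells.values())
    chosen = [
        np.sort(rng.choice(idx, size=n_star, replace=False)) for idx in cells.values()
    ]
    return tm.select_trials(np.sort(np.concatenate(chosen)))
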