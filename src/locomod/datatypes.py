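"""Core data containers shared across the pipeline.

The unit of analysis is a :class:`SessionBundle` -- one imaging session's
worth of ΔF/F traces, behavioral traces and a stimulus epoch table.  Trial
extraction turns a bundle into a :class:`TrialMatrix` (trials × neurons),
which is the common input to decoding and reliability analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "SessionBundle",
    "TrialMatrix",
    "TuningResult",
    "GaussianModelFit",
    "DecodingResult",
    "ReliabilityRecord",
    "RegionSummary",
    "DIRECTIONS",
    "STATE_RUNNING",
    "STATE_STATIONARY",
    "STATE_AMBIGUOUS",
]

#: The 8 drifting-grating motion directions (degrees).
DIRECTIONS = np.arange(0, 360, 45)

STATE_RUNNING = "running"
STATE_STATIONARY = "stationary"
STATE_AMBIGUOUS = "ambiguous"

NEURON_CLASSES = ("up", "down", "nonmono", "untuned")


@dataclass
class GroundTruth:
    """Planted per-neuron parameters of a synthetic session.

    ``neuron_class`` gives each neuron's running-speed tuning type
    (monotone up / monotone down / non-monotonic bump / untuned);
    ``speed_gain`` its signed modulation depth (ΔF/F per cm/s for monotone
    classes, bump amplitude for non-monotonic ones).  Direction tuning is
    von-Mises shaped with preferred direction ``pref_direction`` (deg),
    concentration ``dir_kappa`` and peak amplitude ``dir_amp``.  Trial-to-
    trial noise is Gaussian with a state-dependent standard deviation;
    ``shared_gain_sd`` is the spread of the latent multiplicative gain that
    induces noise correlations.
    """

    neuron_class: np.ndarray  # (n,) str
    speed_gain: np.ndarray  # (n,) float
    bump_center: np.ndarray  # (n,) cm/s, used by nonmono class
    bump_width: np.ndarray  # (n,) cm/s
    pref_direction: np.ndarray  # (n,) degrees in DIRECTIONS
    dir_kappa: np.ndarray  # (n,) >= 0
    dir_amp: np.ndarray  # (n,) >= 0, ΔF/F at preferred direction
    stim_offset: np.ndarray  # (n,) untuned evoked component, ΔF/F
    noise_sd_running: np.ndarray  # (n,) >= 0, per-trial ΔF/F noise
    noise_sd_stationary: np.ndarray  # (n,)
    shared_gain_sd: float
    seed: int

    def __post_init__(self) -> None:
        n = len(self.neuron_class)
        for name in (
            "speed_gain",
            "bump_center",
            "bump_width",
            "pref_direction",
            "dir_kappa",
            "dir_amp",
            "stim_offset",
            "noise_sd_running",
            "noise_sd_stationary",
        ):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"GroundTruth field {name} has length {len(arr)} != {n}")
        unknown = set(np.unique(self.neuron_class)) - set(NEURON_CLASSES)
        if unknown:
            raise ValueError(f"unknown neuron classes: {unknown}")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_class)


@dataclass
class SessionBundle:
    """All per-session arrays plus metadata.

    ``stim_table`` has columns ``epoch_type`` (``drifting_grating``,
    ``blank`` or ``spontaneous``), ``start_frame``, ``end_frame``
    (inclusive-exclusive), ``direction`` (deg, NaN outside gratings) and
    ``temporal_frequency`` (Hz, NaN outside gratings).
    """

    dff: np.ndarray  # (n_neurons, n_frames)
    speed: np.ndarray  # (n_frames,) cm/s
    pupil: np.ndarray  # (n_frames,) a.u., > 0
    stim_table: pd.DataFrame
    frame_rate: float = 30.0
    region: str = "VISp"
    layer: str = "2/3"
    session_id: str = "synthetic"
    raw: Optional[np.ndarray] = None  # raw fluorescence, if carried
    truth: Optional[GroundTruth] = None  # planted parameters, synthetic only

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        n_frames = self.dff.shape[1]
        if self.speed.shape != (n_frames,) or self.pupil.shape != (n_frames,):
            raise ValueError("speed/pupil length must match dff frames")
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")
        if np.any(self.pupil <= 0):
            raise ValueError("pupil must be positive")
        t = self.stim_table
        if len(t):
            if (t["end_frame"].to_numpy() <= t["start_frame"].to_numpy()).any():
                raise ValueError("empty or inverted stimulus epoch")
            starts = t["start_frame"].to_numpy()
            ends = t["end_frame"].to_numpy()
            if not (np.diff(starts) > 0).all() or (starts[1:] < ends[:-1]).any():
                raise ValueError("stimulus epochs must be sorted and non-overlapping")
            if starts[0] < 0 or ends[-1] > n_frames:
                raise ValueError("stimulus epochs outside recording")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    def grating_epochs(self) -> pd.DataFrame:
        return self.stim_table[self.stim_table["epoch_type"] == "drifting_grating"]


@dataclass
class TrialMatrix:
    """Trials × neurons response matrix with class and state labels."""

    responses: np.ndarray  # (n_trials, n_neurons) mean ΔF/F in window
    class_label: np.ndarray  # (n_trials,) direction in degrees
    state: np.ndarray  # (n_trials,) str
    neuron_ids: np.ndarray  # (n_neurons,) int, indices into source session
    window_s: float = 2.0
    offset_frames: int = 10
    source_session: str = "synthetic"

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.class_label = np.asarray(self.class_label)
        self.state = np.asarray(self.state)
        if np.isnan(self.responses).any():
            raise ValueError("TrialMatrix responses contain NaN")
        if len(self.class_label) != self.n_trials or len(self.state) != self.n_trials:
            raise ValueError("label length mismatch")
        if len(self.neuron_ids) != self.n_neurons:
            raise ValueError("neuron_ids length mismatch")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]

    def cell_index(self, direction, state) -> np.ndarray:
        """Trial indices of one (class, state) cell."""
        return np.flatnonzero((self.class_label == direction) & (self.state == state))

    def cell_counts(self) -> pd.DataFrame:
        """Trial counts per (class, state) cell, ambiguous included."""
        return (
            pd.DataFrame({"direction": self.class_label, "state": self.state})
            .value_counts()
            .rename("n")
            .reset_index()
        )

    def select_trials(self, idx: np.ndarray) -> "TrialMatrix":
        return replace(
            self,
            responses=self.responses[idx],
            class_label=self.class_label[idx],
            state=self.state[idx],
        )

    def select_neurons(self, cols: np.ndarray) -> "TrialMatrix":
        return replace(
            self,
            responses=self.responses[:, cols],
            neuron_ids=np.asarray(self.neuron_ids)[cols],
        )


@dataclass
class TuningResult:
    """Per-neuron behavioral-state tuning summary."""

    curve: np.ndarray  # mean activity per covariate bin
    bin_centers: np.ndarray  # mean covariate per bin
    bin_edges: np.ndarray
    sem: np.ndarray
    levene_p: float
    spearman_rho: float
    spearman_p: float
    tclass: str  # positive | negative | nonmonotonic | untuned
    covariate: str = "speed"
    context: str = "stimulus"
    neuron_id: int = -1


@dataclass
class GaussianModelFit:
    """Winner of the constrained three-Gaussian model comparison."""

    model: str  # increasing | decreasing | interior
    amplitude: float
    center: float
    width: float
    offset: float
    cv_error: float
    cv_errors: dict = field(default_factory=dict)  # per-model mean CV error
    degenerate: bool = False


@dataclass
class DecodingResult:
    """Cross-validated state-conditioned decoding accuracies."""

    accuracy_running: float
    accuracy_stationary: float
    per_split_running: np.ndarray
    per_split_stationary: np.ndarray
    shuffled: bool = False
    exclusion: str = "none"  # none | running_positive | reliability_top_k
    k_percent: Optional[int] = None
    n_neurons: int = 0
    session_id: str = "synthetic"

    @property
    def gap(self) -> float:
        return self.accuracy_running - self.accuracy_stationary


@dataclass
class ReliabilityRecord:
    """Per-neuron reliability and grating-response metrics."""

    neuron_id: int
    rel_running: float
    rel_stationary: float
    pref_direction: float
    pct_change_pref: float
    pct_change_nonpref: float
    dsi: float
    responsive_p: float

    @property
    def delta_rel(self) -> float:
        return self.rel_running - self.rel_stationary


@dataclass
class RegionSummary:
    """Aggregate tuning statistics for one region × layer group."""

    region: str
    layer: str
    n_neurons: int
    fraction_tuned: float
    n_monotonic: int
    mean_rho_monotonic: float
    ci_low: float
    ci_high: float
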