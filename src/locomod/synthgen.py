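"""Synthetic two-photon session generator with known ground truth.

Emulates the structure of a drifting-gratings imaging session: 30 Hz ΔF/F
traces for a population of neurons, a running-speed trace organised in
stationary/running bouts, a pupil trace correlated with speed, and a
stimulus epoch table (a leading spontaneous block, then 2 s gratings
separated by 1 s blanks, 8 directions × ``n_reps`` repetitions in random
order).  Every neuron carries planted running-speed tuning (monotone up,
monotone down, a non-monotonic bump, or untuned), von-Mises direction
tuning, and trial noise whose standard deviation may differ between
running and stationary trials -- the "reliability gap" that downstream
analyses are asked to recover.  Noise correlations arise from a latent
multiplicative gain shared by all neurons within a trial.

Everything is deterministic given (config, truth, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._seeding import stage_rng
from .datatypes import DIRECTIONS, GroundTruth, SessionBundle

__all__ = [
    "BoutParams",
    "SessionConfig",
    "generate_speed_trace",
    "sample_ground_truth",
    "generate_session",
]

TEMPORAL_FREQUENCIES = np.array([1.0, 2.0, 4.0, 8.0, 15.0])


@dataclass
class BoutParams:
    """Two-state Markov bout structure for the running-speed trace.

    Dwell times are geometric with per-frame exit probabilities
    ``p_start`` (stationary → running) and ``p_stop``.  The defaults give
    mean dwell times of ~10 s and ~12 s at 30 Hz, i.e. bouts long relative
    to a 3 s trial so that most trials fall cleanly into one state.
    """

    p_start: float = 1.0 / 300.0
    p_stop: float = 1.0 / 270.0
    speed_lo: float = 8.0  # cm/s, slowest bout target
    speed_hi: float = 25.0  # cm/s
    jitter_sd: float = 1.5  # within-bout speed wobble, cm/s
    smooth_s: float = 0.4  # acceleration smoothing, seconds
    stationary_jitter_sd: float = 0.05  # sensor noise at rest, cm/s


def generate_speed_trace(
    duration_frames: int,
    frame_rate: float = 30.0,
    bout_params: Optional[BoutParams] = None,
    seed: int = 0,
) -> np.ndarray:
    """Running-speed trace (cm/s, >= 0) with Markov bout structure."""
    if duration_frames <= 0:
        raise ValueError("duration_frames must be positive")
    bp = bout_params or BoutParams()
    rng = np.random.default_rng(seed)

    # state chain: 0 = stationary, 1 = running
    u = rng.random(duration_frames)
    states = np.empty(duration_frames, dtype=np.int8)
    s = 0
    for i in range(duration_frames):
        if s == 0 and u[i] < bp.p_start:
            s = 1
        elif s == 1 and u[i] < bp.p_stop:
            s = 0
        states[i] = s
    if not states.any():
        return np.zeros(duration_frames)

    # per-bout target speed + within-bout jitter, smoothed into ramps
    speed = rng.normal(0.0, bp.stationary_jitter_sd, duration_frames)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], states, [0]))))
    for b0, b1 in zip(edges[::2], edges[1::2]):
        target = rng.uniform(bp.speed_lo, bp.speed_hi)
        speed[b0:b1] = target + rng.normal(0.0, bp.jitter_sd, b1 - b0)
    speed = gaussian_filter1d(speed, sigma=bp.smooth_s * frame_rate, mode="nearest")
    return np.clip(speed, 0.0, None)


@dataclass
class SessionConfig:
    """Session layout, tuning-population and noise parameters.

    Defaults mirror a full drifting-gratings session: 8 directions × 75
    repetitions of 2 s gratings with 1 s blanks at 30 Hz, preceded by a
    spontaneous (mean-luminance) block.  ``frac_state_noise`` is the
    fraction of neurons whose trial noise is lower while running
    (``noise_sd_run_mod`` vs the common ``noise_sd_stationary``); the rest
    have state-independent noise.  Set ``reliability_gap=False`` to make
    every neuron state-independent.
    """

    n_neurons: int = 100
    n_reps: int = 75
    frame_rate: float = 30.0
    stim_s: float = 2.0
    blank_s: float = 1.0
    spont_s: float = 120.0
    # population composition
    class_props: dict = field(
        default_factory=lambda: {"up": 0.25, "down": 0.25, "nonmono": 0.15, "untuned": 0.35}
    )
    speed_gain: float = 0.005  # |ΔF/F| per cm/s for monotone classes
    bump_amp: float = 0.1  # ΔF/F, non-monotonic class
    bump_center_range: tuple = (6.0, 14.0)  # cm/s
    bump_width: float = 4.0  # cm/s
    # direction tuning
    dir_amp_median: float = 0.15  # ΔF/F, lognormal median
    dir_amp_sigma: float = 0.6  # lognormal shape
    dir_kappa: float = 1.5
    stim_offset: float = 0.12  # untuned evoked component, ΔF/F
    # noise model
    reliability_gap: bool = True
    frac_state_noise: float = 0.5
    noise_sd_stationary: float = 0.25  # per-trial ΔF/F
    noise_sd_run_mod: float = 0.10  # running sd for state-modulated neurons
    shared_gain_sd: float = 0.15
    frame_noise_sd: float = 0.10  # fast per-frame noise, ΔF/F
    # scenario: running suppresses the untuned evoked component (non-
    # preferred responses), the activity-reduction motif of anterior areas
    run_offset_suppression: float = 0.0  # in [0, 1]
    # behavior
    bout_params: BoutParams = field(default_factory=BoutParams)
    pupil_base: float = 1.0
    pupil_gain: float = 0.04  # a.u. per cm/s of smoothed speed
    pupil_noise_sd: float = 0.02
    # optional extras
    calcium_tau_s: float = 0.0  # > 0 convolves dff with an exp kernel
    emit_raw: bool = False  # also carry raw fluorescence (1+dff)*F0
    region: str = "VISp"
    layer: str = "2/3"

    @property
    def n_directions(self) -> int:
        return len(DIRECTIONS)


def sample_ground_truth(config: SessionConfig, seed: int = 0) -> GroundTruth:
    """Draw per-neuron planted parameters from the config's population."""
    rng = stage_rng(seed, "truth")
    n = config.n_neurons
    classes = np.array(list(config.class_props))
    props = np.array([config.class_props[c] for c in classes], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("class proportions must sum to 1")
    neuron_class = rng.choice(classes, size=n, p=props)

    sign = np.where(neuron_class == "down", -1.0, 1.0)
    speed_gain = np.where(
        np.isin(neuron_class, ["up", "down"]),
        sign * config.speed_gain,
        np.where(neuron_class == "nonmono", config.bump_amp, 0.0),
    )
    noise_stat = np.full(n, config.noise_sd_stationary)
    if config.reliability_gap:
        modulated = rng.random(n) < config.frac_state_noise
        noise_run = np.where(modulated, config.noise_sd_run_mod, noise_stat)
    else:
        noise_run = noise_stat.copy()
    return GroundTruth(
        neuron_class=neuron_class,
        speed_gain=speed_gain,
        bump_center=rng.uniform(*config.bump_center_range, size=n),
        bump_width=np.full(n, config.bump_width),
        pref_direction=rng.choice(DIRECTIONS, size=n),
        dir_kappa=np.full(n, config.dir_kappa),
        dir_amp=np.exp(rng.normal(np.log(config.dir_amp_median), config.dir_amp_sigma, n)),
        stim_offset=np.full(n, config.stim_offset),
        noise_sd_running=noise_run,
        noise_sd_stationary=noise_stat,
        shared_gain_sd=config.shared_gain_sd,
        seed=seed,
    )


def _build_stim_table(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    fr = config.frame_rate
    spont_f = int(round(config.spont_s * fr))
    stim_f = int(round(config.stim_s * fr))
    blank_f = int(round(config.blank_s * fr))
    dirs = np.tile(DIRECTIONS, config.n_reps)
    rng.shuffle(dirs)
    tfs = rng.choice(TEMPORAL_FREQUENCIES, size=dirs.size)
    rows = []
    t = 0
    if spont_f:
        rows.append(("spontaneous", 0, spont_f, np.nan, np.nan))
        t = spont_f
    for d, tf in zip(dirs, tfs):
        rows.append(("drifting_grating", t, t + stim_f, float(d), float(tf)))
        t += stim_f
        rows.append(("blank", t, t + blank_f, np.nan, np.nan))
        t += blank_f
    return pd.DataFrame(
        rows,
        columns=["epoch_type", "start_frame", "end_frame", "direction", "temporal_frequency"],
    )


def _speed_tuning_term(truth: GroundTruth, speed: np.ndarray) -> np.ndarray:
    """(n_neurons, n_frames) planted speed-tuning drive."""
    n = truth.n_neurons
    term = np.zeros((n, speed.size))
    mono = np.isin(truth.neuron_class, ["up", "down"])
    term[mono] = truth.speed_gain[mono, None] * speed[None, :]
    bump = truth.neuron_class == "nonmono"
    if bump.any():
        z = (speed[None, :] - truth.bump_center[bump, None]) / truth.bump_width[bump, None]
        term[bump] = truth.speed_gain[bump, None] * np.exp(-0.5 * z**2)
    return term


def _direction_response(truth: GroundTruth, direction_deg: float) -> np.ndarray:
    """(n_neurons,) von-Mises tuned response amplitude, peak = dir_amp."""
    dtheta = np.deg2rad(direction_deg - truth.pref_direction)
    return truth.dir_amp * np.exp(truth.dir_kappa * (np.cos(dtheta) - 1.0))


def generate_session(
    config: SessionConfig,
    truth: Optional[GroundTruth] = None,
    seed: int = 0,
    session_id: Optional[str] = None,
) -> SessionBundle:
    """Generate one :class:`SessionBundle`; the planted truth rides along."""
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2 (trial-to-trial statistics undefined)")
    if truth is None:
        truth = sample_ground_truth(config, seed)
    rng = stage_rng(seed, "session")

    stim_table = _build_stim_table(config, rng)
    n_frames = int(stim_table["end_frame"].iloc[-1])
    speed = generate_speed_trace(
        n_frames,
        config.frame_rate,
        config.bout_params,
        seed=stage_rng(seed, "speed").integers(2**31),
    )

    n = truth.n_neurons
    dff = _speed_tuning_term(truth, speed)
    dff += rng.normal(0.0, config.frame_noise_sd, size=(n, n_frames))

    gratings = stim_table[stim_table["epoch_type"] == "drifting_grating"]
    for _, ep in gratings.iterrows():
        s0, s1 = int(ep["start_frame"]), int(ep["end_frame"])
        running_like = speed[s0:s1].mean() > 3.0
        evoked = _direction_response(truth, ep["direction"]) + truth.stim_offset * (
            1.0 - config.run_offset_suppression * running_like
        )
        gain = 1.0 + rng.normal(0.0, truth.shared_gain_sd)
        noise_sd = truth.noise_sd_running if running_like else truth.noise_sd_stationary
        trial_noise = rng.normal(0.0, 1.0, n) * noise_sd
        dff[:, s0:s1] += (gain * evoked + trial_noise)[:, None]

    if config.calcium_tau_s > 0:
        # causal exponential kernel, unit area; optional indicator dynamics
        tau_f = config.calcium_tau_s * config.frame_rate
        t = np.arange(int(np.ceil(6 * tau_f)) + 1)
        kern = np.exp(-t / tau_f)
        kern /= kern.sum()
        dff = np.apply_along_axis(lambda x: np.convolve(x, kern)[: x.size], 1, dff)

    smooth_speed = gaussian_filter1d(speed, sigma=config.frame_rate, mode="nearest")
    pupil = (
        config.pupil_base
        + config.pupil_gain * smooth_speed
        + rng.normal(0.0, config.pupil_noise_sd, n_frames)
    )
    pupil = np.clip(pupil, 0.05, None)

    raw = None
    if config.emit_raw:
        f0 = rng.uniform(100.0, 300.0, n)
        raw = f0[:, None] * (1.0 + dff)

    return SessionBundle(
        dff=dff,
        speed=speed,
        pupil=pupil,
        stim_table=stim_table,
        frame_rate=config.frame_rate,
        region=config.region,
        layer=config.layer,
        session_id=session_id or f"synth-{seed}",
        raw=raw,
        truth=truth,
    )
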