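"""End-to-end synthetic replay: generator → trials → tuning → decoding →
reliability → LIF, with a machine-readable report.

Scenarios
---------
``reliability_gap``
    The headline condition: half the neurons have lower trial noise while
    running (equal mean responses), a latent shared gain induces noise
    correlations, and the population contains all four speed-tuning
    classes.  Decoding should be better during running, the advantage
    should survive within-class shuffling and exclusion of running-excited
    neurons, and should collapse when the neurons with the most changed
    reliability are excluded.
``null``
    No state-dependent effect of any kind (equal noise, no speed tuning);
    the running-stationary comparison should be at chance.
``suppression``
    Running suppresses the untuned evoked component, lowering responses
    mainly to non-preferred stimuli -- the activity-reduction motif of
    anterior extrastriate areas.

A single root seed is fanned out deterministically to every stage, so a
replay is byte-identical across runs with the same seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import decoding, reliability, state_tuning
from ._seeding import stage_rng, stage_seed
from .datatypes import STATE_RUNNING, STATE_STATIONARY, SessionBundle, TrialMatrix
from .lifsim import IN_VIVO_NOISE_PAIR, LIFConfig, closed_form_rate, run_lif_experiment
from .preprocess import balance_trials, extract_trial_responses
from .synthgen import SessionConfig, generate_session

logger = logging.getLogger(__name__)

__all__ = ["ReplayConfig", "scenario_config", "replay", "analyze_session", "write_report"]

SCENARIOS = ("reliability_gap", "null", "suppression")


def scenario_config(name: str, **overrides) -> SessionConfig:
    """SessionConfig preset for a named scenario (overrides win)."""
    if name == "reliability_gap":
        base = {}
    elif name == "null":
        base = {
            "reliability_gap": False,
            "class_props": {"up": 0.0, "down": 0.0, "nonmono": 0.0, "untuned": 1.0},
        }
    elif name == "suppression":
        base = {"reliability_gap": False, "run_offset_suppression": 0.5}
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    base.update(overrides)
    return SessionConfig(**base)


@dataclass
class ReplayConfig:
    """Replay problem size and per-stage parameters."""

    scenario: str = "reliability_gap"
    n_sessions: int = 8
    n_neurons: int = 100
    n_reps: int = 40
    min_cell_trials: int = 5  # balanced trials per (class, state) cell
    n_perm: int = 1  # tuning permutations
    n_splits: int = 10
    exclusion_k: tuple = (25, 50)
    lif_peaks_nA: tuple = (0.3, 0.5, 0.7, 0.9)
    lif_n_runs: int = 3
    session_overrides: dict = field(default_factory=dict)


@dataclass
class SessionAnalysis:
    """Everything computed for one session during replay."""

    session_id: str
    tm: TrialMatrix  # balanced
    tclass: np.ndarray  # per-neuron speed-tuning class
    delta_rel: np.ndarray  # per-neuron reliability change
    decodings: dict  # condition name -> DecodingResult (or None)


CONDITIONS = (
    "all",
    "exclude_running_positive",
    "shuffled",
    "exclude_running_positive_shuffled",
    "exclude_rel25",
    "exclude_rel50",
)


def analyze_session(
    bundle: SessionBundle,
    seed: int,
    n_perm: int = 1,
    n_splits: int = 10,
    exclusion_k: tuple = (25, 50),
    conditions: tuple = CONDITIONS,
) -> Optional[SessionAnalysis]:
    """Tuning, reliability and all decoding conditions for one session.

    Returns None when the session cannot be balanced (an empty
    (class, state) cell), mirroring the exclusion of sessions without
    enough running or stationary periods.
    """
    tm = extract_trial_responses(bundle)
    try:
        tmb = balance_trials(tm, seed=stage_rng(seed, "balance").integers(2**31))
    except ValueError as e:
        logger.warning("session %s excluded: %s", bundle.session_id, e)
        return None
    n_star = tmb.n_trials // (len(np.unique(tmb.class_label)) * 2)
    if n_star < 2:
        logger.warning(
            "session %s excluded: only %d balanced trials per cell", bundle.session_id, n_star
        )
        return None

    frames = state_tuning.context_frames(bundle, "stimulus")
    speed = bundle.speed[frames]
    tclass = np.array(
        [
            state_tuning.evaluate_tuning(
                bundle.dff[j, frames],
                speed,
                n_perm=n_perm,
                seed=int(stage_seed(seed, "tuning", j).generate_state(1)[0] % 2**31),
                neuron_id=j,
            ).tclass
            for j in range(bundle.n_neurons)
        ]
    )
    records = reliability.reliability_records(tmb)
    delta_rel = np.array([r.delta_rel for r in records])

    decodings: dict = {}
    for cond in conditions:
        work = tmb
        shuffled = "shuffled" in cond
        exclusion, kpct = "none", None
        try:
            if "running_positive" in cond:
                exclusion = "running_positive"
                work = decoding.exclude_neurons(work, "running_positive", tclass)
            if cond.startswith("exclude_rel"):
                exclusion, kpct = "reliability_top_k", int(cond.removeprefix("exclude_rel"))
                work = decoding.exclude_neurons(
                    work, "reliability_top_k", delta_rel, k_percent=kpct
                )
            if shuffled:
                work = decoding.shuffle_within_class(
                    work, seed=stage_rng(seed, "shuffle", cond).integers(2**31)
                )
            decodings[cond] = decoding.fit_eval_mlr(
                work,
                n_splits=n_splits,
                seed=stage_rng(seed, "decode", cond).integers(2**31),
                shuffled=shuffled,
                exclusion=exclusion,
                k_percent=kpct,
            )
        except ValueError as e:
            logger.warning("session %s condition %s skipped: %s", bundle.session_id, cond, e)
            decodings[cond] = None
    return SessionAnalysis(
        session_id=bundle.session_id,
        tm=tmb,
        tclass=tclass,
        delta_rel=delta_rel,
        decodings=decodings,
    )


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if np.isnan(v) else v
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _jsonable(x.tolist())
    return x


def replay(config: ReplayConfig, seed: int = 0) -> dict:
    """Run the full synthetic pipeline and return the report dict."""
    scfg = scenario_config(
        config.scenario,
        n_neurons=config.n_neurons,
        n_reps=config.n_reps,
        **config.session_overrides,
    )
    analyses = []
    attempts = 0
    max_attempts = 2 * config.n_sessions
    while len(analyses) < config.n_sessions and attempts < max_attempts:
        sid = attempts
        attempts += 1
        bundle = generate_session(
            scfg,
            seed=int(stage_seed(seed, "session", sid).generate_state(1)[0] % 2**31),
            session_id=f"{config.scenario}-{sid}",
        )
        res = analyze_session(
            bundle,
            seed=int(stage_seed(seed, "analysis", sid).generate_state(1)[0] % 2**31),
            n_perm=config.n_perm,
            n_splits=config.n_splits,
            exclusion_k=config.exclusion_k,
        )
        if res is None:
            continue
        n_star = res.tm.n_trials // (8 * 2)
        if n_star < config.min_cell_trials:
            logger.warning("session %s excluded: only %d balanced trials/cell", sid, n_star)
            continue
        analyses.append(res)

    report: dict = {
        "scenario": config.scenario,
        "seed": int(seed),
        "n_sessions": len(analyses),
        "conditions": {},
        "tuning": {},
        "reliability": {},
        "lif": {},
    }
    # per-condition aggregates and Wilcoxon comparison
    for cond in CONDITIONS:
        results = [a.decodings[cond] for a in analyses if a.decodings[cond] is not None]
        if not results:
            report["conditions"][cond] = None
            continue
        entry = {
            "n_sessions": len(results),
            "accuracy_running": float(np.mean([r.accuracy_running for r in results])),
            "accuracy_stationary": float(np.mean([r.accuracy_stationary for r in results])),
            "mean_gap": float(np.mean([r.gap for r in results])),
            "per_session_gap": [r.gap for r in results],
        }
        if len(results) >= 6:
            stat, p = decoding.compare_states(results)
            entry["wilcoxon_p"] = p
            entry["median_gap"] = stat
        report["conditions"][cond] = entry

    # tuning composition
    all_classes = np.concatenate([a.tclass for a in analyses]) if analyses else np.array([])
    for c in ("positive", "negative", "nonmonotonic", "untuned"):
        report["tuning"][f"fraction_{c}"] = (
            float(np.mean(all_classes == c)) if all_classes.size else None
        )

    # reliability change and its relation to the decoding gap (per session)
    if analyses:
        mean_dr = np.array([a.delta_rel.mean() for a in analyses])
        report["reliability"]["mean_delta_rel"] = float(mean_dr.mean())
        gaps = np.array(
            [a.decodings["all"].gap for a in analyses if a.decodings["all"] is not None]
        )
        if gaps.size == mean_dr.size and gaps.size >= 3 and np.ptp(mean_dr) > 0:
            fit = reliability.ols_wald(
                mean_dr, gaps, seed=stage_rng(seed, "gap_vs_delta_rel").integers(2**31)
            )
            report["reliability"]["gap_vs_delta_rel_slope"] = fit.slope
            report["reliability"]["gap_vs_delta_rel_p"] = fit.p_value

    # LIF mechanism summary
    lif_cfg = LIFConfig()
    grid = run_lif_experiment(
        lif_cfg,
        noise_vars_mV2=np.array(IN_VIVO_NOISE_PAIR),
        peak_currents_nA=np.array(config.lif_peaks_nA),
        n_runs=config.lif_n_runs,
        seed=int(stage_seed(seed, "lif").generate_state(1)[0] % 2**31),
    )
    report["lif"] = {
        "noise_vars_mV2": list(grid.noise_vars_mV2),
        "peak_currents_nA": list(grid.peak_currents_nA),
        "firing_rate_hz": grid.firing_rate_hz,
        "reliability": grid.reliability,
        "closed_form_rate_0p5nA_hz": closed_form_rate(lif_cfg, 0.5),
    }
    return _jsonable(report)


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a replay report deterministically (sorted keys)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
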