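"""Single-neuron response reliability and grating-response metrics.

Reliability is the variance of a neuron's mean response across stimuli
divided by the total variance of all its responses (population variances
throughout, so with equal trial counts the statistic lies in [0, 1]): a
neuron is reliable when it responds differently to different stimuli but
consistently across repeats of the same stimulus.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from ._seeding import stage_rng
from .datatypes import (
    STATE_RUNNING,
    STATE_STATIONARY,
    ReliabilityRecord,
    TrialMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "reliability",
    "reliability_by_state",
    "reliability_records",
    "population_tuning_curves",
    "pref_vs_nonpref_change",
    "dsi",
    "responsiveness_anova",
    "ols_wald",
    "PopulationCurves",
    "OLSWaldResult",
]


def reliability(responses: np.ndarray) -> float:
    """Signal-variance fraction of a stimuli × trials response matrix.

    Returns NaN (flagged undefined) when the total variance is zero.
    """
    R = np.asarray(responses, dtype=float)
    if R.ndim != 2:
        raise ValueError("responses must be a (stimuli, trials) matrix")
    n_stim, n_trials = R.shape
    if n_stim < 2 or n_trials < 2:
        raise ValueError("need >= 2 stimuli and >= 2 trials per stimulus")
    total = R.var()
    if total == 0:
        logger.warning("zero total variance; reliability undefined")
        return float("nan")
    return float(R.mean(axis=1).var() / total)


def _stim_by_trial(tm: TrialMatrix, neuron: int, state: str) -> Optional[np.ndarray]:
    """Stimuli × trials matrix for one neuron in one state (balanced input)."""
    classes = np.unique(tm.class_label)
    cols = []
    n_per = None
    for d in classes:
        idx = tm.cell_index(d, state)
        if idx.size == 0:
            return None
        if n_per is None:
            n_per = idx.size
        elif idx.size != n_per:
            raise ValueError("unequal trial counts per stimulus; balance trials first")
        cols.append(tm.responses[idx, neuron])
    return np.array(cols)


def reliability_by_state(tm: TrialMatrix, neuron: int) -> tuple[float, float]:
    """(rel_running, rel_stationary) for one neuron of a balanced matrix."""
    out = []
    for s in (STATE_RUNNING, STATE_STATIONARY):
        R = _stim_by_trial(tm, neuron, s)
        out.append(float("nan") if R is None else reliability(R))
    return out[0], out[1]


def _state_means(tm: TrialMatrix, neuron: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(classes, mean_running, mean_stationary) per stimulus for one neuron."""
    classes = np.unique(tm.class_label)
    mr = np.array([tm.responses[tm.cell_index(d, STATE_RUNNING), neuron].mean() for d in classes])
    ms = np.array(
        [tm.responses[tm.cell_index(d, STATE_STATIONARY), neuron].mean() for d in classes]
    )
    return classes, mr, ms


def dsi(r_pref: float, r_null: float) -> float:
    """Direction selectivity index (R_pref - R_null) / (R_pref + R_null)."""
    denom = r_pref + r_null
    if denom == 0:
        logger.warning("zero DSI denominator; undefined")
        return float("nan")
    return float((r_pref - r_null) / denom)


def responsiveness_anova(groups: Sequence[np.ndarray]) -> float:
    """One-way ANOVA p across responses grouped by stimulus condition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 stimulus conditions")
    return float(stats.f_oneway(*groups).pvalue)


def reliability_records(tm: TrialMatrix) -> list[ReliabilityRecord]:
    """Per-neuron reliability / preference / DSI / responsiveness table.

    Preference is the argmax of the mean response pooled over states; the
    null direction for DSI is orthogonal (+90°) to the preferred one.
    Percent changes use the stationary mean as baseline.
    """
    classes = np.unique(tm.class_label)
    records = []
    for j in range(tm.n_neurons):
        rel_r, rel_s = reliability_by_state(tm, j)
        dirs, mr, ms = _state_means(tm, j)
        pooled = np.array([tm.responses[tm.class_label == d, j].mean() for d in dirs])
        k = int(np.argmax(pooled))
        pref = float(dirs[k])
        null_dir = (pref + 90.0) % 360.0
        kn = int(np.flatnonzero(dirs == null_dir)[0]) if null_dir in dirs else None
        d_val = dsi(pooled[k], pooled[kn]) if kn is not None else float("nan")
        others = np.arange(len(dirs)) != k
        pct_pref = _pct_change(mr[k], ms[k])
        pct_non = _pct_change(mr[others].mean(), ms[others].mean())
        groups = [tm.responses[tm.class_label == d, j] for d in dirs]
        records.append(
            ReliabilityRecord(
                neuron_id=int(tm.neuron_ids[j]),
                rel_running=rel_r,
                rel_stationary=rel_s,
                pref_direction=pref,
                pct_change_pref=pct_pref,
                pct_change_nonpref=pct_non,
                dsi=d_val,
                responsive_p=responsiveness_anova(groups),
            )
        )
    return records


def _pct_change(run_mean: float, stat_mean: float, eps: float = 1e-9) -> float:
    if abs(stat_mean) < eps:
        return float("nan")
    return float(100.0 * (run_mean - stat_mean) / stat_mean)


@dataclass
class PopulationCurves:
    """Average sorted (preference-ranked) tuning curves per state."""

    running: np.ndarray  # (n_stimuli,) mean z-scored response, rank-sorted
    stationary: np.ndarray
    ci_running: np.ndarray  # (2, n_stimuli) bootstrap 95% CI
    ci_stationary: np.ndarray
    n_neurons: int


def population_tuning_curves(
    tm: TrialMatrix,
    neuron_mask: Optional[np.ndarray] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> PopulationCurves:
    """Preference-sorted population tuning curves split by state.

    Each neuron's trial responses are z-scored across all stimuli and both
    states pooled, per-stimulus means are computed per state, stimuli are
    sorted by the pooled mean (descending) and the sorted curves averaged
    across neurons, with a percentile bootstrap (over neurons) CI.
    """
    neurons = np.arange(tm.n_neurons) if neuron_mask is None else np.flatnonzero(neuron_mask)
    classes = np.unique(tm.class_label)
    curves_r, curves_s = [], []
    n_skipped = 0
    for j in neurons:
        x = tm.responses[:, j]
        sd = x.std()
        if sd == 0:
            n_skipped += 1
            continue
        z = (x - x.mean()) / sd
        run_idx = [tm.cell_index(d, STATE_RUNNING) for d in classes]
        st_idx = [tm.cell_index(d, STATE_STATIONARY) for d in classes]
        if any(i.size == 0 for i in run_idx) or any(i.size == 0 for i in st_idx):
            n_skipped += 1
            continue
        mr = np.array([z[i].mean() for i in run_idx])
        ms = np.array([z[i].mean() for i in st_idx])
        pooled = np.array([z[tm.class_label == d].mean() for d in classes])
        order = np.argsort(-pooled, kind="stable")
        curves_r.append(mr[order])
        curves_s.append(ms[order])
    if n_skipped:
        logger.info("skipped %d neurons without trials in a state or with zero sd", n_skipped)
    if not curves_r:
        raise ValueError("no usable neurons for population curves")
    CR, CS = np.array(curves_r), np.array(curves_s)
    rng = stage_rng(seed, "popcurves")
    idx = rng.integers(0, CR.shape[0], size=(n_boot, CR.shape[0]))
    boot_r = CR[idx].mean(axis=1)
    boot_s = CS[idx].mean(axis=1)
    return PopulationCurves(
        running=CR.mean(axis=0),
        stationary=CS.mean(axis=0),
        ci_running=np.percentile(boot_r, [2.5, 97.5], axis=0),
        ci_stationary=np.percentile(boot_s, [2.5, 97.5], axis=0),
        n_neurons=CR.shape[0],
    )


def pref_vs_nonpref_change(
    tm: TrialMatrix, neuron_mask: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Session-average percent change (running vs stationary) of the
    response to each neuron's preferred stimulus vs all other stimuli."""
    neurons = np.arange(tm.n_neurons) if neuron_mask is None else np.flatnonzero(neuron_mask)
    pref_changes, non_changes = [], []
    for j in neurons:
        dirs, mr, ms = _state_means(tm, j)
        pooled = np.array([tm.responses[tm.class_label == d, j].mean() for d in dirs])
        k = int(np.argmax(pooled))
        others = np.arange(len(dirs)) != k
        pp = _pct_change(mr[k], ms[k])
        pn = _pct_change(mr[others].mean(), ms[others].mean())
        if np.isnan(pp) or np.isnan(pn):
            logger.info("neuron %d skipped (near-zero stationary mean)", j)
            continue
        pref_changes.append(pp)
        non_changes.append(pn)
    if not pref_changes:
        raise ValueError("no usable neurons")
    return float(np.mean(pref_changes)), float(np.mean(non_changes))


@dataclass
class OLSWaldResult:
    """OLS slope with Wald t-test p and a bootstrap line envelope."""

    slope: float
    intercept: float
    p_value: float
    r_value: float
    x_grid: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray


def ols_wald(
    x: np.ndarray, y: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> OLSWaldResult:
    """Ordinary least squares with a two-sided Wald t-test on the slope and
    a 95% percentile bootstrap envelope of the fitted line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has no variance")
    fit = stats.linregress(x, y)
    rng = stage_rng(seed, "ols_boot")
    grid = np.linspace(x.min(), x.max(), 50)
    lines = np.empty((n_boot, grid.size))
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        while np.ptp(x[idx]) == 0:  # resample until the predictor varies
            idx = rng.integers(0, n, n)
        f = stats.linregress(x[idx], y[idx])
        lines[b] = f.intercept + f.slope * grid
    lo, hi = np.percentile(lines, [2.5, 97.5], axis=0)
    return OLSWaldResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_value=float(fit.rvalue),
        x_grid=grid,
        envelope_low=lo,
        envelope_high=hi,
    )
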