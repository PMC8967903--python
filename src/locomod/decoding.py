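"""State-conditioned stimulus decoding with shuffling and exclusion controls.

An unregularised 8-way multinomial logistic regression is trained and
tested separately on running and stationary trials of a balanced
:class:`TrialMatrix`, over 10 random class-stratified 50:50 train/test
splits that are shared between the two state decoders.  Controls:

* ``shuffle_within_class`` permutes each neuron's responses across trials
  of the same (class, state) cell, destroying noise correlations while
  preserving every single-neuron marginal exactly;
* ``exclude_neurons`` drops running-excited neurons (significant positive
  speed tuning) or the top-k% of neurons by absolute reliability change;
* ``compare_states`` tests the paired running-stationary accuracy
  difference across sessions with a two-sided Wilcoxon signed-rank test
  (exact null distribution for small samples).
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .datatypes import (
    STATE_RUNNING,
    STATE_STATIONARY,
    DecodingResult,
    TrialMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "fit_eval_mlr",
    "shuffle_within_class",
    "exclude_neurons",
    "compare_states",
    "MIN_NEURONS",
]

#: Sessions with fewer surviving neurons than this are excluded.
MIN_NEURONS = 10


def _fit_mlr(X: np.ndarray, y: np.ndarray, tol: float, max_iter: int) -> LogisticRegression:
    clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning:
            logger.info("MLR did not converge; refitting with a tiny ridge")
            clf = LogisticRegression(C=1e8, solver="lbfgs", tol=tol, max_iter=max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X, y)
    return clf


def fit_eval_mlr(
    tm: TrialMatrix,
    n_splits: int = 10,
    train_frac: float = 0.5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    shuffled: bool = False,
    exclusion: str = "none",
    k_percent: Optional[int] = None,
) -> DecodingResult:
    """Cross-validated per-state decoding accuracy on a balanced TrialMatrix.

    Each split partitions every (class, state) cell 50:50 so that both
    state decoders see identical class balance; a decoder per state is
    trained on that state's training trials and scored on its held-out
    trials.  The ``shuffled``/``exclusion`` flags only annotate the result
    (apply :func:`shuffle_within_class` / :func:`exclude_neurons` first).
    """
    rng = np.random.default_rng(seed)
    states = (STATE_RUNNING, STATE_STATIONARY)
    classes = np.unique(tm.class_label)
    cells = {(d, s): tm.cell_index(d, s) for d in classes for s in states}
    for (d, s), idx in cells.items():
        if idx.size < 2:
            raise ValueError(f"cell (class={d}, state={s}) has {idx.size} trials; need >= 2")
    acc = {s: [] for s in states}
    for _ in range(n_splits):
        train_idx = {s: [] for s in states}
        test_idx = {s: [] for s in states}
        for (d, s), idx in cells.items():
            perm = rng.permutation(idx)
            n_train = max(1, min(idx.size - 1, int(round(train_frac * idx.size))))
            train_idx[s].append(perm[:n_train])
            test_idx[s].append(perm[n_train:])
        for s in states:
            tr = np.concatenate(train_idx[s])
            te = np.concatenate(test_idx[s])
            clf = _fit_mlr(tm.responses[tr], tm.class_label[tr], tol, max_iter)
            acc[s].append(float(np.mean(clf.predict(tm.responses[te]) == tm.class_label[te])))
    return DecodingResult(
        accuracy_running=float(np.mean(acc[STATE_RUNNING])),
        accuracy_stationary=float(np.mean(acc[STATE_STATIONARY])),
        per_split_running=np.array(acc[STATE_RUNNING]),
        per_split_stationary=np.array(acc[STATE_STATIONARY]),
        shuffled=shuffled,
        exclusion=exclusion,
        k_percent=k_percent,
        n_neurons=tm.n_neurons,
        session_id=tm.source_session,
    )


def shuffle_within_class(tm: TrialMatrix, seed: int = 0) -> TrialMatrix:
    """Permute each neuron's responses across trials within every
    (class, state) cell, independently per neuron; labels untouched."""
    rng = np.random.default_rng(seed)
    responses = tm.responses.copy()
    for d in np.unique(tm.class_label):
        for s in np.unique(tm.state):
            idx = tm.cell_index(d, s)
            if idx.size > 1:
                responses[idx] = rng.permuted(responses[idx], axis=0)
    out = tm.select_trials(np.arange(tm.n_trials))
    out.responses = responses
    return out


def exclude_neurons(
    tm: TrialMatrix,
    rule: str,
    aux: np.ndarray,
    k_percent: Optional[int] = None,
    min_neurons: int = MIN_NEURONS,
) -> TrialMatrix:
    """Drop neurons by the requested control rule.

    ``running_positive``: ``aux`` is the per-neuron tuning class array;
    neurons classified ``positive`` (significant positive monotonic speed
    tuning) are removed.  ``reliability_top_k``: ``aux`` is the per-neuron
    reliability change (running - stationary); the ``k_percent`` of neurons
    with the largest absolute change are removed.
    """
    aux = np.asarray(aux)
    if aux.shape[0] != tm.n_neurons:
        raise ValueError("aux table must cover every neuron in the TrialMatrix")
    if rule == "running_positive":
        keep = np.flatnonzero(aux != "positive")
    elif rule == "reliability_top_k":
        if k_percent is None:
            raise ValueError("k_percent required for reliability_top_k")
        n_drop = int(round(k_percent / 100.0 * tm.n_neurons))
        order = np.argsort(-np.abs(aux.astype(float)), kind="stable")
        keep = np.sort(order[n_drop:])
    else:
        raise ValueError(f"unknown exclusion rule {rule!r}")
    if keep.size < min_neurons:
        raise ValueError(
            f"only {keep.size} neurons survive exclusion {rule!r}; session excluded"
        )
    return tm.select_neurons(keep)


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p via the sign-flip distribution.

    Midranks handle ties; zeros are dropped beforehand.  The distribution
    of W+ over all 2^n sign assignments is built by convolution on a
    half-unit grid (ranks doubled to integers).
    """
    r2 = (2 * stats.rankdata(np.abs(diffs))).astype(int)  # doubled midranks
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    w = int(round((2 * stats.rankdata(np.abs(diffs))[diffs > 0].sum())))
    p_lo = dist[: w + 1].sum()
    p_hi = dist[w:].sum()
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def compare_states(
    results: Sequence[DecodingResult], exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on per-session accuracy differences.

    Returns (median paired difference, p).  Zero differences are dropped;
    if all are zero the comparison is degenerate and p = 1.
    """
    results = list(results)
    if len(results) < 6:
        raise ValueError("need >= 6 paired sessions")
    diffs = np.array([r.gap for r in results])
    stat = float(np.median(diffs))
    nz = diffs[diffs != 0]
    if nz.size == 0:
        logger.warning("all paired differences are zero; degenerate comparison")
        return stat, 1.0
    if nz.size <= exact_max_n:
        return stat, _exact_signed_rank_p(nz)
    _, p = stats.wilcoxon(nz, alternative="two-sided", method="approx")
    return stat, float(p)
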