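"""Per-neuron behavioral-state tuning (speed or pupil covariates).

A neuron's tuning curve is its mean activity in 20 quantile bins of the
covariate.  Significance of tuning is assessed by comparing the variance
of the real binned curve against the curve obtained after randomly
permuting the activity trace, with Levene's test (one-sided: the real
curve must be MORE variable).  Monotonicity is classified from Spearman's
rho computed on the binned curve.  A constrained three-Gaussian model
comparison (center above the speed range = increasing, below = decreasing,
inside = interior bump) is selected by cross-validation.
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from ._seeding import stage_rng
from .datatypes import GaussianModelFit, RegionSummary, SessionBundle, TuningResult

logger = logging.getLogger(__name__)

__all__ = [
    "speed_tuning_curve",
    "tuning_significance",
    "classify_tuning",
    "evaluate_tuning",
    "fit_gaussian_speed_models",
    "session_qc",
    "aggregate_region",
    "context_frames",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# binning

def _quantile_bins(covariate: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin index per sample and bin edges; duplicate quantile edges (heavy
    ties, e.g. a large mass at speed 0) are merged with a log message."""
    edges = np.quantile(covariate, np.linspace(0, 1, n_bins + 1))
    uniq = np.unique(edges)
    if uniq.size < edges.size:
        logger.info("merged %d tied covariate bins", edges.size - uniq.size)
    if uniq.size < 2:
        raise ValueError("covariate is constant; tuning curve undefined")
    idx = np.clip(np.searchsorted(uniq[1:-1], covariate, side="right"), 0, uniq.size - 2)
    return idx, uniq


def _equal_width_bins(covariate: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    edges = np.linspace(covariate.min(), covariate.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges[1:-1], covariate, side="right"), 0, n_bins - 1)
    # drop empty bins so downstream group statistics stay defined
    occupied = np.isin(np.arange(n_bins), idx)
    if not occupied.all():
        logger.info("merged %d empty equal-width bins", int((~occupied).sum()))
        remap = np.cumsum(occupied) - 1
        idx = remap[idx]
        edges = np.concatenate((edges[:-1][occupied], [edges[-1]]))
    return idx, edges


def speed_tuning_curve(
    activity: np.ndarray,
    covariate: np.ndarray,
    n_bins: int = 20,
    binning: str = "quantile",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Binned tuning curve: (curve, bin_centers, bin_edges, sem)."""
    activity = np.asarray(activity, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if activity.shape != covariate.shape:
        raise ValueError("activity and covariate must have equal length")
    if binning == "quantile":
        idx, edges = _quantile_bins(covariate, n_bins)
    elif binning == "equal_width":
        idx, edges = _equal_width_bins(covariate, n_bins)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    nb = edges.size - 1
    counts = np.bincount(idx, minlength=nb)
    curve = np.bincount(idx, weights=activity, minlength=nb) / counts
    centers = np.bincount(idx, weights=covariate, minlength=nb) / counts
    sq = np.bincount(idx, weights=activity**2, minlength=nb) / counts
    var = np.maximum(sq - curve**2, 0.0)
    sem = np.sqrt(var / counts)
    return curve, centers, edges, sem


# ---------------------------------------------------------------------------
# significance

def _levene_one_sided(real: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Classic Levene (center = mean) between ``real`` (B,) and each row of
    ``perm`` (P, B); one-sided p, small when the real curve is more variable."""
    B = real.size
    z1 = np.abs(real - real.mean())
    z2 = np.abs(perm - perm.mean(axis=1, keepdims=True))
    zb1, zb2 = z1.mean(), z2.mean(axis=1)
    zbar = (zb1 + zb2) / 2.0
    num = B * ((zb1 - zbar) ** 2 + (zb2 - zbar) ** 2)
    den = ((z1 - zb1) ** 2).sum() + ((z2 - zb2[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = (2 * B - 2) * num / den
    p_two = np.where(den > 0, stats.f.sf(W, 1, 2 * B - 2), 1.0)
    real_more = real.var(ddof=1) > perm.var(axis=1, ddof=1)
    return np.where(real_more, p_two / 2.0, 1.0 - p_two / 2.0)


def _permuted_bin_means(
    activity: np.ndarray, idx: np.ndarray, nb: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    counts = np.bincount(idx, minlength=nb).astype(float)
    perms = rng.permuted(np.broadcast_to(activity, (n_perm, activity.size)).copy(), axis=1)
    order = np.argsort(idx, kind="stable")
    starts = np.concatenate(([0], np.cumsum(np.bincount(idx, minlength=nb))[:-1]))
    return np.add.reduceat(perms[:, order], starts, axis=1) / counts


def tuning_significance(
    activity: np.ndarray,
    covariate: np.ndarray,
    n_perm: int = 1,
    seed: int = 0,
    n_bins: int = 20,
    binning: str = "quantile",
) -> tuple[float, float, float]:
    """(levene_p, spearman_rho, spearman_p) for one neuron.

    With ``n_perm == 1`` (default) the real curve is compared against a
    single shuffled curve; with more permutations the reported Levene p is
    the median across permutations, a deliberately conservative variant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    activity = np.asarray(activity, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    curve, centers, _, _ = speed_tuning_curve(activity, covariate, n_bins, binning)
    if binning == "quantile":
        idx, edges = _quantile_bins(covariate, n_bins)
    else:
        idx, edges = _equal_width_bins(covariate, n_bins)
    nb = edges.size - 1
    rng = np.random.default_rng(seed)
    if np.allclose(curve.var(), 0.0):
        levene_p = 1.0  # constant curve can never be MORE variable
    else:
        perm_means = _permuted_bin_means(activity, idx, nb, n_perm, rng)
        levene_p = float(np.median(_levene_one_sided(curve, perm_means)))
    if np.allclose(curve, curve[0]):
        rho, sp = 0.0, 1.0
    else:
        rho, sp = stats.spearmanr(centers, curve)
    return levene_p, float(rho), float(sp)


def classify_tuning(
    levene_p: float, spearman_rho: float, spearman_p: float, alpha: float = ALPHA
) -> str:
    """Decision table: monotone classes from Spearman, ``nonmonotonic`` when
    only the Levene variance test fires, ``untuned`` otherwise."""
    for p in (levene_p, spearman_p):
        if not (0.0 <= p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    if spearman_p < alpha and spearman_rho > 0:
        return "positive"
    if spearman_p < alpha and spearman_rho < 0:
        return "negative"
    if levene_p < alpha:
        return "nonmonotonic"
    return "untuned"


def evaluate_tuning(
    activity: np.ndarray,
    covariate: np.ndarray,
    n_perm: int = 1,
    seed: int = 0,
    n_bins: int = 20,
    binning: str = "quantile",
    alpha: float = ALPHA,
    covariate_name: str = "speed",
    context: str = "stimulus",
    neuron_id: int = -1,
) -> TuningResult:
    """Full per-neuron tuning summary (curve + significance + class)."""
    curve, centers, edges, sem = speed_tuning_curve(activity, covariate, n_bins, binning)
    lp, rho, sp = tuning_significance(activity, covariate, n_perm, seed, n_bins, binning)
    return TuningResult(
        curve=curve,
        bin_centers=centers,
        bin_edges=edges,
        sem=sem,
        levene_p=lp,
        spearman_rho=rho,
        spearman_p=sp,
        tclass=classify_tuning(lp, rho, sp, alpha),
        covariate=covariate_name,
        context=context,
        neuron_id=neuron_id,
    )


# ---------------------------------------------------------------------------
# constrained Gaussian models

def _gauss(x: np.ndarray, amp: float, center: float, width: float, offset: float) -> np.ndarray:
    return offset + amp * np.exp(-0.5 * ((x - center) / width) ** 2)


def _fit_one_model(
    x: np.ndarray, y: np.ndarray, center_bounds: tuple[float, float], rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Bounded least squares with 3 jittered restarts; returns (params, sse)."""
    span = x.max() - x.min()
    amp0 = max(y.max() - y.min(), 1e-12)
    c0 = float(np.clip(x[np.argmax(y)], *center_bounds))
    lo = [0.0, center_bounds[0], span / 50.0, y.min() - 10 * amp0]
    hi = [10 * amp0, center_bounds[1], 10 * span, y.max() + 10 * amp0]
    best, best_sse = None, np.inf
    for k in range(3):
        p0 = np.array([amp0, c0, span / 4.0, y.min()])
        if k:
            p0 = p0 * rng.uniform(0.5, 1.5, 4)
        p0 = np.clip(p0, lo, hi)
        try:
            res = optimize.least_squares(
                lambda p: _gauss(x, *p) - y, p0, bounds=(lo, hi), method="trf"
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        sse = float(np.sum(res.fun**2))
        if sse < best_sse:
            best, best_sse = res.x, sse
    if best is None:
        return np.array([0.0, np.mean(center_bounds), span / 4.0, y.mean()]), np.inf
    return best, best_sse


def fit_gaussian_speed_models(
    activity: np.ndarray,
    covariate: np.ndarray,
    n_cv: int = 10,
    train_frac: float = 0.75,
    seed: int = 0,
    n_bins: int = 20,
    binning: str = "quantile",
) -> GaussianModelFit:
    """Select among increasing / decreasing / interior constrained Gaussians.

    Per CV split, tuning curves are built from the training frames, each
    model is fit to the training curve by bounded least squares, and scored
    by squared error against the held-out curve; the model with the lowest
    mean CV error wins.  Final reported parameters are refit on all data.
    """
    activity = np.asarray(activity, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    rng = np.random.default_rng(seed)
    vmin, vmax = covariate.min(), covariate.max()
    span = vmax - vmin
    bounds = {
        "increasing": (vmax, vmax + 5 * span),
        "decreasing": (vmin - 5 * span, vmin),
        "interior": (vmin + 1e-9 * span, vmax - 1e-9 * span),
    }
    n = activity.size
    errors = {m: [] for m in bounds}
    for _ in range(n_cv):
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        tr, te = perm[:n_train], perm[n_train:]
        yc_tr, xc_tr, _, _ = speed_tuning_curve(activity[tr], covariate[tr], n_bins, binning)
        yc_te, xc_te, _, _ = speed_tuning_curve(activity[te], covariate[te], n_bins, binning)
        for m, cb in bounds.items():
            params, _ = _fit_one_model(xc_tr, yc_tr, cb, rng)
            err = float(np.mean((_gauss(xc_te, *params) - yc_te) ** 2))
            errors[m].append(err if np.isfinite(err) else np.inf)
    mean_err = {m: float(np.mean(e)) for m, e in errors.items()}
    # ties (flat curves fit equally by offset-only) break toward interior
    order = ["interior", "increasing", "decreasing"]
    winner = min(order, key=lambda m: mean_err[m])
    yc, xc, _, _ = speed_tuning_curve(activity, covariate, n_bins, binning)
    params, _ = _fit_one_model(xc, yc, bounds[winner], rng)
    degenerate = params[0] < 1e-3 * max(np.ptp(yc), 1e-12) or np.ptp(yc) < 1e-12
    return GaussianModelFit(
        model=winner,
        amplitude=float(params[0]),
        center=float(params[1]),
        width=float(params[2]),
        offset=float(params[3]),
        cv_error=mean_err[winner],
        cv_errors=mean_err,
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# session QC and aggregation

def context_frames(bundle: SessionBundle, context: str = "stimulus") -> np.ndarray:
    """Frame indices of a tuning context.

    ``stimulus`` covers grating presentations, ``spontaneous`` the blank-
    screen blocks.  Inter-stimulus blank frames belong to neither context
    and are always discarded.
    """
    if context == "stimulus":
        types = {"drifting_grating"}
    elif context == "spontaneous":
        types = {"spontaneous"}
    else:
        raise ValueError(f"unknown context {context!r}")
    sel = bundle.stim_table[bundle.stim_table["epoch_type"].isin(types)]
    if not len(sel):
        return np.array([], dtype=int)
    return np.concatenate(
        [np.arange(int(a), int(b)) for a, b in zip(sel["start_frame"], sel["end_frame"])]
    )


def session_qc(
    bundle: SessionBundle,
    min_running_frac: float = 0.25,
    min_max_speed: float = 15.0,
    running_frame_speed: float = 1.0,
) -> bool:
    """Eligibility for tuning analyses: the animal must run for at least a
    quarter of the stimulus period and reach at least 15 cm/s."""
    frames = context_frames(bundle, "stimulus")
    if frames.size == 0:
        return False
    speed = bundle.speed[frames]
    running_frac = np.mean(speed > running_frame_speed)
    return bool(running_frac >= min_running_frac and bundle.speed.max() >= min_max_speed)


def aggregate_region(
    results: Sequence[TuningResult],
    region: str = "",
    layer: str = "",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = ALPHA,
) -> RegionSummary:
    """Fraction of tuned neurons and mean monotonic rho with bootstrap CI.

    "Tuned" is Levene-significant; the mean Spearman rho is taken over the
    monotonically (positively or negatively) classified neurons only, with
    a 95% percentile bootstrap CI over neurons.
    """
    results = list(results)
    if not results:
        raise ValueError("no tuning results to aggregate")
    lev = np.array([r.levene_p for r in results])
    frac_tuned = float(np.mean(lev < alpha))
    rhos = np.array([r.spearman_rho for r in results if r.tclass in ("positive", "negative")])
    if rhos.size == 0:
        mean_rho = ci_lo = ci_hi = float("nan")
    else:
        mean_rho = float(rhos.mean())
        rng = stage_rng(seed, "aggregate", region, layer)
        boots = rng.choice(rhos, size=(n_boot, rhos.size), replace=True).mean(axis=1)
        ci_lo, ci_hi = (float(v) for v in np.percentile(boots, [2.5, 97.5]))
    return RegionSummary(
        region=region,
        layer=layer,
        n_neurons=len(results),
        fraction_tuned=frac_tuned,
        n_monotonic=int(rhos.size),
        mean_rho_monotonic=mean_rho,
        ci_low=ci_lo,
        ci_high=ci_hi,
    )
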