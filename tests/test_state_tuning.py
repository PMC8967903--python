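"""Speed/pupil tuning curves, significance, classification and models."""
import numpy as np
import pytest
from scipy import stats

from helpers import tiny_bundle
from locomod.state_tuning import (
    _levene_one_sided,
    aggregate_region,
    classify_tuning,
    context_frames,
    evaluate_tuning,
    fit_gaussian_speed_models,
    session_qc,
    speed_tuning_curve,
    tuning_significance,
)


class TestTuningCurve:
    def test_identity_activity_gives_monotone_curve(self):
        rng = np.random.default_rng(0)
        cov = rng.normal(10, 3, 5000)
        curve, centers, edges, sem = speed_tuning_curve(cov, cov)
        assert curve.size == 20
        assert np.all(np.diff(curve) > 0)
        assert np.all(np.diff(centers) > 0)
        assert np.allclose(curve, centers)  # mean activity == mean covariate per bin

    def test_constant_activity_gives_flat_curve(self):
        rng = np.random.default_rng(1)
        cov = rng.normal(10, 3, 2000)
        curve, _, _, sem = speed_tuning_curve(np.full(2000, 7.0), cov)
        assert np.allclose(curve, 7.0)
        assert np.allclose(sem, 0.0)

    def test_quantile_bins_have_near_equal_occupancy(self):
        rng = np.random.default_rng(2)
        cov = rng.normal(0, 1, 2000)
        curve, centers, bin_edges, _ = speed_tuning_curve(rng.normal(0, 1, 2000), cov)
        idx = np.clip(np.searchsorted(bin_edges[1:-1], cov, side="right"), 0, 19)
        counts = np.bincount(idx, minlength=20)
        assert counts.max() - counts.min() <= 2

    def test_heavy_ties_merge_bins(self):
        # a large mass at zero speed collapses several quantile edges
        cov = np.concatenate((np.zeros(1500), np.linspace(1, 20, 500)))
        curve, centers, edges, _ = speed_tuning_curve(np.arange(2000.0), cov)
        assert curve.size < 20
        assert curve.size >= 2

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant"):
            speed_tuning_curve(np.arange(100.0), np.full(100, 3.0))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            speed_tuning_curve(np.arange(10.0), np.arange(11.0))

    def test_equal_width_binning(self):
        cov = np.linspace(0, 20, 2000)
        _, _, edges, _ = speed_tuning_curve(cov, cov, binning="equal_width")
        assert np.allclose(np.diff(edges), np.diff(edges)[0])


class TestSignificance:
    def test_levene_matches_scipy(self):
        rng = np.random.default_rng(3)
        real = rng.normal(0, 2, 20)
        perm = rng.normal(0, 1, (5, 20))
        ours = _levene_one_sided(real, perm)
        for k in range(5):
            W, p_two = stats.levene(real, perm[k], center="mean")
            expect = p_two / 2 if real.var(ddof=1) > perm[k].var(ddof=1) else 1 - p_two / 2
            assert ours[k] == pytest.approx(expect, rel=1e-10)

    def test_linear_tuning_detected(self):
        rng = np.random.default_rng(4)
        cov = rng.uniform(0, 25, 4000)
        act = 0.05 * cov + rng.normal(0, 0.01, 4000)
        lp, rho, sp = tuning_significance(act, cov, seed=0)
        assert lp < 0.05
        assert rho > 0.99
        assert sp < 1e-6

    def test_constant_activity_is_never_significant(self):
        rng = np.random.default_rng(5)
        cov = rng.uniform(0, 25, 1000)
        lp, rho, sp = tuning_significance(np.full(1000, 2.0), cov, seed=0)
        assert lp == 1.0
        assert rho == 0.0
        assert sp == 1.0

    def test_false_positive_rate_on_white_noise(self):
        # iid activity has no tuning; the variance test should reject at
        # approximately its nominal 5% level
        rng = np.random.default_rng(6)
        cov = rng.normal(10, 3, 5000)
        hits = 0
        n_neurons = 400
        for j in range(n_neurons):
            act = rng.normal(0, 1, 5000)
            lp, _, _ = tuning_significance(act, cov, seed=10_000 + j)
            hits += lp < 0.05
        assert 0.02 <= hits / n_neurons <= 0.09

    def test_n_perm_validation(self):
        with pytest.raises(ValueError):
            tuning_significance(np.arange(100.0), np.arange(100.0), n_perm=0)


class TestClassifyTuning:
    @pytest.mark.parametrize(
        "lp,rho,sp,expected",
        [
            (0.01, 0.8, 0.01, "positive"),
            (0.20, 0.8, 0.01, "positive"),  # monotone wins regardless of Levene
            (0.01, -0.8, 0.01, "negative"),
            (0.01, 0.3, 0.50, "nonmonotonic"),
            (0.20, 0.3, 0.50, "untuned"),
            # rho == 0 rules out both monotone classes even with a small
            # Spearman p; the significant variance test then takes over
            (0.049, 0.0, 0.049, "nonmonotonic"),
        ],
    )
    def test_decision_table(self, lp, rho, sp, expected):
        assert classify_tuning(lp, rho, sp) == expected

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            classify_tuning(1.5, 0.0, 0.5)

    def test_evaluate_tuning_end_to_end(self):
        rng = np.random.default_rng(7)
        cov = rng.uniform(0, 25, 4000)
        res = evaluate_tuning(-0.05 * cov + rng.normal(0, 0.01, 4000), cov, neuron_id=3)
        assert res.tclass == "negative"
        assert res.neuron_id == 3
        assert res.curve.size == res.bin_centers.size == res.sem.size


@pytest.fixture(scope="module")
def cov():
    return np.random.default_rng(8).uniform(0, 25, 4000)


class TestGaussianModels:
    def test_interior_bump_recovered(self, cov):
        rng = np.random.default_rng(9)
        act = 0.5 * np.exp(-0.5 * ((cov - 12) / 3) ** 2) + rng.normal(0, 0.02, cov.size)
        fit = fit_gaussian_speed_models(act, cov, seed=1)
        assert fit.model == "interior"
        assert abs(fit.center - 12) < 2.0
        assert not fit.degenerate

    def test_monotone_curves_pick_edge_models(self, cov):
        rng = np.random.default_rng(10)
        inc = 0.4 * np.exp(-0.5 * ((cov - 35) / 10) ** 2) + rng.normal(0, 0.02, cov.size)
        dec = 0.4 * np.exp(-0.5 * ((cov + 10) / 10) ** 2) + rng.normal(0, 0.02, cov.size)
        assert fit_gaussian_speed_models(inc, cov, seed=1).model == "increasing"
        assert fit_gaussian_speed_models(dec, cov, seed=1).model == "decreasing"

    def test_flat_curve_flagged_degenerate(self, cov):
        fit = fit_gaussian_speed_models(np.full(cov.size, 0.3), cov, seed=1)
        assert fit.degenerate

    def test_cv_errors_reported_for_all_models(self, cov):
        fit = fit_gaussian_speed_models(np.full(cov.size, 0.3), cov, seed=1)
        assert set(fit.cv_errors) == {"interior", "increasing", "decreasing"}


class TestSessionQC:
    def _bundle(self, speed):
        return tiny_bundle(speed)

    def test_never_runs_excluded(self):
        assert not session_qc(self._bundle(np.zeros(3000)))

    def test_sufficient_running_included(self):
        speed = np.zeros(3000)
        speed[:1000] = 20.0  # 33% of stimulus frames, max 20 cm/s
        assert session_qc(self._bundle(speed))

    def test_slow_running_excluded(self):
        speed = np.zeros(3000)
        speed[:1000] = 10.0  # never reaches 15 cm/s
        assert not session_qc(self._bundle(speed))

    def test_rare_running_excluded(self):
        speed = np.zeros(3000)
        speed[:300] = 20.0  # only 10% of frames
        assert not session_qc(self._bundle(speed))


class TestContextFrames:
    def test_partition(self, gap_bundle):
        stim = context_frames(gap_bundle, "stimulus")
        spont = context_frames(gap_bundle, "spontaneous")
        assert stim.size == 8 * 30 * 60
        assert spont.size == 60 * 30  # 60 s spontaneous block at 30 Hz
        assert np.intersect1d(stim, spont).size == 0
        # blanks belong to neither context
        assert stim.size + spont.size < gap_bundle.n_frames

    def test_unknown_context(self, gap_bundle):
        with pytest.raises(ValueError):
            context_frames(gap_bundle, "blank")


class TestAggregateRegion:
    def test_fractions_and_mean_rho(self):
        from locomod.datatypes import TuningResult

        def tr(lp, rho, sp, tclass):
            z = np.zeros(3)
            return TuningResult(z, z, z, z, lp, rho, sp, tclass)

        results = (
            [tr(0.01, 0.5, 0.01, "positive")] * 4
            + [tr(0.01, -0.5, 0.01, "negative")] * 4
            + [tr(0.5, 0.1, 0.5, "untuned")] * 2
        )
        summary = aggregate_region(results, region="VISp", layer="2/3", seed=0)
        assert summary.n_neurons == 10
        assert summary.fraction_tuned == pytest.approx(0.8)
        assert summary.n_monotonic == 8
        assert summary.mean_rho_monotonic == pytest.approx(0.0)
        assert summary.ci_low <= summary.mean_rho_monotonic <= summary.ci_high

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_region([])

    def test_no_monotonic_gives_nan(self):
        from locomod.datatypes import TuningResult

        z = np.zeros(3)
        summary = aggregate_region([TuningResult(z, z, z, z, 0.5, 0.0, 0.9, "untuned")])
        assert np.isnan(summary.mean_rho_monotonic)


class TestPupilCovariate:
    def test_pupil_tuning_matches_speed_tuning_sign(self, gap_bundle):
        # pupil is a monotone function of (smoothed) speed, so a strongly
        # speed-tuned neuron must show same-signed pupil tuning
        truth = gap_bundle.truth
        ups = np.flatnonzero(truth.neuron_class == "up")
        frames = context_frames(gap_bundle, "stimulus")
        j = int(ups[0])
        act = gap_bundle.dff[j, frames] - 0  # copy not needed; read-only
        r_speed = evaluate_tuning(act, gap_bundle.speed[frames], covariate_name="speed")
        r_pupil = evaluate_tuning(act, gap_bundle.pupil[frames], covariate_name="pupil")
        assert r_speed.spearman_rho > 0
        assert r_pupil.spearman_rho > 0
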