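"""Generator invariants: determinism, bout structure, planted structure."""
import numpy as np
import pytest

from locomod.datatypes import DIRECTIONS, STATE_RUNNING, STATE_STATIONARY
from locomod.preprocess import balance_trials, extract_trial_responses
from locomod.reliability import reliability_records
from locomod.synthgen import (
    BoutParams,
    SessionConfig,
    TEMPORAL_FREQUENCIES,
    generate_session,
    generate_speed_trace,
    sample_ground_truth,
)

UNTUNED_ONLY = {"up": 0.0, "down": 0.0, "nonmono": 0.0, "untuned": 1.0}


class TestSpeedTrace:
    def test_deterministic_given_seed(self):
        a = generate_speed_trace(5000, seed=3)
        b = generate_speed_trace(5000, seed=3)
        c = generate_speed_trace(5000, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_nonnegative(self):
        assert generate_speed_trace(20000, seed=1).min() >= 0.0

    def test_no_running_without_bout_starts(self):
        sp = generate_speed_trace(3000, bout_params=BoutParams(p_start=0.0), seed=2)
        assert np.array_equal(sp, np.zeros(3000))

    def test_equal_rates_give_half_time_running(self):
        # symmetric two-state Markov chain spends half its time in each state
        bp = BoutParams(p_start=1 / 300, p_stop=1 / 300)
        sp = generate_speed_trace(200_000, bout_params=bp, seed=4)
        frac = np.mean(sp > 4.0)  # bout targets are >= 8 cm/s
        assert 0.42 < frac < 0.58

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            generate_speed_trace(0)


class TestSessionStructure:
    def test_deterministic(self):
        cfg = SessionConfig(n_neurons=10, n_reps=5, spont_s=10.0)
        a = generate_session(cfg, seed=7)
        b = generate_session(cfg, seed=7)
        assert np.array_equal(a.dff, b.dff)
        assert np.array_equal(a.speed, b.speed)
        assert a.stim_table.equals(b.stim_table)

    def test_layout(self, gap_bundle):
        t = gap_bundle.stim_table
        gratings = t[t["epoch_type"] == "drifting_grating"]
        n_reps = 30
        assert len(gratings) == 8 * n_reps
        # every direction appears exactly n_reps times
        counts = gratings["direction"].value_counts()
        assert sorted(counts.index) == list(map(float, DIRECTIONS))
        assert (counts == n_reps).all()
        assert set(gratings["temporal_frequency"]).issubset(set(TEMPORAL_FREQUENCIES))
        # 2 s stimulus / 1 s blank at 30 Hz, led by the spontaneous block
        assert ((gratings["end_frame"] - gratings["start_frame"]) == 60).all()
        assert t.iloc[0]["epoch_type"] == "spontaneous"
        assert gap_bundle.n_frames == int(t["end_frame"].iloc[-1])

    def test_behavior_traces_valid(self, gap_bundle):
        assert gap_bundle.speed.min() >= 0.0
        assert gap_bundle.pupil.min() > 0.0
        # pupil tracks smoothed speed
        assert np.corrcoef(gap_bundle.pupil, gap_bundle.speed)[0, 1] > 0.5

    def test_rejects_single_rep(self):
        with pytest.raises(ValueError, match="n_reps"):
            generate_session(SessionConfig(n_reps=1), seed=0)

    def test_truth_rides_along(self, gap_bundle):
        assert gap_bundle.truth is not None
        assert gap_bundle.truth.n_neurons == gap_bundle.n_neurons


class TestGroundTruth:
    def test_proportions_must_sum_to_one(self):
        cfg = SessionConfig(class_props={"up": 0.5, "down": 0.2, "nonmono": 0.0, "untuned": 0.0})
        with pytest.raises(ValueError, match="sum to 1"):
            sample_ground_truth(cfg)

    def test_signs_match_classes(self):
        truth = sample_ground_truth(SessionConfig(n_neurons=300), seed=5)
        assert (truth.speed_gain[truth.neuron_class == "up"] > 0).all()
        assert (truth.speed_gain[truth.neuron_class == "down"] < 0).all()
        assert (truth.speed_gain[truth.neuron_class == "untuned"] == 0).all()

    def test_reliability_gap_flag(self):
        cfg = SessionConfig(n_neurons=200, reliability_gap=False)
        truth = sample_ground_truth(cfg, seed=5)
        assert np.array_equal(truth.noise_sd_running, truth.noise_sd_stationary)
        cfg = SessionConfig(n_neurons=200, reliability_gap=True, frac_state_noise=1.0)
        truth = sample_ground_truth(cfg, seed=5)
        assert (truth.noise_sd_running < truth.noise_sd_stationary).all()


def _mean_offdiag_corr(tm):
    """Mean pairwise neuron correlation of within-cell residuals."""
    res = tm.responses.copy()
    for d in np.unique(tm.class_label):
        for s in (STATE_RUNNING, STATE_STATIONARY):
            i = tm.cell_index(d, s)
            res[i] -= res[i].mean(axis=0)
    C = np.corrcoef(res.T)
    return (C.sum() - np.trace(C)) / (C.size - len(C))


class TestPlantedStatistics:
    def test_shared_gain_induces_noise_correlations(self):
        base = dict(
            n_neurons=40,
            n_reps=30,
            spont_s=30.0,
            class_props=UNTUNED_ONLY,
            stim_offset=0.3,
            dir_amp_median=0.3,
            dir_amp_sigma=0.01,
            noise_sd_stationary=0.1,
            reliability_gap=False,
            frame_noise_sd=0.05,
        )
        with_gain = generate_session(SessionConfig(shared_gain_sd=0.5, **base), seed=17)
        without = generate_session(SessionConfig(shared_gain_sd=0.0, **base), seed=17)
        c1 = _mean_offdiag_corr(balance_trials(extract_trial_responses(with_gain), seed=0))
        c0 = _mean_offdiag_corr(balance_trials(extract_trial_responses(without), seed=0))
        assert c1 > 0.3
        assert abs(c0) < 0.05

    def test_reliability_matches_planted_variances(self):
        # With equal mean responses across states, reliability per state is
        # predicted by the variance decomposition of the planted model:
        # rel = S / (S + N_state), with finite-trial corrections.
        cfg = SessionConfig(
            n_neurons=50,
            n_reps=50,
            spont_s=60.0,
            class_props=UNTUNED_ONLY,
            reliability_gap=True,
            frac_state_noise=1.0,
            noise_sd_stationary=0.3,
            noise_sd_run_mod=0.1,
            shared_gain_sd=0.0,
            dir_amp_median=0.3,
            dir_amp_sigma=0.3,
            stim_offset=0.1,
            frame_noise_sd=0.1,
        )
        b = generate_session(cfg, seed=21)
        tm = balance_trials(extract_trial_responses(b), seed=0)
        T = tm.cell_index(0.0, STATE_RUNNING).size
        recs = reliability_records(tm)
        meas_r = np.array([r.rel_running for r in recs])
        meas_s = np.array([r.rel_stationary for r in recs])

        t = b.truth
        dil = 50.0 / 60.0  # last 10 window frames fall in the blank
        dth = np.deg2rad(DIRECTIONS[None, :] - t.pref_direction[:, None])
        evoked = t.dir_amp[:, None] * np.exp(t.dir_kappa[:, None] * (np.cos(dth) - 1.0))
        mu = dil * (evoked + t.stim_offset[:, None])
        S = mu.var(axis=1)
        frame_var = cfg.frame_noise_sd**2 / 60.0

        def expected(noise_sd):
            N = (dil * noise_sd) ** 2 + frame_var
            return (S + (7 / 8) * N / T) / (S + N * (1 - 1 / (8 * T)))

        exp_r = expected(t.noise_sd_running)
        exp_s = expected(t.noise_sd_stationary)
        assert meas_r.mean() > meas_s.mean() + 0.2
        assert abs(meas_r.mean() - exp_r.mean()) < 0.05
        assert abs(meas_s.mean() - exp_s.mean()) < 0.05
        assert np.corrcoef(meas_r, exp_r)[0, 1] > 0.6
        assert np.corrcoef(meas_s, exp_s)[0, 1] > 0.4

    def test_monotone_up_without_noise_is_increasing(self):
        cfg = SessionConfig(
            n_neurons=3,
            n_reps=10,
            spont_s=30.0,
            class_props={"up": 1.0, "down": 0.0, "nonmono": 0.0, "untuned": 0.0},
            speed_gain=0.02,
            noise_sd_stationary=0.0,
            reliability_gap=False,
            shared_gain_sd=0.0,
            stim_offset=0.0,
            dir_amp_median=1e-9,
            dir_amp_sigma=1e-3,
            frame_noise_sd=0.0,
        )
        b = generate_session(cfg, seed=9)
        # activity is exactly gain * speed (plus a vanishing evoked term)
        assert np.allclose(b.dff[0], 0.02 * b.speed, atol=1e-6)
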