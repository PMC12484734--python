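import numpy as np
import pytest

from pev import responsiveness as rs
from pev import signal_processing as sp
from pev import synthetic_data as sd

from conftest import null_ground_truth, planted_ground_truth

FR = 30.0


def dff_traceset(values):
    return sd.TraceSet(np.atleast_2d(np.asarray(values, dtype=float)), FR, "dff")


class TestShuffleNull:
    def test_flat_trace_gives_all_zero_null(self):
        null = rs.build_shuffle_null(dff_traceset(np.full(600, 0.05)), seed=0)
        assert null.values.shape == (1, 1000)
        assert np.all(null.values == 0.0)

    def test_same_seed_identical(self):
        trace = dff_traceset(np.random.default_rng(1).normal(0, 0.02, 600))
        a = rs.build_shuffle_null(trace, seed=5)
        b = rs.build_shuffle_null(trace, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_white_noise_null_centred_on_zero(self):
        # difference of two 30-frame means of N(0, 0.02) noise: sd ~ 0.0052
        trace = dff_traceset(np.random.default_rng(2).normal(0, 0.02, 6000))
        null = rs.build_shuffle_null(trace, seed=6)
        assert abs(null.values.mean()) < 0.01

    def test_positions_leave_room_for_window_and_baseline(self):
        trace = dff_traceset(np.random.default_rng(3).normal(0, 0.02, (3, 120)))
        null = rs.build_shuffle_null(trace, n_shuffles=200, seed=7)
        assert null.positions.min() >= 30
        assert null.positions.max() <= 120 - 30

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError, match="too short"):
            rs.build_shuffle_null(dff_traceset(np.zeros(59)), seed=0)

    def test_event_window_exclusion(self):
        cfg = sd.SessionConfig("pairing", 3)
        trials = sd.build_trial_table(cfg, seed=0)
        trace = dff_traceset(np.zeros(3 * 240))
        null = rs.build_shuffle_null(
            trace, n_shuffles=500, seed=1, trials=trials, exclude_event_windows=True
        )
        onsets = trials["whisker_onset_frame"].to_numpy()
        for onset in onsets:
            overlap = (null.positions + 30 > onset) & (null.positions < onset + 30)
            assert not overlap.any()


class TestClassifyNeuron:
    def test_complete_separation_positive(self):
        out = rs.classify_neuron(np.full(30, 0.15), np.zeros(1000))
        assert out.label == "responsive_positive"
        assert out.p_value < 1e-10

    def test_sign_symmetry_negative(self):
        out = rs.classify_neuron(np.full(30, -0.15), np.zeros(1000))
        assert out.label == "responsive_negative"

    def test_all_tied_degenerate_returns_not_responsive(self):
        out = rs.classify_neuron(np.zeros(10), np.zeros(1000))
        assert out.label == "not_responsive"
        assert out.p_value == 1.0

    def test_minimum_trial_floor(self):
        with pytest.raises(ValueError, match=">= 5"):
            rs.classify_neuron(np.zeros(3), np.zeros(100))

    def test_small_samples_use_exact_test(self):
        # 6 + 10 observations < 25: exact Mann-Whitney null, p bounded below
        out = rs.classify_neuron(np.full(6, 1.0) + np.arange(6) * 0.01,
                                 np.arange(10) * 0.001)
        assert out.p_value == pytest.approx(2 / 8008, rel=1e-6)  # 2/C(16,6)


def test_classifier_type_one_error_near_alpha():
    """Null neurons classified against their own trace's shuffle null are
    called (positively) responsive at roughly alpha (alpha/2)."""
    cfg = sd.SessionConfig("pairing", 30)
    raw, trials, _ = sd.generate_session(
        cfg, ground_truth=null_ground_truth(400), noise_sd=0.02, seed=11
    )
    dff = sp.compute_dff(raw, trials)
    rm = sp.trial_response(dff, trials)
    null = rs.build_shuffle_null(dff, seed=12)
    cls = rs.classify_matrix(rm.values, null.values)
    rate = (cls["label"] != "not_responsive").mean()
    pos = (cls["label"] == "responsive_positive").mean()
    assert 0.01 < rate < 0.10  # ~ alpha = 0.05
    assert pos < 0.06  # ~ alpha / 2


@pytest.fixture(scope="module")
def experiment():
    gt = planted_ground_truth(
        [("mismatch_responsive_s1", 0.10)] * 3
        + [("mismatch_responsive_both", 0.10)]
        + [("null", 0.0)] * 8
    )
    configs = sd.default_session_configs(n_pairing_trials=40, n_interleaved_trials=60)
    rng = np.random.default_rng(21)
    sessions = {}
    for cfg in configs:
        raw, trials, _ = sd.generate_session(cfg, ground_truth=gt, noise_sd=0.01, seed=rng)
        sessions[cfg.session_kind] = (sp.compute_dff(raw, trials), trials)
    dff_by = {k: v[0] for k, v in sessions.items()}
    trials_by = {k: v[1] for k, v in sessions.items()}
    labels = rs.session_classification(dff_by, trials_by, seed=22)
    return gt, labels


class TestSessionClassification:
    def test_planted_mismatch_neurons_found_in_their_session(self, experiment):
        gt, labels = experiment
        planted = set(gt.loc[gt["class_label"] == "mismatch_responsive_s1", "neuron_id"])
        found = set(rs.mismatch_responsive_ids(labels, "interleaved1"))
        assert planted <= found

    def test_null_neurons_mostly_unlabelled(self, experiment):
        gt, labels = experiment
        nulls = set(gt.loc[gt["class_label"] == "null", "neuron_id"])
        positives = set(
            labels.loc[labels["label"] == "responsive_positive", "neuron_id"]
        )
        # 8 null neurons x 5 tests at alpha/2 = 2.5%: ~1 false positive
        # expected; 5+ has binomial probability < 1%
        assert len(nulls & positives) <= 4

    def test_both_session_neuron_flagged_overlapping(self, experiment):
        gt, labels = experiment
        both = gt.loc[gt["class_label"] == "mismatch_responsive_both", "neuron_id"].iloc[0]
        flagged = labels.loc[labels["overlapping"], "neuron_id"].unique()
        assert both in flagged

    def test_missing_trial_table_errors(self, experiment):
        gt, _ = experiment
        dff = dff_traceset(np.zeros((2, 240)))
        with pytest.raises(KeyError, match="interleaved1"):
            rs.session_classification({"interleaved1": dff}, {}, seed=0)


class TestShuffledPopulationCI:
    def test_all_zero_nulls_give_zero_interval(self):
        lo, hi = rs.shuffled_population_ci(np.zeros((50, 100)), 0.1, seed=0)
        assert (lo, hi) == (0.0, 0.0)

    def test_symmetric_null_brackets_zero(self):
        nulls = np.random.default_rng(5).normal(0, 0.01, (100, 1000))
        lo, hi = rs.shuffled_population_ci(nulls, (0.08, 0.12), seed=1)
        assert lo < 0 < hi

    def test_planted_population_mean_outside_noise_ci(self):
        nulls = np.random.default_rng(6).normal(0, 0.01, (100, 1000))
        lo, hi = rs.shuffled_population_ci(nulls, (0.08, 0.12), seed=2)
        assert 0.05 > hi  # planted mismatch mean of 0.05 dF/F lies outside

    def test_fraction_validation(self):
        nulls = np.zeros((20, 10))
        with pytest.raises(ValueError, match="fraction"):
            rs.shuffled_population_ci(nulls, 0.0)
        with pytest.raises(ValueError, match="fraction"):
            rs.shuffled_population_ci(nulls, 1.5)

    def test_coverage_of_null_population_means(self):
        """~95% of random null sub-population means fall inside the CI."""
        rng = np.random.default_rng(7)
        nulls = rng.normal(0, 0.01, (200, 500))
        lo, hi = rs.shuffled_population_ci(nulls, 0.1, n_draws=2000, seed=3)
        inside = 0
        for _ in range(400):
            idx = rng.choice(200, 20, replace=False)
            m = nulls[idx, rng.integers(0, 500, 20)].mean()
            inside += lo <= m <= hi
        assert 0.88 < inside / 400 <= 1.0
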