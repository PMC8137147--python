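import numpy as np
import pandas as pd
import pytest

from choicelab import cohort, task
from choicelab.cohort import (AgentParams, CohortConfig, LearningTrajectory,
                              agent_choice_prob, calibrate_visual_weights,
                              default_agent, sample_session_length,
                              sample_trial_duration, simulate_cohort,
                              simulate_session, simulate_training_course)
from choicelab.psychometrics import (PsychometricParams, fit_psychometric_trials,
                                     psych_eval)


class TestCalibration:
    def test_symmetric_target_logit_arithmetic(self):
        # P(+100) = 0.95, P(-100) = 0.05: W_100 = logit(0.95), W_0 = 0
        target = PsychometricParams(0.05, 0.05, 0.0, 10.0)
        weights, w0 = calibrate_visual_weights(target, [100.0])
        assert weights[100.0] == pytest.approx(np.log(0.95 / 0.05), abs=1e-3)
        assert w0 == pytest.approx(0.0, abs=1e-6)

    def test_zero_contrast_gets_no_weight(self):
        weights, _ = calibrate_visual_weights(cohort.DEFAULT_ASYMPTOTE,
                                              task.ALL_CONTRASTS)
        assert 0.0 not in weights

    def test_round_trip_choice_fractions(self, rng):
        """History-free agent from calibrated weights reproduces the target."""
        # symmetric target: the averaged bias term is exact per contrast
        target = PsychometricParams(0.05, 0.05, 0.0, 16.0)
        weights, w0 = calibrate_visual_weights(target, [6.25, 12.5, 25, 50, 100])
        agent = AgentParams(visual_weights=weights, w_rewarded=0.0,
                            w_unrewarded=0.0, w_bias=w0)
        n = 20_000
        for c in (-100, -25, -6.25, 6.25, 25, 100):
            p = agent_choice_prob(agent, c, None)
            frac = rng.binomial(n, p) / n
            expected = psych_eval(target, c)
            assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / n) + 0.01

    def test_only_nonzero_magnitudes_required(self):
        with pytest.raises(ValueError):
            calibrate_visual_weights(cohort.DEFAULT_ASYMPTOTE, [0.0])


class TestChoiceProb:
    def test_neutral_everything_is_half(self):
        agent = AgentParams(visual_weights={100.0: 0.0}, w_rewarded=0.0,
                            w_unrewarded=0.0, w_bias=0.0)
        assert agent_choice_prob(agent, 100.0, None) == pytest.approx(0.5)

    def test_direct_logistic_evaluation(self):
        from collections import namedtuple
        Prev = namedtuple("Prev", "signed_contrast stim_side choice correct")
        agent = AgentParams(visual_weights={100.0: 3.0}, w_rewarded=0.42,
                            w_unrewarded=0.0, w_bias=0.0)
        prev = Prev(100.0, 1, 1, 1)  # rewarded rightward choice
        p = agent_choice_prob(agent, 100.0, prev)
        assert p == pytest.approx(1 / (1 + np.exp(-3.42)), abs=1e-9)

    def test_odd_symmetry_without_bias(self):
        agent = AgentParams(visual_weights={25.0: 1.3}, w_rewarded=0.2,
                            w_unrewarded=0.3, w_bias=0.0)
        assert agent_choice_prob(agent, 25.0, None) + \
            agent_choice_prob(agent, -25.0, None) == pytest.approx(1.0)

    def test_block_label_contribution(self):
        agent = AgentParams(visual_weights={100.0: 0.0}, w_rewarded=0.0,
                            w_unrewarded=0.0, w_bias=0.0, w_block=0.5)
        assert agent_choice_prob(agent, 0.0, None, 1) == \
            pytest.approx(1 / (1 + np.exp(-0.5)))


class TestDurations:
    def test_median_near_default(self, rng):
        d = sample_trial_duration(rng, size=100_000)
        assert np.median(d) == pytest.approx(0.468, rel=0.02)

    def test_floor(self, rng):
        d = sample_trial_duration(rng, median=0.06, sigma=2.0, size=10_000)
        assert d.min() >= 0.05

    def test_zero_dispersion_constant(self, rng):
        d = sample_trial_duration(rng, sigma=0.0, size=100)
        assert np.allclose(d, 0.468)


class TestSessionLength:
    def test_truncated_normal_moments(self, rng):
        n = np.array([sample_session_length(rng) for _ in range(5000)])
        assert n.mean() == pytest.approx(719, abs=25)
        assert n.std() == pytest.approx(223, abs=30)
        assert n.min() >= 50 and n.max() <= 1400


class TestSimulateSession:
    def test_saturated_agent_accuracy_on_easy(self, trained_stage, rng):
        agent = AgentParams(
            visual_weights={m: 40.0 for m in (6.25, 12.5, 25.0, 50.0, 100.0)},
            w_rewarded=0.0, w_unrewarded=0.0, w_bias=0.0)
        sched = task.build_session_schedule("basic", 1500, rng)
        trials = simulate_session(agent, trained_stage, sched, rng,
                                  n_trials=1500)
        easy = trials[np.abs(trials["signed_contrast"]) >= 50]
        assert easy["correct"].mean() > 0.99

    def test_psychometric_refit_consistency(self, basic_trials, basic_agent):
        """Simulate-then-refit recovers the generative asymptote."""
        fit = fit_psychometric_trials(basic_trials).params
        target = cohort.DEFAULT_ASYMPTOTE
        assert abs(fit.mu - target.mu) < 2.0
        assert abs(fit.sigma - target.sigma) < 3.0
        assert abs(fit.gamma - target.gamma) < 0.03
        assert abs(fit.lambda_ - target.lambda_) < 0.03

    def test_zero_contrast_reward_follows_block_prior(self, trained_stage):
        rng = np.random.default_rng(0)
        agent = default_agent("full")
        sched = task.build_session_schedule("full", 3000, rng)
        trials = simulate_session(agent, trained_stage, sched, rng,
                                  variant="full", n_trials=3000)
        zero = trials[(trials["signed_contrast"] == 0)
                      & (trials["block_p_left"] == 0.2)]
        # hidden correct side is right 80% of the time in 20:80 blocks:
        # a right choice on those trials is rewarded at ~0.8
        right = zero[zero["choice"] == 1]
        assert right["correct"].mean() == pytest.approx(0.8, abs=0.08)


class TestMechanisticMode:
    def test_session_ends_by_rules_not_budget(self, basic_agent, trained_stage):
        rng = np.random.default_rng(2)
        sched = task.build_session_schedule("basic", 5000, rng)
        fast = simulate_session(basic_agent, trained_stage, sched, rng,
                                use_session_rules=True)
        slow = simulate_session(basic_agent, trained_stage, sched, rng,
                                use_session_rules=True, duration_median=3.0,
                                duration_sigma=1.5)
        # a slow responder hits the low-count / slowdown rules much earlier
        assert len(slow) < len(fast)
        assert len(fast) < 5000


class TestTrainingCourse:
    def test_instant_learner_minimum_three_days(self):
        rng = np.random.default_rng(5)
        traj = LearningTrajectory(rate=1e-9, initial_scale=0.2,
                                  asymptote_params=cohort.DEFAULT_ASYMPTOTE)
        out = simulate_training_course(traj, rng, 10)
        assert out["status"] == "trained_1a"
        assert out["days_to_proficiency"] == 3

    def test_non_learner_flagged_at_day_40(self):
        rng = np.random.default_rng(5)
        traj = LearningTrajectory(rate=1e9, initial_scale=0.1,
                                  asymptote_params=cohort.DEFAULT_ASYMPTOTE)
        out = simulate_training_course(traj, rng, 40)
        assert out["status"] == "not_trained"
        assert out["days_to_proficiency"] is None

    def test_learning_scale_monotone(self):
        traj = LearningTrajectory(rate=1000.0, initial_scale=0.2,
                                  asymptote_params=cohort.DEFAULT_ASYMPTOTE)
        t = np.linspace(0, 20_000, 200)
        s = np.array([traj.scale_at(x) for x in t])
        assert (np.diff(s) >= -1e-12).all()
        assert s[0] == pytest.approx(0.2)

    def test_invalid_trajectory_rejected(self):
        with pytest.raises(ValueError):
            LearningTrajectory(rate=-1.0, initial_scale=0.1,
                               asymptote_params=cohort.DEFAULT_ASYMPTOTE)
        with pytest.raises(ValueError):
            LearningTrajectory(rate=100.0, initial_scale=1.0,
                               asymptote_params=cohort.DEFAULT_ASYMPTOTE)


class TestSimulateCohort:
    def test_default_lab_count_is_seven(self):
        assert CohortConfig().n_labs == 7

    def test_seed_determinism(self):
        cfg = CohortConfig(n_labs=2, n_mice_per_lab=2, mode="trained_only")
        a = simulate_cohort(cfg, np.random.default_rng(7))
        b = simulate_cohort(cfg, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(CohortConfig(n_labs=1, n_mice_per_lab=5),
                            np.random.default_rng(0))

    def test_timezone_groups_sizes(self):
        cfg = CohortConfig(n_labs=7, n_mice_per_lab=2, mode="trained_only")
        data = simulate_cohort(cfg, np.random.default_rng(0))
        tz = pd.Series([l.timezone_group for l in data.labs]).value_counts()
        assert sorted(tz.values) == [2, 2, 3]

    def test_asymptotes_share_one_distribution_across_labs(self):
        """Lab identity only enters through learning speed."""
        cfg = CohortConfig(n_labs=4, n_mice_per_lab=30, mode="trained_only")
        data = simulate_cohort(cfg, np.random.default_rng(3))
        mus = {}
        for m, gt in data.ground_truth.items():
            mus.setdefault(gt["lab_id"], []).append(
                gt["trajectory"].asymptote_params.mu)
        from scipy.stats import kruskal
        assert kruskal(*mus.values()).pvalue > 0.01

    def test_lab_learning_rates_differ(self):
        cfg = CohortConfig(n_labs=3, n_mice_per_lab=25, mode="trained_only",
                           lab_tau_means=(800.0, 3000.0, 9000.0))
        data = simulate_cohort(cfg, np.random.default_rng(3))
        days = {}
        for m, st in data.statuses.items():
            if st["days_to_proficiency"] is not None:
                days.setdefault(data.ground_truth[m]["lab_id"], []).append(
                    st["days_to_proficiency"])
        from scipy.stats import kruskal
        assert kruskal(*days.values()).pvalue < 0.001
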