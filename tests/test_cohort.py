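"""Synthetic cohort generator: agent behavior, scheduler, outcomes."""

import math

import numpy as np
import pytest

import rbdkit as rk
from rbdkit import cohort


class TestSimulateSession:
    def test_fixed_seed_determinism(self):
        agent = rk.AgentParams()
        sched = rk.ScheduleConfig()
        a = rk.simulate_session(agent, sched, seed=99)
        b = rk.simulate_session(agent, sched, seed=99)
        assert a.trials == b.trials

    def test_structure(self):
        sess = rk.simulate_session(rk.AgentParams(), rk.ScheduleConfig(), seed=1)
        assert len(sess.trials) == 200
        assert len(sess.block_trials(1)) == 100
        assert len(sess.block_trials(2)) == 100

    def test_near_perfect_agent_accuracy_and_reward_ratio(self):
        # d' = 10 proxy for perfect discrimination over 10,000 trials
        sched = rk.ScheduleConfig(trials_per_block=5000,
                                  target_rich_rewards_per_block=1500,
                                  target_lean_rewards_per_block=500)
        agent = rk.AgentParams(d_prime=10.0, lapse_rate=0.0, engagement=0.0)
        sess = rk.simulate_session(agent, sched, seed=17)
        n_correct = sum(t.correct for t in sess.trials)
        assert n_correct / len(sess.trials) > 0.999
        rich_rewards = sum(t.rewarded for t in sess.trials if t.stimulus == "rich")
        lean_rewards = sum(t.rewarded for t in sess.trials if t.stimulus == "lean")
        assert rich_rewards / lean_rewards == pytest.approx(3.0, rel=0.05)

    def test_rewards_never_exceed_targets_and_imply_correct(self):
        sched = rk.ScheduleConfig()
        for seed in range(10):
            sess = rk.simulate_session(rk.AgentParams(d_prime=0.8,
                                                      lapse_rate=0.1),
                                       sched, seed=seed)
            for block in (1, 2):
                trials = sess.block_trials(block)
                assert all(t.correct for t in trials if t.rewarded)
                rich = sum(t.rewarded for t in trials if t.stimulus == "rich")
                lean = sum(t.rewarded for t in trials if t.stimulus == "lean")
                assert rich <= sched.target_rich_rewards_per_block
                assert lean <= sched.target_lean_rewards_per_block

    def test_engagement_raises_block2_bias(self):
        sched = rk.ScheduleConfig()
        means = {}
        for eng in (0.0, 1.0):
            agent = rk.AgentParams(d_prime=1.8, lapse_rate=0.0, engagement=eng)
            vals = []
            for seed in range(300):
                sess = rk.simulate_session(agent, sched, seed=seed)
                b2 = rk.tabulate_blocks(sess)[1]
                vals.append(rk.response_bias(b2))
            means[eng] = np.mean(vals)
        assert means[1.0] > means[0.0]

    def test_block2_bias_nondecreasing_in_engagement(self):
        sched = rk.ScheduleConfig()
        means = []
        for eng in (0.0, 0.5, 1.0):
            agent = rk.AgentParams(d_prime=1.8, lapse_rate=0.0, engagement=eng)
            vals = [rk.response_bias(rk.tabulate_blocks(
                rk.simulate_session(agent, sched, seed=s))[1])
                for s in range(150)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_impossible_schedule_config_error(self):
        with pytest.raises(cohort.ConfigError):
            rk.ScheduleConfig(trials_per_block=40,
                              target_rich_rewards_per_block=30,
                              target_lean_rewards_per_block=10)


class TestSimulateCohort:
    def test_sizes_and_phenotype_mixture(self):
        counts = []
        for seed in range(8):
            cfg = rk.CohortConfig(n_mdd=195, n_hc=40, rng_seed=seed)
            sessions, demo = rk.simulate_cohort(cfg)
            assert len(sessions) == 235
            mdd = demo[demo["group"] == "MDD"]
            counts.append((mdd["true_phenotype"] == "disengaged").sum())
            assert set(demo[demo["group"] == "HC"]["true_phenotype"]) == {"engaged"}
        mean_frac = np.mean(counts) / 195
        # Binomial(195, 0.3): SE of the mean over 8 seeds ~ 0.0116
        assert abs(mean_frac - 0.30) < 4 * math.sqrt(0.3 * 0.7 / (195 * 8))

    def test_zero_fraction_all_engaged(self):
        cfg = rk.CohortConfig(n_mdd=30, n_hc=5, mdd_disengaged_fraction=0.0,
                              rng_seed=3)
        _, demo = rk.simulate_cohort(cfg)
        assert (demo["true_phenotype"] == "engaged").all()

    def test_different_seeds_differ_same_hash(self):
        c1 = rk.CohortConfig(n_mdd=5, n_hc=2, rng_seed=1)
        c2 = rk.CohortConfig(n_mdd=5, n_hc=2, rng_seed=2)
        s1, _ = rk.simulate_cohort(c1)
        s2, _ = rk.simulate_cohort(c2)
        assert s1[0].trials != s2[0].trials
        # hash covers structural parameters, not the seed-dependent draws
        h1 = cohort.config_hash(rk.ScheduleConfig())
        h2 = cohort.config_hash(rk.ScheduleConfig())
        assert h1 == h2

    def test_treatment_randomized_within_mdd(self, small_cohort):
        _, _, demo = small_cohort
        mdd = demo[demo["group"] == "MDD"]
        assert set(mdd["treatment"]) == {"sertraline", "placebo"}
        assert abs((mdd["treatment"] == "sertraline").sum()
                   - len(mdd) / 2) <= 1
        assert (demo.loc[demo["group"] == "HC", "treatment"] == "").all()


class TestSimulateOutcomes:
    def test_noise_free_trajectories_follow_cell_means(self, small_cohort):
        _, _, demo = small_cohort
        params = rk.OutcomeGenParams(baseline_sd=0.0, random_intercept_sd=0.0,
                                     residual_sd=0.0,
                                     missing_visit_probability=0.0)
        visits = rk.simulate_outcomes(demo, params, seed=0)
        by_subject = {}
        for v in visits:
            by_subject.setdefault(v.subject_id, {})[v.week] = v.hamd17
        demo_idx = demo.set_index("subject_id")
        for sid, traj in by_subject.items():
            phen = demo_idx.loc[sid, "true_phenotype"]
            treat = demo_idx.loc[sid, "treatment"]
            slope = params.slopes[(phen, treat)]
            for week, val in traj.items():
                expect = params.baseline_mean + (
                    slope * math.log(week) if week > 0 else 0.0)
                assert val == round(np.clip(expect, 0, 52))

    def test_week_grid_and_missingness(self, small_cohort):
        _, _, demo = small_cohort
        params = rk.OutcomeGenParams(missing_visit_probability=0.0)
        visits = rk.simulate_outcomes(demo, params, seed=1)
        n_treated = (demo["treatment"] != "").sum()
        assert len(visits) == n_treated * 7
        weeks = {v.week for v in visits}
        assert weeks == {0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0}
        assert all(0 <= v.hamd17 <= 52 for v in visits)
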