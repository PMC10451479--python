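"""QDA cutoff derivation, classification rule, and comparison statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rbdkit as rk
from rbdkit import classifier


def grid_cutoff(model: rk.EngagementModel, lo=-50.0, hi=50.0, n=100_000):
    """Dense-grid oracle: first upward crossing of the class posterior
    at or above the healthy-control mean."""
    x = np.linspace(lo, hi, n)
    g = model.discriminant(x)
    crossings = np.flatnonzero((g[:-1] <= 0) & (g[1:] > 0))
    cands = [x[i] for i in crossings if x[i + 1] >= model.mean_hc]
    return cands[0] if cands else None


class TestQDAFit:
    def test_equal_variance_reduces_to_midpoint(self):
        rng = np.random.default_rng(0)
        hc = rng.normal(4.0, 1.0, 4000)
        mdd = rng.normal(6.0, 1.0, 4000)
        model = rk.fit_qda_1d(mdd, hc, priors=(0.5, 0.5))
        assert model.cutoff == pytest.approx(5.0, abs=0.1)

    def test_quadratic_root_oracle(self):
        roots = classifier._boundary_roots(4.6, 0.3, 4.9, 0.9, 0.5, 0.5)
        assert roots == pytest.approx((4.0776, 5.0474), abs=1e-3)
        # polynomial check: 8x^2 - 73x + 164.6503 = 0 (x 1.62 rescaling)
        for r in roots:
            assert 8 * r**2 - 73 * r + 164.6503 == pytest.approx(0.0, abs=1e-3)

    def test_cutoff_is_upper_root_above_hc_mean(self):
        rng = np.random.default_rng(3)
        hc = rng.normal(4.6, 0.3, 2000)
        mdd = rng.normal(4.9, 0.9, 2000)
        model = rk.fit_qda_1d(mdd, hc, priors=(0.5, 0.5))
        assert model.cutoff == max(model.roots)
        assert model.cutoff > model.mean_hc
        assert model.cutoff == pytest.approx(5.0474, abs=0.1)

    def test_grid_oracle_agreement(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            mu_hc = rng.uniform(2, 6)
            sd_hc = rng.uniform(0.2, 0.8)
            mu_mdd = mu_hc + rng.uniform(0.1, 1.5)
            sd_mdd = sd_hc * rng.uniform(1.5, 4.0)
            pri = rng.uniform(0.2, 0.8)
            model = rk.EngagementModel(
                mean_hc=mu_hc, sd_hc=sd_hc, mean_mdd=mu_mdd, sd_mdd=sd_mdd,
                prior_hc=pri, prior_mdd=1 - pri,
                cutoff=classifier._select_cutoff(
                    classifier._boundary_roots(mu_hc, sd_hc, mu_mdd, sd_mdd,
                                               pri, 1 - pri),
                    mu_hc, sd_hc, mu_mdd, sd_mdd, pri, 1 - pri),
                roots=classifier._boundary_roots(mu_hc, sd_hc, mu_mdd, sd_mdd,
                                                 pri, 1 - pri))
            oracle = grid_cutoff(model)
            assert oracle is not None
            assert abs(model.cutoff - oracle) < 100.0 / 100_000 * 2

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        hc = rng.normal(4.6, 0.3, 500)
        mdd = rng.normal(4.9, 0.9, 500)
        m0 = rk.fit_qda_1d(mdd, hc)
        m1 = rk.fit_qda_1d(mdd + 10.0, hc + 10.0)
        assert m1.cutoff == pytest.approx(m0.cutoff + 10.0, abs=1e-8)
        assert rk.classify(mdd + 10.0, m1) == rk.classify(mdd, m0)

    def test_degenerate_inputs(self):
        with pytest.raises(classifier.DegenerateModelError):
            rk.fit_qda_1d([1.0, 1.0, 1.0], [2.0, 2.1, 2.2])
        with pytest.raises(classifier.DegenerateModelError):
            rk.fit_qda_1d([1.0], [2.0, 2.1])
        same = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(classifier.DegenerateModelError):
            rk.fit_qda_1d(same, same, priors=(0.5, 0.5))


class TestClassify:
    def test_boundary_tie_goes_disengaged(self):
        rng = np.random.default_rng(2)
        model = rk.fit_qda_1d(rng.normal(5, 1, 100), rng.normal(4, 0.5, 100))
        assert rk.classify([model.cutoff], model) == [classifier.DISENGAGED]
        assert rk.classify([model.cutoff - 1e-9], model) == [classifier.ENGAGED]

    def test_value_below_both_roots_engaged(self):
        rng = np.random.default_rng(2)
        hc = rng.normal(4.6, 0.3, 2000)
        mdd = rng.normal(4.9, 0.9, 2000)
        model = rk.fit_qda_1d(mdd, hc, priors=(0.5, 0.5))
        below = min(model.roots) - 1.0
        assert rk.classify([below], model) == [classifier.ENGAGED]

    def test_well_separated_two_phenotype_accuracy(self):
        # disengaged mode far enough out that even the single-Gaussian fit
        # to the bimodal depressed mixture leaves < 5% in the overlap
        rng = np.random.default_rng(9)
        hc = rng.normal(0.0, 1.0, 200)
        engaged = rng.normal(0.0, 1.0, 350)
        disengaged = rng.normal(8.0, 1.5, 150)
        model = rk.fit_qda_1d(np.concatenate([engaged, disengaged]), hc,
                              priors=(0.5, 0.5))
        labels = rk.classify(np.concatenate([engaged, disengaged]), model)
        truth = ["engaged"] * 350 + ["disengaged"] * 150
        acc = np.mean([l == t for l, t in zip(labels, truth)])
        assert acc > 0.95


class TestDiagnostics:
    def test_perfect_classifier(self):
        stats_ = rk.diagnostic_stats(
            ["disengaged"] * 5 + ["engaged"] * 3,
            ["MDD"] * 5 + ["HC"] * 3)
        assert stats_.sensitivity == 1.0 and stats_.specificity == 1.0

    def test_confusion_arithmetic(self):
        labels = (["disengaged"] * 9 + ["engaged"] * 1
                  + ["engaged"] * 8 + ["disengaged"] * 2)
        truth = ["MDD"] * 10 + ["HC"] * 10
        d = rk.diagnostic_stats(labels, truth)
        assert d.sensitivity == pytest.approx(0.9)
        assert d.specificity == pytest.approx(0.8)
        assert (d.tp, d.fn, d.tn, d.fp) == (9, 1, 8, 2)
        for ci, point in ((d.sensitivity_ci, 0.9), (d.specificity_ci, 0.8)):
            assert ci[0] <= point <= ci[1]

    def test_all_positive_classifier(self):
        d = rk.diagnostic_stats(["disengaged"] * 8, ["MDD"] * 5 + ["HC"] * 3)
        assert d.sensitivity == 1.0 and d.specificity == 0.0

    def test_empty_group_error(self):
        with pytest.raises(classifier.DegenerateTableError):
            rk.diagnostic_stats(["disengaged"] * 3, ["MDD"] * 3)


class TestChiSquare:
    @given(st.lists(st.lists(st.integers(1, 200), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
        lambda rows: len({len(r) for r in rows}) == 1))
    @settings(deadline=None, max_examples=60)
    def test_matches_direct_summation_oracle(self, rows):
        obs = np.array(rows, dtype=float)
        total = obs.sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        oracle = ((obs - expected) ** 2 / expected).sum()
        stat, df, p = rk.chisq_independence(obs)
        assert stat == pytest.approx(oracle, rel=1e-10)
        assert df == (obs.shape[0] - 1) * (obs.shape[1] - 1)

    def test_proportional_rows_give_zero(self):
        assert rk.chisq_independence([[10, 20], [30, 60]])[0] == pytest.approx(0.0)

    def test_degenerate_table(self):
        with pytest.raises(classifier.DegenerateTableError):
            rk.chisq_independence([[0, 0], [5, 5]])
        with pytest.raises(classifier.DegenerateTableError):
            rk.chisq_independence([[5, 5]])


class TestCochranCox:
    def test_identical_samples_zero(self):
        r = rk.cochran_cox_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p_cochran_cox == pytest.approx(1.0)

    def test_equal_n_equal_variance_reduces_to_pooled(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 3.0, 4.0, 5.0]
        r = rk.cochran_cox_ttest(x, y)
        pooled = stats.ttest_ind(x, y, equal_var=True)
        assert r.t == pytest.approx(pooled.statistic)

    def test_hand_oracle(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 4, 6, 8, 10, 12.0])
        wx, wy = x.var(ddof=1) / 5, y.var(ddof=1) / 6
        t_oracle = (x.mean() - y.mean()) / math.sqrt(wx + wy)
        df_oracle = (wx + wy) ** 2 / (wx**2 / 4 + wy**2 / 5)
        r = rk.cochran_cox_ttest(x, y)
        assert r.t == pytest.approx(t_oracle)
        assert r.df_satterthwaite == pytest.approx(df_oracle)
        # Cochran-Cox p: |t| equals the weighted critical value at that level
        alpha = r.p_cochran_cox
        ta = stats.t.isf(alpha / 2, 4)
        tb = stats.t.isf(alpha / 2, 5)
        assert abs(r.t) == pytest.approx((wx * ta + wy * tb) / (wx + wy), abs=1e-8)

    def test_zero_variance_error(self):
        with pytest.raises(classifier.DegenerateModelError):
            rk.cochran_cox_ttest([1.0, 1.0], [1.0, 1.0])


class TestCompareGroups:
    def test_report_structure(self, small_cohort):
        _, _, demographics = small_cohort
        demo = demographics[demographics["group"] == "MDD"]
        rng = np.random.default_rng(0)
        labels = rng.choice(["engaged", "disengaged"], size=len(demo))
        comps = rk.compare_groups(demo, labels)
        table = classifier.comparison_table(comps)
        assert set(table["test"]) == {"chi2", "cochran_cox_t"}
        cont = {c.feature for c in comps if c.kind == "continuous"}
        assert {"age", "hamd17_baseline", "qids_sr", "shaps"} <= cont
        assert np.isfinite(table["p"]).all()

    def test_single_category_feature_degenerate(self, small_cohort):
        _, _, demographics = small_cohort
        demo = demographics[demographics["group"] == "MDD"].copy()
        demo["sex"] = "female"
        labels = ["engaged", "disengaged"] * (len(demo) // 2 + 1)
        with pytest.raises(classifier.DegenerateTableError):
            rk.compare_groups(demo, labels[:len(demo)], features=["sex"])

    def test_unknown_feature(self, small_cohort):
        _, _, demographics = small_cohort
        demo = demographics[demographics["group"] == "MDD"]
        with pytest.raises(KeyError):
            rk.compare_groups(demo, ["engaged"] * len(demo),
                              features=["shoe_size"])

    def test_null_association_type_i_rate(self):
        # independent labels => about 5% of features significant at 0.05
        rng = np.random.default_rng(21)
        cfg = rk.CohortConfig(n_mdd=120, n_hc=0, rng_seed=13)
        _, demo = rk.simulate_cohort(cfg)
        demo = demo[demo["group"] == "MDD"]
        pvals = []
        for _ in range(40):
            labels = rng.choice(["engaged", "disengaged"], size=len(demo),
                                p=[0.7, 0.3])
            comps = rk.compare_groups(demo, labels)
            pvals.extend(c.p for c in comps)
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.0 <= rate < 0.12
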