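"""Diagnostic-statistics battery against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from coroflow import diagstats as ds


class TestConfusionAndPerformance:
    def test_all_correct_has_no_errors(self):
        cm = ds.confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 0, 0, 2)

    def test_inverted_predictions_have_no_hits(self):
        cm = ds.confusion([0, 0, 1, 1], [1, 1, 0, 0])
        assert cm.tp == 0 and cm.tn == 0

    def test_hand_tallied_six_items(self):
        pred = [1, 1, 0, 1, 0, 0]
        truth = [1, 0, 1, 1, 0, 1]
        # brute-force tally: TP pairs (1,1): idx 0,3; FP: idx 1; FN: idx 2,5; TN: idx 4
        cm = ds.confusion(pred, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 2, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ds.DiagStatsError):
            ds.confusion([1, 0], [1])

    def test_perfect_classifier_metrics_all_one(self):
        perf = ds.performance(ds.ConfusionMatrix(tp=50, fp=0, fn=0, tn=50))
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            m = getattr(perf, name)
            assert m.estimate == 1.0 and m.hi == 1.0

    def test_clopper_pearson_96_of_100(self):
        # incomplete-beta oracle evaluated independently
        lo = sps.beta.ppf(0.025, 96, 5)
        hi = sps.beta.ppf(0.975, 97, 4)
        m = ds._cp_interval(96, 100)
        assert np.isclose(m.lo, lo) and np.isclose(m.hi, hi)
        assert 0.900 < m.lo < 0.902 and 0.988 < m.hi < 0.990

    def test_symmetric_matrix_gives_equal_se_sp(self):
        perf = ds.performance(ds.ConfusionMatrix(tp=30, fp=7, fn=7, tn=30))
        assert perf.sensitivity.estimate == perf.specificity.estimate

    def test_zero_denominator_flagged_not_zero(self):
        perf = ds.performance(ds.ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert not perf.sensitivity.available
        assert perf.sensitivity.estimate is None

    def test_bayes_matches_performance_at_matrix_prevalence(self):
        cm = ds.ConfusionMatrix(tp=40, fp=12, fn=8, tn=60)
        perf = ds.performance(cm)
        ppv, npv, acc = ds.bayes_predictive(
            perf.sensitivity.estimate, perf.specificity.estimate, cm.prevalence
        )
        assert np.isclose(ppv, perf.ppv.estimate)
        assert np.isclose(npv, perf.npv.estimate)
        assert np.isclose(acc, perf.accuracy.estimate)

    def test_perfect_specificity_gives_unit_ppv(self):
        ppv, _, _ = ds.bayes_predictive(0.7, 1 - 1e-12, 0.3)
        assert np.isclose(ppv, 1.0)


class TestROC:
    def test_perfectly_separated_auc_one(self):
        curve = ds.roc([0.5, 0.6, 0.9, 0.95], [True, True, False, False])
        assert curve.auc == 1.0

    def test_four_pair_hand_case(self):
        # positives {0.9, 0.8}, negatives {0.7, 0.85}, higher-is-positive:
        # pairs won 3 of 4 -> AUC 0.75
        curve = ds.roc([0.9, 0.8, 0.7, 0.85], [True, True, False, False],
                       lower_is_positive=False)
        assert curve.auc == 0.75

    def test_constant_scores_auc_half(self):
        curve = ds.roc([0.5] * 6, [True, False, True, False, True, False])
        assert curve.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ds.DiagStatsError):
            ds.roc([0.1, 0.2], [True, True])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        scores=st.lists(st.integers(0, 9), min_size=2, max_size=50),
        flips=st.data(),
    )
    def test_auc_equals_brute_force_pair_counting(self, scores, flips):
        n = len(scores)
        truth = flips.draw(
            st.lists(st.booleans(), min_size=n, max_size=n)
        )
        truth = np.asarray(truth)
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        scores = np.asarray(scores, dtype=float)
        curve = ds.roc(scores, truth, lower_is_positive=True)
        pos = scores[truth]
        neg = scores[~truth]
        wins = sum((p < q) + 0.5 * (p == q) for p in pos for q in neg)
        assert np.isclose(curve.auc, wins / (len(pos) * len(neg)))


class TestDeLong:
    def test_identical_curves_p_one_delta_zero(self):
        scores = np.array([0.3, 0.7, 0.55, 0.9, 0.45, 0.8])
        truth = np.array([True, False, True, False, True, False])
        a = ds.roc(scores, truth)
        b = ds.roc(scores.copy(), truth)
        delta, z, p = ds.delong_compare(a, b)
        assert delta == 0.0 and p == 1.0

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(0)
        truth = rng.random(40) < 0.5
        truth[0], truth[1] = True, False
        s1 = rng.normal(size=40) - truth
        s2 = rng.normal(size=40) - 0.5 * truth
        a, b = ds.roc(s1, truth), ds.roc(s2, truth)
        d_ab, z_ab, _ = ds.delong_compare(a, b)
        d_ba, z_ba, _ = ds.delong_compare(b, a)
        assert np.isclose(d_ab, -d_ba) and np.isclose(z_ab, -z_ba)

    def test_structural_components_match_hand_formula(self):
        # toy with n = 8: components computed by direct pair enumeration
        scores = np.array([0.2, 0.4, 0.5, 0.9, 0.3, 0.6, 0.7, 0.8])
        truth = np.array([True, True, True, True, False, False, False, False])
        oriented = -scores  # lower score indicates disease
        v10, v01 = ds._delong_components(oriented, truth)
        pos, neg = oriented[truth], oriented[~truth]
        v10_hand = [
            np.mean([(p > q) + 0.5 * (p == q) for q in neg]) for p in pos
        ]
        v01_hand = [
            np.mean([(p > q) + 0.5 * (p == q) for p in pos]) for q in neg
        ]
        assert np.allclose(v10, v10_hand)
        assert np.allclose(v01, v01_hand)
        assert np.isclose(np.mean(v10), ds.roc(scores, truth).auc)

    def test_p_value_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(42)
        n = 60
        truth = np.arange(n) < 30
        s_a = rng.normal(size=n) - 1.2 * truth
        s_b = rng.normal(size=n) - 0.7 * truth
        a, b = ds.roc(s_a, truth), ds.roc(s_b, truth)
        _, _, p = ds.delong_compare(a, b)
        # paired bootstrap of delta AUC
        deltas = []
        idx_all = np.arange(n)
        for _ in range(4000):
            idx = rng.choice(idx_all, size=n, replace=True)
            t = truth[idx]
            if t.all() or not t.any():
                continue
            sa, sb = -s_a[idx], -s_b[idx]
            deltas.append(
                ds._auc_mann_whitney(sa, t) - ds._auc_mann_whitney(sb, t)
            )
        deltas = np.array(deltas)
        d_obs = a.auc - b.auc
        z_boot = d_obs / deltas.std(ddof=1)
        p_boot = 2 * sps.norm.sf(abs(z_boot))
        assert abs(p - p_boot) < 0.05


class TestYouden:
    def test_separable_toy_flags_tie(self):
        curve = ds.roc([0.3, 0.4, 0.8, 0.9], [True, True, False, False])
        thr, j, tie = ds.youden_threshold(curve)
        assert j == 1.0
        assert tie  # any threshold in the gap attains J = 1

    def test_six_point_hand_maximizer(self):
        scores = np.array([0.55, 0.60, 0.70, 0.75, 0.85, 0.95])
        truth = np.array([True, True, True, False, True, False])
        curve = ds.roc(scores, truth)
        # enumerate J over all unique thresholds by hand
        best_thr, best_j = None, -2
        for t in np.unique(scores):
            pred = scores <= t
            se = (pred & truth).sum() / truth.sum()
            sp = (~pred & ~truth).sum() / (~truth).sum()
            if se + sp - 1 > best_j:
                best_j, best_thr = se + sp - 1, t
        thr, j, _ = ds.youden_threshold(curve)
        assert np.isclose(j, best_j)
        assert np.isclose(thr, best_thr)


class TestMcNemarSpearmanBA:
    def test_balanced_discordance_p_near_one(self):
        stat, p = ds.mcnemar_from_counts(10, 10)
        assert p > 0.9

    def test_continuity_corrected_statistic_closed_form(self):
        stat, _ = ds.mcnemar_from_counts(5, 15)
        assert np.isclose(stat, 4.05)

    def test_no_discordance_degenerate(self):
        stat, p = ds.mcnemar_from_counts(0, 0)
        assert stat == 0.0 and p == 1.0

    def test_mcnemar_from_vectors(self):
        a = np.array([True] * 5 + [False] * 15 + [True] * 10)
        b = np.array([False] * 5 + [True] * 15 + [True] * 10)
        stat, p = ds.mcnemar(a, b)
        assert np.isclose(stat, 4.05)

    def test_spearman_monotone_map_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, _ = ds.spearman(x, np.exp(x))
        assert np.isclose(r, 1.0)
        r, _ = ds.spearman(x, -x)
        assert np.isclose(r, -1.0)

    def test_spearman_five_point_hand_case(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 0.5, 3.0, 2.5, 4.0]
        # ranks x: 3 1 4 2 5 ; ranks y: 2 1 4 3 5 ; d = (1,0,0,-1,0)
        r_hand = 1 - 6 * 2 / (5 * 24)
        r, _ = ds.spearman(x, y)
        assert np.isclose(r, r_hand)

    def test_bland_altman_identical_arrays(self):
        res = ds.bland_altman([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_bland_altman_two_point_hand_case(self):
        res = ds.bland_altman([0.7, 0.85], [0.8, 0.8])
        assert np.isclose(res.bias, -0.025)
        sd = np.std([-0.1, 0.05], ddof=1)
        assert np.isclose(res.loa_low, -0.025 - 1.96 * sd)
        assert np.isclose(res.loa_high, -0.025 + 1.96 * sd)

    def test_bland_altman_recovers_generative_bias(self):
        rng = np.random.default_rng(7)
        n = 5000
        f = rng.uniform(0.5, 1.0, n)
        ct = f - 0.02 + rng.normal(0, 0.05, n)
        res = ds.bland_altman(ct, f)
        assert abs(res.bias + 0.02) < 3 * 0.05 / np.sqrt(n)


class TestStratifiedAndRegression:
    def test_agreement_certain_stratum_is_100pct(self, cohort_seed1):
        import pandas as pd

        v = cohort_seed1.vessels
        sub = v[(v["ctffr"] > 0.90) & (v["true_ffr"] > 0.80)]
        df = pd.DataFrame({"ctffr": sub["ctffr"], "true_ffr": sub["true_ffr"]})
        out = ds.agreement_by_stratum(df)
        assert np.isclose(out.loc[">=0.90", "agreement"], 1.0)

    def test_stratified_performance_splits_by_label(self, cohort_seed1):
        v = cohort_seed1.vessels
        lab = (v["agatston"] >= 400).map({True: ">=400", False: "<400"})
        table = ds.stratified_performance(v, lab)
        assert set(table.index) == {"<400", ">=400"}
        assert table["n"].sum() == len(v)

    def test_logistic_or_equals_cross_product_on_2x2(self):
        # a=10 exposed cases, b=20 exposed controls, c=5, d=40
        x = np.array([1.0] * 30 + [0.0] * 45)
        y = np.array([1.0] * 10 + [0.0] * 20 + [1.0] * 5 + [0.0] * 40)
        import pandas as pd

        df = pd.DataFrame(
            {"exposure": x, "ctffr": np.where(y == 1, 0.7, 0.9),
             "true_ffr": np.full(75, 0.9)}
        )
        fits = ds.discordance_regression(df, ["exposure"])
        assert np.isclose(fits[0].odds_ratio, (10 * 40) / (20 * 5), rtol=1e-3)

    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(1)
        n = 10_000
        import pandas as pd

        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "ctffr": rng.uniform(0.5, 1.0, n),
                "true_ffr": rng.uniform(0.5, 1.0, n),
            }
        )
        fits = ds.discordance_regression(df, ["x"])
        assert 0.9 < fits[0].odds_ratio < 1.1

    def test_all_events_stratum_flagged_separated(self):
        import pandas as pd

        df = pd.DataFrame(
            {"x": [0.1, 0.2, 0.3], "ctffr": [0.7] * 3, "true_ffr": [0.9] * 3}
        )
        fits = ds.discordance_regression(df, ["x"])
        assert fits[0].separation
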