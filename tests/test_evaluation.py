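"""LOCO protocol, AUC, confusion/OR/trend statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from gifa import evaluation as ev
from gifa import modeling, synthetic
from gifa.errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedMetricError,
)


class TestLocoProtocol:
    def test_one_score_per_original_case(self, small_table):
        scores = ev.loco_cv(small_table, ev.LocoConfig(k=5))
        assert len(scores) == len(small_table)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_synthetic_rows_rejected_as_input(self, small_table):
        smoted = modeling.smote(small_table, target_ratio=1.0, seed=0)
        with pytest.raises(InvalidInputError):
            ev.loco_cv(smoted, ev.LocoConfig(k=5))

    def test_training_fold_size_with_smote_doubling(self):
        # 26+81 cases, SMOTE doubling inside each fold: the fold trains on
        # 106 originals + 26 synthetic = 132 cases; 107 scores come out
        spec = synthetic.FeatureTableSpec(
            n_pos=26, n_neg=81, n_features=3, effect_size=1.0, seed=0
        )
        table = synthetic.gen_feature_table(spec)
        seen_sizes = set()
        orig_smote = modeling.smote

        def spy(t, **kwargs):
            out = orig_smote(t, **kwargs)
            seen_sizes.add(len(out))
            return out

        import gifa.modeling as mo

        mo_smote = mo.smote
        mo.smote = spy
        try:
            scores = ev.loco_cv(
                table,
                ev.LocoConfig(smote_ratio=None, smote_multiplier=2.0, select=False),
            )
        finally:
            mo.smote = mo_smote
        assert len(scores) == 107
        # 132 when a negative is held out (52 pos + 80 neg); 131 when a
        # positive is held out (50 pos + 81 neg)
        assert seen_sizes == {131, 132}

    def test_determinism_given_seed(self, small_table):
        c = ev.LocoConfig(k=5, seed=77)
        np.testing.assert_array_equal(
            ev.loco_cv(small_table, c), ev.loco_cv(small_table, c)
        )


class TestAUC:
    def test_perfect_separation(self):
        a, _ = ev.auc(np.r_[np.ones(5), np.zeros(5)], np.r_[np.ones(5), np.zeros(5)])
        assert a == 1.0

    def test_all_ties_give_half(self):
        a, _ = ev.auc(np.full(10, 0.3), np.r_[np.ones(4), np.zeros(6)])
        assert a == 0.5

    def test_hand_counted_concordant_pairs(self):
        scores = np.array([0.9, 0.8, 0.85, 0.7])
        labels = np.array([1, 1, 0, 0])
        a, _ = ev.auc(scores, labels)
        assert a == pytest.approx(0.75)  # 3 of 4 concordant pairs

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(size=80)
        labels = (rng.uniform(size=80) < 0.4).astype(int)
        a, _ = ev.auc(scores, labels)
        assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_matches_trapezoid_integration_tie_free(self, rng):
        # oracle: trapezoidal ROC integration on tie-free scores
        for _ in range(20):
            scores = rng.permutation(np.linspace(0, 1, 30))
            labels = (rng.uniform(size=30) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            order = np.argsort(-scores)
            y = labels[order]
            tpr = np.concatenate([[0], np.cumsum(y) / y.sum()])
            fpr = np.concatenate([[0], np.cumsum(1 - y) / (1 - y).sum()])
            trap = np.trapezoid(tpr, fpr)
            assert ev.auc(scores, labels)[0] == pytest.approx(trap, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            ev.auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_hanley_mcneil_se_positive_and_shrinks(self):
        rng = np.random.default_rng(0)
        small = ev.auc(rng.uniform(size=40), np.r_[np.ones(20), np.zeros(20)])[1]
        big = ev.auc(rng.uniform(size=400), np.r_[np.ones(200), np.zeros(200)])[1]
        assert 0 < big < small


class TestConfusion:
    def test_all_positive_scores_all_positive_labels(self):
        cm = ev.confusion_at_threshold(np.ones(7), np.ones(7))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (7, 0, 0, 0)

    def test_zero_threshold_predicts_everything_positive(self):
        cm = ev.confusion_at_threshold(
            np.array([0.0, 0.4, 0.9]), np.array([0, 1, 0]), threshold=0.0
        )
        assert cm.fn == 0 and cm.tn == 0

    def test_straddling_scores_match_enumeration(self, rng):
        scores = rng.uniform(size=50)
        labels = (rng.uniform(size=50) < 0.3).astype(int)
        cm = ev.confusion_at_threshold(scores, labels, 0.5)
        tp = sum(s >= 0.5 and l == 1 for s, l in zip(scores, labels))
        fp = sum(s >= 0.5 and l == 0 for s, l in zip(scores, labels))
        assert (cm.tp, cm.fp) == (tp, fp)
        assert cm.total == 50

    def test_exact_half_score_counts_positive(self):
        cm = ev.confusion_at_threshold(np.array([0.5]), np.array([1]))
        assert cm.tp == 1

    def test_perfect_matrix_all_metrics_100(self):
        m = ev.matrix_metrics(ev.ConfusionMatrix(tp=5, fp=0, fn=0, tn=9))
        assert all(v == 100.0 for v in m.values())

    def test_zero_denominator_is_undefined_not_zero(self):
        m = ev.matrix_metrics(ev.ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert m["ppv"] is None
        assert m["specificity"] == 100.0


class TestQuantileBins:
    def test_1045_scores_five_bins_of_209(self, rng):
        bins = ev.quantile_bins(rng.uniform(size=1045), k=5)
        sizes = np.bincount(bins)[1:]
        assert list(sizes) == [209] * 5

    def test_ten_scores_bins_of_two(self):
        bins = ev.quantile_bins(np.arange(10, dtype=float), k=5)
        assert list(np.bincount(bins)[1:]) == [2] * 5
        assert bins[0] == 1 and bins[-1] == 5

    def test_monotone_relabeling_invariance(self, rng):
        scores = rng.uniform(size=97)
        b1 = ev.quantile_bins(scores, 5)
        b2 = ev.quantile_bins(np.exp(3 * scores), 5)
        np.testing.assert_array_equal(b1, b2)

    def test_too_few_scores_rejected(self):
        with pytest.raises(InvalidParameterError):
            ev.quantile_bins(np.array([0.1, 0.2]), k=5)


class TestOddsRatios:
    def test_identical_odds_give_unit_or(self):
        rows = ev.odds_ratio_from_counts(np.array([10, 20]), np.array([30, 60]))
        assert rows[1].odds_ratio == pytest.approx(1.0)

    def test_baseline_row_flagged_exact_unit(self):
        rows = ev.odds_ratio_from_counts(np.array([5, 9]), np.array([7, 3]))
        assert rows[0].baseline and rows[0].odds_ratio == 1.0

    def test_zero_cell_haldane_correction_flagged(self):
        rows = ev.odds_ratio_from_counts(np.array([5, 0]), np.array([5, 10]))
        assert rows[1].corrected
        assert np.isfinite(rows[1].odds_ratio)

    def test_from_case_level_bins(self, rng):
        scores = rng.uniform(size=200)
        labels = rng.binomial(1, 0.15 + 0.5 * scores)
        bins = ev.quantile_bins(scores, 5)
        rows = ev.odds_ratio_table(bins, labels)
        assert sum(r.positives + r.negatives for r in rows) == 200
        assert all(r.ci_low <= r.odds_ratio <= r.ci_high for r in rows)


class TestTrendTest:
    def test_extreme_monotone_trend_significant(self):
        pos = np.array([2, 10, 30, 60, 90])
        neg = np.array([98, 90, 70, 40, 10])
        z, p = ev.trend_test_from_counts(pos, neg)
        assert p < 1e-6 and z > 0

    def test_flat_counts_give_zero_statistic(self):
        z, p = ev.trend_test_from_counts(np.full(5, 20), np.full(5, 30))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_chi2_based_computation(self):
        # independent route: CA z^2 equals the 1-df chi-square trend statistic
        pos = np.array([34, 62, 84, 94, 128], float)
        neg = np.array([175, 147, 125, 115, 81], float)
        z, _ = ev.trend_test_from_counts(pos, neg)
        n_g = pos + neg
        s = np.arange(1, 6, dtype=float)
        big_n, big_r = n_g.sum(), pos.sum()
        num = (big_n * (s * pos).sum() - big_r * (s * n_g).sum()) ** 2
        den = (
            big_r * (big_n - big_r) * (big_n * (n_g * s**2).sum() - ((n_g * s).sum()) ** 2)
        )
        chi2 = num / den * big_n
        assert z**2 == pytest.approx(chi2, rel=1e-12)


class TestLeakageCanary:
    def test_label_feature_leaks_auc_one(self):
        rng = np.random.default_rng(0)
        n = 40
        labels = np.r_[np.ones(14, int), np.zeros(26, int)]
        x = rng.normal(0, 1, (n, 2))
        table = pd.DataFrame(x, columns=["f1", "f2"])
        table.insert(0, "case_id", [f"c{i:03d}" for i in range(n)])
        table["f3"] = labels.astype(float)  # perfectly informative feature
        table["label"] = labels
        table["synthetic"] = False
        scores = ev.loco_cv(table, ev.LocoConfig(k=5))
        assert ev.auc(scores, labels)[0] == 1.0

    def test_heldout_only_label_feature_gives_chance(self):
        # the canary equals the label only in the held-out row of each fold:
        # a leak-free pipeline can extract nothing from it
        rng = np.random.default_rng(1)
        n = 40
        labels = np.r_[np.ones(16, int), np.zeros(24, int)]
        base = rng.normal(0, 1, (n, 3))
        scores = np.empty(n)
        for i in range(n):
            canary = rng.normal(0, 1, n)
            canary[i] = 5.0 if labels[i] == 1 else -5.0
            table = pd.DataFrame(base, columns=["f1", "f2", "f3"])
            table.insert(0, "case_id", [f"c{i:03d}" for i in range(n)])
            table["f4"] = canary
            table["label"] = labels
            table["synthetic"] = False
            scores[i] = ev.loco_cv(table, ev.LocoConfig(k=5, seed=i), indices=[i])[0]
        a, _ = ev.auc(scores, labels)
        assert abs(a - 0.5) < 0.25  # chance level, far from a leaking 1.0


class TestEvaluateScores:
    def test_bundle_consistency(self, rng):
        scores = rng.uniform(size=150)
        labels = (scores + rng.normal(0, 0.25, 150) > 0.55).astype(int)
        res = ev.evaluate_scores(scores, labels)
        assert res.confusion.total == 150
        assert len(res.or_table) == 5
        assert res.metrics["accuracy"] is not None
        assert 0 <= res.auc <= 1
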