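import numpy as np
import pytest

from stentrisk import (
    ConfusionCounts,
    brier_and_calibration,
    classification_metrics,
    confusion,
    dca_curve,
    f1_score,
    net_benefit,
    pr_auc,
    roc_auc,
)


class TestConfusion:
    def test_simple_case(self):
        c = confusion([1, 0], [0.9, 0.1], 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_perfect_predictor_any_threshold(self):
        y = np.array([0, 1, 1, 0, 1])
        for thr in (0.1, 0.5, 0.9):
            c = confusion(y, y.astype(float), thr)
            assert c.FP == 0 and c.FN == 0

    def test_tie_predicts_positive(self):
        c = confusion([0], [0.5], 0.5)
        assert c.FP == 1

    def test_brute_force_loop_equality(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 60)
            y = rng.integers(0, 2, size=n)
            p = rng.uniform(size=n)
            thr = rng.uniform(0.05, 0.95)
            c = confusion(y, p, thr)
            tp = sum(1 for yi, pi in zip(y, p) if pi >= thr and yi == 1)
            fp = sum(1 for yi, pi in zip(y, p) if pi >= thr and yi == 0)
            fn = sum(1 for yi, pi in zip(y, p) if pi < thr and yi == 1)
            tn = n - tp - fp - fn
            assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [0.5], 0.5)


class TestClassificationMetrics:
    def test_f1_from_reported_precision_sensitivity_pair(self):
        # the tuned model's held-out precision/sensitivity imply its F1
        assert round(f1_score(0.6234, 0.9600), 4) == 0.7559

    def test_all_positive_classifier_pattern(self):
        # degenerate always-positive prediction: SEN 1, SPE 0, ACC = prevalence
        y = np.array([1] * 100 + [0] * 140)
        p = np.full(240, 0.99)
        m = classification_metrics(confusion(y, p, 0.5))
        assert m.SEN == 1.0
        assert m.SPE == 0.0
        assert round(m.ACC, 4) == 0.4167
        assert round(m.PRE, 4) == 0.4167

    def test_reconstructed_counts_give_reported_accuracy(self):
        m = classification_metrics(ConfusionCounts(TP=96, FP=58, TN=82, FN=4))
        assert round(m.ACC, 4) == 0.7417
        assert round(m.PRE, 4) == 0.6234
        assert m.F1 == pytest.approx(2 * m.PRE * m.SEN / (m.PRE + m.SEN))

    def test_undefined_precision_warns_and_reports_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            m = classification_metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert m.PRE == 0.0


class TestAreas:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        p = [0.1, 0.2, 0.8, 0.9]
        assert roc_auc(y, p) == 1.0
        assert pr_auc(y, p) == 1.0

    def test_constant_scores_give_half_roc(self):
        assert roc_auc([0, 1, 0, 1], [0.3] * 4) == 0.5

    def test_roc_auc_equals_pair_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(10, 50)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            pos = p[y == 1]
            neg = p[y == 0]
            wins = sum((pi > ni) + 0.5 * (pi == ni) for pi in pos for ni in neg)
            assert roc_auc(y, p) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        p = rng.uniform(size=40)
        assert roc_auc(y, p) == pytest.approx(roc_auc(1 - y, 1 - p))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])


class TestCalibration:
    def test_exact_predictions_give_zero_brier(self):
        y = np.array([0, 1, 1, 0])
        cal = brier_and_calibration(y, y.astype(float))
        assert cal.brier == 0.0

    def test_half_probability_gives_quarter_brier(self):
        for y in ([0, 0, 1], [1, 1, 1, 0]):
            cal = brier_and_calibration(np.array(y), np.full(len(y), 0.5))
            assert cal.brier == pytest.approx(0.25)

    def test_bin_counts_sum_to_n(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=200)
        p = rng.uniform(size=200)
        cal = brier_and_calibration(y, p, bins=10)
        assert cal.counts.sum() == 200
        assert len(cal.mean_predicted) == len(cal.observed_fraction)

    def test_brier_decomposition_on_three_bin_hand_case(self):
        # three homogeneous score groups: Brier = reliability - resolution
        # + uncertainty, computed directly from the group structure
        y = np.array([0, 0, 1, 0, 1, 1, 1, 1])
        p = np.array([0.1, 0.1, 0.1, 0.55, 0.55, 0.55, 0.9, 0.9])
        cal = brier_and_calibration(y, p, bins=3)
        ybar = y.mean()
        rel = res = 0.0
        for pk in np.unique(p):
            m = p == pk
            ok = y[m].mean()
            rel += m.mean() * (pk - ok) ** 2
            res += m.mean() * (ok - ybar) ** 2
        unc = ybar * (1 - ybar)
        assert cal.brier == pytest.approx(rel - res + unc, abs=1e-12)


class TestNetBenefit:
    def test_hand_computed_value(self):
        c = ConfusionCounts(TP=96, FP=58, TN=82, FN=4)
        assert net_benefit(c, 0.2) == pytest.approx(0.4 - (58 / 240) * 0.25)

    def test_no_false_positives_threshold_free(self):
        c = ConfusionCounts(TP=30, FP=0, TN=60, FN=10)
        assert net_benefit(c, 0.1) == net_benefit(c, 0.8) == 0.3

    def test_treat_none_is_zero(self):
        c = ConfusionCounts(TP=0, FP=0, TN=70, FN=30)
        assert net_benefit(c, 0.3) == 0.0

    def test_monotone_in_false_positives(self):
        nb1 = net_benefit(ConfusionCounts(10, 5, 80, 5), 0.3)
        nb2 = net_benefit(ConfusionCounts(10, 15, 70, 5), 0.3)
        assert nb2 < nb1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            net_benefit(ConfusionCounts(1, 1, 1, 1), 1.0)


class TestDecisionCurve:
    def test_treat_all_crosses_zero_at_prevalence(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 30 + [0] * 70)
        p = rng.uniform(size=100)
        curve = dca_curve(y, p, thresholds=[0.3])
        assert curve.nb_all[0] == pytest.approx(0.0, abs=1e-12)
        assert curve.nb_none[0] == 0.0

    def test_perfect_predictor_dominates_references(self):
        y = np.array([1] * 20 + [0] * 80)
        p = y.astype(float) * 0.98 + 0.01
        curve = dca_curve(y, p)
        assert (curve.nb_model >= curve.nb_all - 1e-12).all()
        assert (curve.nb_model >= -1e-12).all()

    def test_six_point_hand_example_matches_loop_oracle(self):
        y = np.array([1, 0, 1, 1, 0, 0])
        p = np.array([0.9, 0.4, 0.6, 0.2, 0.1, 0.55])
        thresholds = [0.15, 0.5, 0.8]
        curve = dca_curve(y, p, thresholds=thresholds)
        for i, t in enumerate(thresholds):
            treat = p >= t
            tp = int((treat & (y == 1)).sum())
            fp = int((treat & (y == 0)).sum())
            nb = tp / 6 - (fp / 6) * t / (1 - t)
            assert curve.nb_model[i] == pytest.approx(nb)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        c1 = dca_curve(y, p)
        c2 = dca_curve(y[perm], p[perm])
        np.testing.assert_allclose(c1.nb_model, c2.nb_model)
        assert roc_auc(y, p) == roc_auc(y[perm], p[perm])
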