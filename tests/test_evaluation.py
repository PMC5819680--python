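import numpy as np
import pytest
from scipy.stats import rankdata

from varprior import (LabeledScore, call_rates, clinical_utility, evaluate,
                      roc_auc, score_vs_frequency, youden_curve)


def labeled(scores_path, scores_benign, unscored_path=0, unscored_benign=0):
    data = [LabeledScore(float(s), "pathogenic") for s in scores_path]
    data += [LabeledScore(float(s), "benign") for s in scores_benign]
    data += [LabeledScore(None, "pathogenic")] * unscored_path
    data += [LabeledScore(None, "benign")] * unscored_benign
    return data


def ranksum_auc(pos, neg):
    """Tie-corrected rank-sum probability P(score_pos > score_neg) + 0.5 P(=)."""
    s = np.concatenate([pos, neg])
    ranks = rankdata(s)
    r_pos = ranks[:len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2
    return u / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(labeled([5, 6, 7], [1, 2, 3]))
        assert auc == 1.0

    def test_uninformative_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=10000)
        data = labeled(scores[:5000], scores[5000:])
        _, auc = roc_auc(data)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_trapezoid_equals_ranksum_probability(self):
        rng = np.random.default_rng(42)
        pos = rng.normal(1.0, 1.0, 300)
        neg = rng.normal(0.0, 1.0, 400)
        # inject ties across classes
        pos[:50] = neg[:50]
        _, auc = roc_auc(labeled(pos, neg))
        assert auc == pytest.approx(ranksum_auc(pos, neg), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.normal(1, 1, 100), rng.normal(0, 1, 100)
        _, auc1 = roc_auc(labeled(pos, neg))
        _, auc2 = roc_auc(labeled(np.exp(pos / 3), np.exp(neg / 3)))
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(labeled([1, 2], []))

    def test_unscored_items_excluded(self):
        _, auc = roc_auc(labeled([5, 6], [1, 2], unscored_path=5, unscored_benign=5))
        assert auc == 1.0


class TestYouden:
    def test_j_from_hand_built_confusion_table(self):
        # at threshold 5: Sn = 9/10, Sp = 8/10 -> J = 0.7; at 0: Sn=1, Sp=0
        pos = [5] * 9 + [0]
        neg = [0] * 8 + [5, 5]
        curve, optimal, j_max = youden_curve(labeled(pos, neg))
        assert j_max == pytest.approx(0.7)
        assert optimal == 5.0  # lowest raw score attaining J_max

    def test_perfect_classifier_jmax_one(self):
        _, _, j_max = youden_curve(labeled([5, 6, 7], [1, 2, 3]))
        assert j_max == 1.0

    def test_uninformative_jmax_near_zero(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=8000)
        _, _, j_max = youden_curve(labeled(s[:4000], s[4000:]))
        assert j_max == pytest.approx(0.0, abs=0.06)

    def test_jmax_equals_best_roc_gap(self):
        rng = np.random.default_rng(3)
        data = labeled(rng.normal(1, 1, 200), rng.normal(0, 1, 200))
        points, _ = roc_auc(data)
        _, _, j_max = youden_curve(data)
        assert j_max == pytest.approx(max(tpr - fpr for fpr, tpr in points), abs=1e-12)

    def test_normalized_axis_in_unit_interval(self):
        curve, _, _ = youden_curve(labeled([-5, -1, 4], [-9, -3, 0]))
        xs = [x for x, _ in curve]
        assert min(xs) >= 0.0 and max(xs) <= 1.0


class TestClinicalUtility:
    def test_full_coverage_equals_accuracy(self):
        # Sn = Sp = 0.9 at threshold 0.5
        pos = [1] * 9 + [0]
        neg = [0] * 9 + [1]
        assert clinical_utility(labeled(pos, neg), 0.5) == pytest.approx(0.9)

    def test_perfect_tool_at_half_coverage(self):
        data = labeled([5, 6], [1, 2], unscored_path=2, unscored_benign=2)
        assert clinical_utility(data, 4.0) == pytest.approx(0.5)

    def test_scoring_nothing_is_zero(self):
        data = labeled([], [], unscored_path=3, unscored_benign=3)
        assert clinical_utility(data, 0.5) == 0.0

    def test_never_exceeds_accuracy(self):
        rng = np.random.default_rng(4)
        data = labeled(rng.normal(1, 1, 50), rng.normal(0, 1, 50),
                       unscored_path=10, unscored_benign=5)
        summary_threshold = 0.5
        util = clinical_utility(data, summary_threshold)
        scored = [d for d in data if d.score is not None]
        y = np.array([d.label == "pathogenic" for d in scored])
        s = np.array([d.score for d in scored])
        sn = (s[y] >= summary_threshold).mean()
        sp = (s[~y] < summary_threshold).mean()
        assert util <= (sn + sp) / 2 + 1e-12


class TestCallRates:
    def test_three_way_split(self):
        data = labeled([5] * 9, [1] * 81, unscored_benign=10)
        assert call_rates(data, 4.0) == pytest.approx((9.0, 81.0, 10.0))

    def test_rows_sum_to_hundred(self):
        data = labeled([5, 1], [0, 9], unscored_path=1)
        assert sum(call_rates(data, 3.0)) == pytest.approx(100.0)

    def test_rare_subset(self):
        data = [LabeledScore(5.0, "pathogenic", frequency=1e-4)] * 5 \
            + [LabeledScore(1.0, "benign", frequency=1e-4)] * 15 \
            + [LabeledScore(5.0, "benign", frequency=0.3)] * 80
        assert call_rates(data, 4.0, rare_only=True) == pytest.approx((25.0, 75.0, 0.0))


class TestScoreVsFrequency:
    def test_monotone_input_gives_monotone_bins(self):
        freqs = np.logspace(-3, -0.5, 200)
        data = [LabeledScore(float(-np.log10(f)), "benign", frequency=float(f))
                for f in freqs]
        profile = score_vs_frequency(data, n_bins=5)
        assert np.all(np.diff(profile["mean_score"]) < 0)

    def test_single_bin_is_overall_mean(self):
        data = [LabeledScore(s, "benign", frequency=f)
                for s, f in [(1.0, 0.01), (3.0, 0.1), (5.0, 0.4)]]
        profile = score_vs_frequency(data, n_bins=1)
        assert profile["mean_score"].iloc[0] == pytest.approx(3.0)

    def test_empty_bins_omitted(self):
        data = [LabeledScore(1.0, "benign", frequency=1e-3)] * 5 \
            + [LabeledScore(2.0, "benign", frequency=0.4)] * 5
        profile = score_vs_frequency(data, n_bins=8)
        assert len(profile) == 2
        assert profile["n"].sum() == 10


def test_evaluate_summary_consistency():
    rng = np.random.default_rng(5)
    data = labeled(rng.normal(2, 1, 200), rng.normal(0, 1, 300),
                   unscored_benign=50)
    s = evaluate(data)
    assert 0.0 <= s.auc <= 1.0
    assert -1.0 <= s.j_max <= 1.0
    assert s.fraction_scored == pytest.approx(500 / 550)
    assert s.clinical_utility <= s.accuracy_at[s.optimal_threshold] + 1e-12
    assert sum(s.call_rates[s.optimal_threshold]) == pytest.approx(100.0)
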