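"""Discrimination metrics: AUC, OR per SD, Youden, centile rule, overlap."""

import numpy as np
import pytest
from scipy.stats import norm

from smrprs import (
    ScoreSet,
    auc_ci,
    binary_high_risk,
    evaluate_scores,
    joint_model_auc,
    or_per_sd,
    overlap_analysis,
    youden_point,
)


def pair_count_auc(cases, controls):
    """Brute-force Mann-Whitney oracle: exhaustive pair enumeration, ties half."""
    wins = sum(1.0 if c > k else 0.5 if c == k else 0.0 for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


class TestAuc:
    def test_small_example_with_ties(self, make_scoreset):
        s = make_scoreset([2, 3, 4], [1, 2, 3])
        auc, lo, hi = auc_ci(s)
        assert auc == pytest.approx(7 / 9)
        assert lo <= auc <= hi

    def test_perfect_separation(self, make_scoreset):
        s = make_scoreset([10, 11, 12], [1, 2, 3])
        assert auc_ci(s)[0] == 1.0

    def test_null_scores_near_half(self, make_scoreset):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(2000)
        labels = rng.permutation([1] * 1000 + [0] * 1000)
        s = ScoreSet(scores=scores, labels=np.array(labels))
        assert 0.45 < auc_ci(s)[0] < 0.55

    def test_matches_pair_count_oracle(self, make_scoreset):
        rng = np.random.default_rng(6)
        for trial in range(10):
            n1, n0 = int(rng.integers(2, 250)), int(rng.integers(2, 250))
            cases = rng.integers(0, 20, n1).astype(float)  # heavy ties
            controls = rng.integers(0, 20, n0).astype(float) - rng.random() * 0.5
            s = make_scoreset(cases, controls)
            assert auc_ci(s)[0] == pytest.approx(pair_count_auc(cases, controls), abs=1e-12)

    def test_matches_sklearn(self, make_scoreset):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        cases = rng.normal(0.5, 1, 300)
        controls = rng.normal(0, 1, 400)
        s = make_scoreset(cases, controls)
        assert auc_ci(s)[0] == pytest.approx(
            roc_auc_score(s.labels, s.scores), abs=1e-12
        )

    def test_binormal_closed_form(self, make_scoreset):
        rng = np.random.default_rng(8)
        delta = 1.0
        s = make_scoreset(rng.normal(delta, 1, 5000), rng.normal(0, 1, 5000))
        assert auc_ci(s)[0] == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.02)

    def test_single_class_rejected(self):
        s = ScoreSet(scores=np.arange(5.0), labels=np.ones(5, int))
        with pytest.raises(ValueError):
            auc_ci(s)


class TestOrPerSd:
    def test_no_association_near_one(self, make_scoreset):
        rng = np.random.default_rng(9)
        s = make_scoreset(rng.normal(0, 1, 5000), rng.normal(0, 1, 5000))
        orr, lo, hi = or_per_sd(s)
        assert 0.9 < orr < 1.1 and lo < orr < hi

    def test_gaussian_shift_logit_slope(self, make_scoreset):
        # equal-variance Gaussians: per-unit logistic slope = delta_mu / sigma^2
        rng = np.random.default_rng(10)
        s = make_scoreset(rng.normal(1, 1, 10000), rng.normal(0, 1, 10000))
        orr, _, _ = or_per_sd(s)
        per_unit = np.log(orr) / s.scores.std(ddof=1)
        assert per_unit == pytest.approx(1.0, abs=0.1)

    def test_scale_invariance(self, make_scoreset):
        rng = np.random.default_rng(11)
        cases, controls = rng.normal(0.5, 1, 800), rng.normal(0, 1, 800)
        a = or_per_sd(make_scoreset(cases, controls))[0]
        b = or_per_sd(make_scoreset(2 * cases, 2 * controls))[0]
        assert a == pytest.approx(b, rel=1e-8)

    def test_zero_variance_rejected(self, make_scoreset):
        with pytest.raises(ValueError):
            or_per_sd(make_scoreset([1.0, 1.0], [1.0, 1.0]))


class TestYouden:
    def test_worked_example(self, make_scoreset):
        s = make_scoreset([4.5, 5.5, 6, 7], [1, 2, 3, 4, 5])
        thr, sens, spec = youden_point(s)
        assert sens == 1.0 and spec == pytest.approx(0.8)
        assert sens + spec - 1 == pytest.approx(0.8)
        assert thr == pytest.approx(4.25)

    def test_perfect_separation(self, make_scoreset):
        thr, sens, spec = youden_point(make_scoreset([5, 6], [1, 2]))
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_tie_takes_smallest_threshold(self, make_scoreset):
        # J ties at several thresholds; the smallest (max sensitivity) wins
        s = make_scoreset([2, 4], [1, 3])
        thr, sens, spec = youden_point(s)
        # J = 0.5 at thresholds 1.5 (sens 1, spec .5) and 2.5/3.5 variants
        assert thr == pytest.approx(1.5)
        assert sens == 1.0

    def test_degenerate_identical_scores_warns(self, make_scoreset):
        with pytest.warns(UserWarning):
            thr, sens, spec = youden_point(make_scoreset([1.0, 1.0], [1.0]))
        assert sens + spec - 1 == 0.0


class TestBinaryHighRisk:
    def test_worked_example_type7_quantile(self, make_scoreset):
        s = make_scoreset([5, 9, 10], list(range(1, 11)))
        b = binary_high_risk(s, 80)
        assert b.threshold == pytest.approx(8.2)
        assert b.sensitivity == pytest.approx(2 / 3)
        assert b.specificity == pytest.approx(0.8)
        assert b.auc_binary == pytest.approx((2 / 3 + 0.8) / 2)

    def test_specificity_exact_when_n_divisible_by_five(self, make_scoreset):
        rng = np.random.default_rng(12)
        for n0 in (10, 100, 1000):
            s = make_scoreset(rng.standard_normal(50), rng.standard_normal(n0))
            assert binary_high_risk(s, 80).specificity == pytest.approx(0.8, abs=1e-12)

    def test_auc_identity_always_holds(self, make_scoreset):
        rng = np.random.default_rng(13)
        for _ in range(5):
            s = make_scoreset(rng.normal(0.3, 1, 200), rng.normal(0, 1, 300))
            b = binary_high_risk(s, 80)
            assert b.auc_binary == (b.sensitivity + b.specificity) / 2

    def test_centile_validation(self, make_scoreset):
        s = make_scoreset([1, 2], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            binary_high_risk(s, 0)
        with pytest.raises(ValueError):
            binary_high_risk(s, 100)


class TestJointModel:
    def test_identical_second_score_changes_nothing(self, make_scoreset):
        rng = np.random.default_rng(14)
        s = make_scoreset(rng.normal(0.6, 1, 1000), rng.normal(0, 1, 1000))
        joint, _, _ = joint_model_auc(s, s)
        assert joint == pytest.approx(auc_ci(s)[0], abs=1e-9)

    def test_noise_second_score_asymptotically_irrelevant(self, make_scoreset):
        rng = np.random.default_rng(15)
        s = make_scoreset(rng.normal(0.6, 1, 2500), rng.normal(0, 1, 2500))
        noise = ScoreSet(
            scores=rng.standard_normal(5000), labels=s.labels, label="noise"
        )
        joint, _, _ = joint_model_auc(s, noise)
        assert joint == pytest.approx(auc_ci(s)[0], abs=0.02)

    def test_two_informative_scores_do_not_hurt(self, make_scoreset):
        rng = np.random.default_rng(16)
        n = 3000
        labels = np.array([1] * n + [0] * n)
        a_scores = rng.standard_normal(2 * n) + 0.4 * labels
        b_scores = rng.standard_normal(2 * n) + 0.4 * labels
        a = ScoreSet(scores=a_scores, labels=labels, label="a")
        b = ScoreSet(scores=b_scores, labels=labels, label="b")
        joint, _, _ = joint_model_auc(a, b)
        assert joint >= max(auc_ci(a)[0], auc_ci(b)[0]) - 0.01

    def test_mismatched_individuals_rejected(self, make_scoreset):
        a = make_scoreset([1, 2], [0, 1])
        b = make_scoreset([1, 2, 3], [0, 1])
        with pytest.raises(ValueError):
            joint_model_auc(a, b)


class TestOverlap:
    def test_self_overlap_has_no_discordant_cells(self, make_scoreset):
        rng = np.random.default_rng(17)
        s = make_scoreset(rng.normal(0.5, 1, 400), rng.normal(0, 1, 500))
        rep = overlap_analysis(s, s)
        for stratum in ("cases", "controls"):
            assert rep.cells[stratum]["only_a"] == 0
            assert rep.cells[stratum]["only_b"] == 0

    def test_cells_sum_to_stratum_size(self, make_scoreset):
        rng = np.random.default_rng(18)
        a = make_scoreset(rng.normal(0.5, 1, 400), rng.normal(0, 1, 500))
        b = ScoreSet(scores=rng.standard_normal(900), labels=a.labels, label="b")
        rep = overlap_analysis(a, b)
        for stratum in ("cases", "controls"):
            c = rep.cells[stratum]
            assert c["both"] + c["only_a"] + c["only_b"] + c["neither"] == c["n"]

    def test_negated_score_brute_force(self, make_scoreset):
        rng = np.random.default_rng(19)
        a = make_scoreset(rng.normal(0.5, 1, 200), rng.normal(0, 1, 300))
        b = ScoreSet(scores=-a.scores, labels=a.labels, label="neg")
        rep = overlap_analysis(a, b)
        thr_a = np.quantile(a.control_scores, 0.8)
        thr_b = np.quantile(-a.control_scores, 0.8)
        both = int(((a.scores > thr_a) & (-a.scores > thr_b) & (a.labels == 0)).sum())
        assert rep.cells["controls"]["both"] == both
        assert both <= 1  # top and bottom quintiles barely intersect

    def test_independent_scores_product_rule(self, make_scoreset):
        rng = np.random.default_rng(20)
        n = 20000
        labels = np.array([1] * 100 + [0] * (n - 100))
        a = ScoreSet(scores=rng.standard_normal(n), labels=labels, label="a")
        b = ScoreSet(scores=rng.standard_normal(n), labels=labels, label="b")
        rep = overlap_analysis(a, b)
        frac = rep.cells["controls"]["both"] / rep.cells["controls"]["n"]
        assert frac == pytest.approx(0.04, abs=0.01)


def test_full_report_consistency(make_scoreset):
    rng = np.random.default_rng(21)
    s = make_scoreset(rng.normal(0.5, 1, 500), rng.normal(0, 1, 500))
    rep = evaluate_scores(s)
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
    assert rep.or_per_sd_ci[0] <= rep.or_per_sd <= rep.or_per_sd_ci[1]
    assert rep.binary80.auc_binary == (rep.binary80.sensitivity + rep.binary80.specificity) / 2
    assert rep.n_cases == 500 and rep.n_controls == 500
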