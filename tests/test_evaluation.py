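import numpy as np
import pytest

from cxrcaption.evaluation import (
    ARMS,
    MetricUndefinedError,
    assign_arm,
    bootstrap_ci,
    classification_metrics,
    evaluate_arms,
)
from cxrcaption.textproc import tokenize

from oracles import all_pairs_auc


class TestClassificationMetrics:
    def test_perfect_separation(self):
        m = classification_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.auc == 1.0 and m.auprc == 1.0

    def test_worked_ranking_example(self):
        m = classification_metrics([0.9, 0.8, 0.7, 0.2], [1, 0, 1, 0])
        assert m.auc == pytest.approx(0.75)

    def test_confusion_matrix_metrics(self):
        # predictions at 0.5: [1,0,0,0] for truth [1,1,0,0]
        m = classification_metrics([0.9, 0.3, 0.2, 0.1], [1, 1, 0, 0], threshold=0.5)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == pytest.approx(1.0)
        assert m.accuracy == pytest.approx(0.75)
        assert m.f1 == pytest.approx(2 / 3)

    def test_single_class_truth_leaves_auc_undefined(self):
        m = classification_metrics([0.9, 0.1], [1, 1])
        assert m.auc is None and m.auprc is None
        assert m.sensitivity == pytest.approx(0.5)

    def test_rank_auc_equals_all_pairs_counting(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            truth = rng.integers(0, 2, size=n)
            if truth.sum() in (0, n):
                truth[0], truth[-1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            m = classification_metrics(scores, truth)
            assert m.auc == pytest.approx(all_pairs_auc(scores, truth), abs=1e-12)

    def test_reversing_scores_complements_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        truth = rng.integers(0, 2, size=40)
        truth[0], truth[-1] = 0, 1
        a = classification_metrics(scores, truth).auc
        b = classification_metrics(1 - scores, truth).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_accuracy_identity_from_sensitivity_and_specificity(self):
        rng = np.random.default_rng(6)
        scores = rng.random(200)
        truth = rng.integers(0, 2, size=200)
        m = classification_metrics(scores, truth, threshold=0.5)
        p, n = int(truth.sum()), int((1 - truth).sum())
        assert m.accuracy == pytest.approx(
            (m.sensitivity * p + m.specificity * n) / (p + n), abs=1e-12
        )


class TestBootstrapCI:
    def test_constant_statistic(self):
        lo, hi = bootstrap_ci(lambda sub: 3.5, list(range(100)), rng_seed=0)
        assert (lo, hi) == (3.5, 3.5)

    def test_same_seed_reproduces_interval(self):
        data = list(np.random.default_rng(2).normal(size=200))
        a = bootstrap_ci(lambda s: float(np.mean(s)), data, rng_seed=7)
        b = bootstrap_ci(lambda s: float(np.mean(s)), data, rng_seed=7)
        assert a == b

    def test_interval_brackets_estimate_and_shrinks_with_n(self):
        # the 95%-subsample scheme perturbs the full-sample mean only
        # slightly, so its interval brackets that mean and narrows ~1/sqrt(n)
        rng = np.random.default_rng(11)
        small = list(rng.normal(size=1000))
        big = list(rng.normal(size=4000))
        lo_s, hi_s = bootstrap_ci(lambda s: float(np.mean(s)), small, rng_seed=3)
        lo_b, hi_b = bootstrap_ci(lambda s: float(np.mean(s)), big, rng_seed=3)
        assert lo_s < np.mean(small) < hi_s
        assert lo_b < np.mean(big) < hi_b
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_classical_bootstrap_interval_contains_true_mean(self):
        rng = np.random.default_rng(12)
        data = list(rng.normal(size=1000))
        lo, hi = bootstrap_ci(
            lambda s: float(np.mean(s)), data, rng_seed=4, with_replacement=True
        )
        assert lo < 0 < hi

    def test_undefined_statistic_iterations_are_skipped_until_majority(self):
        def bad(sub):
            raise MetricUndefinedError("always undefined")

        with pytest.raises(MetricUndefinedError):
            bootstrap_ci(bad, list(range(50)), rng_seed=1)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda s: 0.0, [1, 2, 3], iterations=1)
        with pytest.raises(ValueError):
            bootstrap_ci(lambda s: 0.0, [1, 2, 3], sample_fraction=0.0)


class TestAssignArm:
    def test_deterministic(self):
        assert assign_arm("case-17", 5) == assign_arm("case-17", 5)

    def test_roughly_uniform_over_arms(self):
        counts = {arm: 0 for arm in ARMS}
        n = 30_000
        for i in range(n):
            counts[assign_arm(f"case-{i}", 123)] += 1
        for arm in ARMS:
            assert abs(counts[arm] / n - 1 / 3) < 0.01

    def test_seed_changes_some_assignment(self):
        ids = [f"case-{i}" for i in range(100)]
        a = [assign_arm(i, 1) for i in ids]
        b = [assign_arm(i, 2) for i in ids]
        assert a != b


class TestEvaluateArms:
    def test_identical_captions_score_one(self):
        report = tokenize("the lungs are clear.")
        cases = [(arm, report, report) for arm in ARMS for _ in range(3)]
        for summary in evaluate_arms(cases):
            assert summary.bleu_mean == pytest.approx(1.0)
            assert summary.bleu_sd == pytest.approx(0.0)

    def test_identical_per_case_lists_give_p_one(self):
        report = tokenize("nodule is observed in the lung.")
        caption = tokenize("nodule is observed.")
        cases = [
            ("nlp_generated", caption, report),
            ("nlp_generated", caption, report),
            ("rule_based", caption, report),
            ("rule_based", caption, report),
        ]
        summaries = {s.arm: s for s in evaluate_arms(cases)}
        assert summaries["nlp_generated"].pairwise_p["rule_based"] == pytest.approx(1.0)

    def test_small_arm_flags_sd_and_p_undefined(self):
        report = tokenize("the lungs are clear.")
        cases = [
            ("nlp_generated", report, report),
            ("rule_based", report, report),
            ("rule_based", report, report),
        ]
        summaries = {s.arm: s for s in evaluate_arms(cases)}
        assert summaries["nlp_generated"].bleu_sd is None
        assert summaries["nlp_generated"].pairwise_p["rule_based"] is None

    def test_unknown_arm_rejected(self):
        report = tokenize("a.")
        with pytest.raises(ValueError):
            evaluate_arms([("bogus", report, report)])
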