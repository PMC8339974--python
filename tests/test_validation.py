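"""Crossvalidation harness, metric panel, McNemar's test."""

import numpy as np
import pytest
from scipy import stats

from amesread import MUTAGENIC, NON_MUTAGENIC
from amesread.validation import (
    ConfusionMatrix,
    PredictionOutcome,
    build_report,
    crossvalidate_lazar,
    kfold_split,
    mcnemar,
    metrics,
    roc_point,
)


class TestMetrics:
    def test_hand_arithmetic_panel(self):
        panel = metrics(ConfusionMatrix(tp=89, fn=11, tn=78, fp=22))
        assert panel["accuracy"] == pytest.approx(83.5)
        assert panel["tpr"] == pytest.approx(89.0)
        assert panel["tnr"] == pytest.approx(78.0)

    def test_perfect_classifier_all_hundred(self):
        panel = metrics(ConfusionMatrix(tp=10, tn=15))
        assert all(v == 100.0 for v in panel.values())

    def test_zero_denominator_reports_undefined(self):
        panel = metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert panel["ppv"] is None
        assert panel["tnr"] == 100.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1)


class TestRocPoint:
    def test_perfect_classifier_top_left(self):
        assert roc_point(ConfusionMatrix(tp=5, tn=5)) == (0.0, 1.0)

    def test_constant_positive_top_right(self):
        assert roc_point(ConfusionMatrix(tp=5, fp=5)) == (1.0, 1.0)

    def test_hand_example(self):
        fpr, tpr = roc_point(ConfusionMatrix(tp=89, fn=11, tn=78, fp=22))
        assert (fpr, tpr) == pytest.approx((0.22, 0.89))


class TestMcNemar:
    def test_balanced_discordance_statistic_zero_continuity(self):
        # b = c = 5 -> exact branch (n < 25); chi2 form would be (|0|-1)^2/10
        pred = [1] * 5 + [0] * 5 + [1, 0]
        act = [0] * 5 + [1] * 5 + [1, 0]
        _, p = mcnemar(pred, act)
        assert p == pytest.approx(1.0)

    def test_no_discordance_p_one(self):
        assert mcnemar([1, 0, 1], [1, 0, 1]) == (0.0, 1.0)

    def test_exact_binomial_oracle(self):
        # b=20, c=2 -> exact two-sided binomial p = 2 P(X<=2 | n=22, p=.5)
        pred = [1] * 20 + [0] * 2
        act = [0] * 20 + [1] * 2
        _, p = mcnemar(pred, act)
        assert p == pytest.approx(2 * stats.binom.cdf(2, 22, 0.5), rel=1e-12)

    def test_large_sample_chi2_branch(self):
        pred = [1] * 30 + [0] * 10
        act = [0] * 30 + [1] * 10
        statistic, p = mcnemar(pred, act)
        assert statistic == pytest.approx((abs(30 - 10) - 1) ** 2 / 40)
        assert p == pytest.approx(stats.chi2.sf(statistic, 1))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(5)
        for _ in range(10):
            pred = rng.integers(0, 2, 60)
            act = rng.integers(0, 2, 60)
            b = int(np.sum((pred == 1) & (act == 0)))
            c = int(np.sum((pred == 0) & (act == 1)))
            table = [[0, b], [c, 0]]
            exact = (b + c) < 25
            reference = sm_mcnemar(table, exact=exact, correction=True)
            _, p = mcnemar(pred, act)
            assert p == pytest.approx(reference.pvalue, rel=1e-9)


class TestKfoldSplit:
    def test_partition_properties(self):
        keys = [f"k{i}" for i in range(103)]
        folds = kfold_split(keys, k=10, seed=4)
        flat = [k for fold in folds for k in fold]
        assert sorted(flat) == sorted(keys)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_equal_sizes_when_divisible(self):
        folds = kfold_split([str(i) for i in range(100)], k=10, seed=0)
        assert all(len(f) == 10 for f in folds)

    def test_deterministic_given_seed(self):
        keys = [str(i) for i in range(50)]
        assert kfold_split(keys, 5, seed=9) == kfold_split(keys, 5, seed=9)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=3)


def _stub_rows(pairs):
    return [
        PredictionOutcome(f"k{i}", fold=i % 2, actual=a, predicted=p,
                          p_mutagenic=None, confidence="high")
        for i, (a, p) in enumerate(pairs)
    ]


class TestBuildReport:
    def test_perfect_stub_scores_hundred(self):
        rows = _stub_rows([(MUTAGENIC, MUTAGENIC)] * 5 + [(NON_MUTAGENIC, NON_MUTAGENIC)] * 5)
        report = build_report(rows, "stub")
        assert report.panel["accuracy"] == 100.0
        assert report.pooled.fp == report.pooled.fn == 0

    def test_constant_positive_stub_on_balanced_data(self):
        rows = _stub_rows([(MUTAGENIC, MUTAGENIC)] * 25 + [(NON_MUTAGENIC, MUTAGENIC)] * 25)
        report = build_report(rows, "stub")
        assert report.panel["accuracy"] == 50.0
        assert report.panel["tnr"] == 0.0

    def test_pooled_equals_sum_of_folds(self):
        rows = _stub_rows(
            [(MUTAGENIC, MUTAGENIC), (MUTAGENIC, NON_MUTAGENIC),
             (NON_MUTAGENIC, MUTAGENIC), (NON_MUTAGENIC, NON_MUTAGENIC)] * 6
        )
        report = build_report(rows, "stub")
        summed = sum(report.per_fold, ConfusionMatrix())
        assert summed == report.pooled

    def test_abstentions_counted_in_total_not_predictions(self):
        rows = _stub_rows([(MUTAGENIC, MUTAGENIC)] * 4)
        rows.append(
            PredictionOutcome("abst", 0, MUTAGENIC, None, None, "none")
        )
        report = build_report(rows, "stub")
        assert report.n_total == 5
        assert report.n_predictions == 4


class TestCrossvalidateLazar:
    def test_fingerprint_path_scores_every_measurement(self, small_fixture, small_fingerprints):
        dataset, _ = small_fixture
        rows = crossvalidate_lazar(dataset, fingerprints=small_fingerprints, k=5, seed=0)
        assert len(rows) == dataset.n_measurements

    def test_descriptor_path_runs_and_reports(self, small_fixture):
        dataset, descriptors = small_fixture
        rows = crossvalidate_lazar(dataset, descriptors=descriptors, k=5, seed=0)
        report = build_report(rows, "lazar-cdk")
        assert report.n_total == dataset.n_structures  # fixture has no conflicts
        assert report.n_predictions <= report.n_total

    def test_fold_membership_is_partition(self, small_fixture, small_fingerprints):
        dataset, _ = small_fixture
        rows = crossvalidate_lazar(dataset, fingerprints=small_fingerprints, k=5, seed=0)
        seen = {}
        for r in rows:
            assert seen.setdefault(r.key, r.fold) == r.fold
        assert set(seen) == set(dataset.keys())
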