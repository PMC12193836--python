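import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

from levywolf.gwo import GWOConfig
from levywolf.lgwo import LGWOConfig
from levywolf.metrics_stats import (
    classification_metrics,
    cohens_d,
    kfold_split,
    label_swap_metrics,
    macro_weighted,
    ranksum_p,
    run_trials,
    signed_rank_p,
)


def brute_force_auc(labels, scores):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0, 1])
        r = classification_metrics(y, y, y.astype(float))
        assert (r.accuracy, r.recall, r.precision, r.f1, r.auc) == (1, 1, 1, 1, 1)
        assert r.brier == 0.0
        assert (r.tp, r.tn, r.fp, r.fn) == (3, 2, 0, 0)

    def test_f1_is_harmonic_mean(self):
        # precision 0.88, recall 0.93 -> F1 = 2*0.88*0.93/1.81
        y = np.concatenate([np.ones(100), np.zeros(100)])
        # build predictions achieving tp=93, fn=7, fp=12 (precision ~0.8857)
        pred = np.concatenate([np.ones(93), np.zeros(7), np.ones(12), np.zeros(88)])
        r = classification_metrics(y, pred)
        assert r.recall == pytest.approx(0.93)
        assert r.f1 == pytest.approx(2 * r.precision * r.recall / (r.precision + r.recall))

    def test_pairwise_auc_example(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        assert classification_metrics(labels, labels, scores).auc == 0.75

    def test_auc_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 51)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            got = classification_metrics(labels, labels, scores).auc
            assert abs(got - brute_force_auc(labels, scores)) < 1e-12

    def test_auc_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=300)
        labels[0], labels[1] = 0, 1
        scores = rng.random(300)
        got = classification_metrics(labels, labels, scores).auc
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_prf_agree_with_sklearn(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=200)
        preds = rng.integers(0, 2, size=200)
        r = classification_metrics(labels, preds)
        assert r.precision == pytest.approx(precision_score(labels, preds))
        assert r.recall == pytest.approx(recall_score(labels, preds))
        assert r.f1 == pytest.approx(f1_score(labels, preds))

    def test_single_class_auc_missing_with_warning(self):
        with pytest.warns(UserWarning):
            r = classification_metrics(np.ones(5), np.ones(5), np.random.rand(5))
        assert r.auc is None

    @given(st.integers(1, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_fields_bounded_and_counts_reconcile(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        labels = rng.integers(0, 2, size=n)
        preds = rng.integers(0, 2, size=n)
        scores = rng.random(n)
        r = classification_metrics(labels, preds, scores)
        for v in (r.accuracy, r.recall, r.precision, r.f1, r.brier):
            assert 0.0 <= v <= 1.0
        assert r.n == n
        assert r.accuracy == pytest.approx((r.tp + r.tn) / n)


class TestLabelSwap:
    def test_accuracy_invariant_and_roles_swap(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=100)
        preds = rng.integers(0, 2, size=100)
        scores = rng.random(100)
        base = classification_metrics(labels, preds, scores)
        swap = label_swap_metrics(labels, preds, scores)
        assert swap.accuracy == base.accuracy
        assert (swap.tp, swap.tn) == (base.tn, base.tp)
        assert swap.auc == pytest.approx(base.auc, abs=1e-12)

    def test_degenerate_all_positive_predictions(self):
        labels = np.array([1, 0, 1, 0])
        preds = np.ones(4, dtype=int)
        assert label_swap_metrics(labels, preds).recall == 0.0


class TestMacroWeighted:
    def test_weighted_example_and_balanced_equality(self):
        a = classification_metrics([1, 0], [1, 0])
        b = classification_metrics([1, 0], [1, 0])
        a.f1, b.f1 = 0.8, 0.6
        macro, weighted = macro_weighted([a, b], [0.9, 0.1])
        assert weighted["f1"] == pytest.approx(0.78)
        assert macro["f1"] == pytest.approx(0.7)
        macro, weighted = macro_weighted([a, b], [0.5, 0.5])
        assert macro["f1"] == weighted["f1"]


class TestKFold:
    @pytest.mark.parametrize("n,k", [(10, 5), (23, 4), (7, 7)])
    def test_partition_invariants(self, n, k):
        folds = kfold_split(n, k, seed=1)
        assert len(folds) == k
        tests = [set(te.tolist()) for _, te in folds]
        union = set().union(*tests)
        assert union == set(range(n))
        sizes = sorted(len(t) for t in tests)
        assert sizes[-1] - sizes[0] <= 1
        for tr, te in folds:
            assert set(tr.tolist()) | set(te.tolist()) == set(range(n))
            assert not set(tr.tolist()) & set(te.tolist())

    def test_seeded_reproducibility_and_validation(self):
        assert all(
            np.array_equal(a[1], b[1])
            for a, b in zip(kfold_split(20, 5, seed=3), kfold_split(20, 5, seed=3))
        )
        with pytest.raises(ValueError):
            kfold_split(4, 5)


class TestRankSum:
    def test_fingerprint_tied_zeros_vs_distinct(self):
        p = ranksum_p(np.zeros(30), np.linspace(1, 2, 30))
        assert f"{p:.2E}" == "1.21E-12"

    def test_fingerprint_fully_separated_tie_free(self):
        p = ranksum_p(np.arange(30.0), np.arange(100.0, 130.0))
        assert f"{p:.2E}" == "3.02E-11"

    def test_identical_samples_give_one(self):
        assert ranksum_p([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.normal(size=rng.integers(5, 40))
            b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(5, 40))
            expected = ss.mannwhitneyu(a, b, method="asymptotic").pvalue
            assert ranksum_p(a, b) == pytest.approx(expected, rel=1e-10)

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=20)
        b = rng.normal(loc=0.5, size=25)
        assert ranksum_p(a, b) == ranksum_p(b, a)
        f = np.exp  # strictly monotone
        assert ranksum_p(f(a), f(b)) == pytest.approx(ranksum_p(a, b), rel=1e-12)


class TestSignedRank:
    def test_identical_pairs_give_one(self):
        a = np.arange(10.0)
        assert signed_rank_p(a, a) == 1.0

    def test_exact_small_sample_all_positive(self):
        assert signed_rank_p([1, 2, 3, 4, 5], [0, 0, 0, 0, 0]) == pytest.approx(0.0625)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=15)
        b = rng.normal(loc=0.3, size=15)
        assert signed_rank_p(a, b) == pytest.approx(signed_rank_p(b, a))

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(size=12)
            b = a + rng.normal(scale=0.5, size=12)
            expected = ss.wilcoxon(a, b, mode="exact").pvalue
            assert signed_rank_p(a, b) == pytest.approx(expected, rel=1e-9)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=40)
        b = a + rng.normal(loc=0.4, scale=0.5, size=40)
        expected = ss.wilcoxon(a, b, mode="approx", correction=True).pvalue
        assert signed_rank_p(a, b) == pytest.approx(expected, rel=1e-6)


class TestCohensD:
    def test_identical_samples_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a) == 0.0

    def test_degenerate_zero_spread_is_nan(self):
        assert np.isnan(cohens_d([0.0, 0.0], [1.0, 1.0]))

    def test_unit_effect_constructed_moments(self):
        # means 1 and 0, both sample sd exactly 1, equal n -> d = 1
        a = np.array([1.0 - np.sqrt(0.5), 1.0 + np.sqrt(0.5)])
        b = np.array([-np.sqrt(0.5), np.sqrt(0.5)])
        assert cohens_d(a, b) == pytest.approx(1.0)


class TestRunTrials:
    def test_single_run_and_degenerate_std(self):
        cfg = LGWOConfig(dim=2, n_agents=5, max_iter=10)
        table = run_trials(cfg, ["f14"], n_runs=1, base_seed=1)
        row = table.summary.iloc[0]
        assert row["best"] == row["mean"] and row["std"] == 0.0
        assert table.seeds == [1]

    def test_best_le_mean_and_seed_bookkeeping(self):
        cfg = GWOConfig(dim=2, n_agents=8, max_iter=20)
        table = run_trials(cfg, ["f14", "f15"], n_runs=4, base_seed=5)
        assert table.seeds == [5, 6, 7, 8]
        for _, row in table.summary.iterrows():
            assert row["best"] <= row["mean"]
            assert row["std"] >= 0
            finals = table.finals[row["function"]]
            assert np.std(finals, ddof=1) == pytest.approx(row["std"])
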