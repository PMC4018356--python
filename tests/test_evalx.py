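import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from fragbayes import evalx, nbayes
from fragbayes.errors import FitError, ParameterError
from fragbayes.evalx import ConfusionCounts, compute_metrics, round_half_up
from fragbayes.featurize.featureset import FeatureSet, FragmentKey


def fs(cid, *names):
    out = FeatureSet(cid)
    for n in names:
        out.add(FragmentKey("ACF", 1, n, True))
    return out


class TestComputeMetrics:
    def test_published_training_row(self):
        rep = compute_metrics(ConfusionCounts(637, 140, 143, 44))
        assert round_half_up(rep.SE) == 0.820
        assert round_half_up(rep.SP) == 0.765
        assert round_half_up(rep.Q_i) == 0.935
        assert round_half_up(rep.Q_ni) == 0.505
        assert round_half_up(rep.C) == 0.508

    def test_published_test_row(self):
        rep = compute_metrics(ConfusionCounts(215, 23, 58, 4))
        assert round_half_up(rep.C) == 0.765

    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (rep.SE, rep.SP, rep.Q_i, rep.Q_ni, rep.Q, rep.C) == (1, 1, 1, 1, 1, 1)

    def test_zero_denominator_flags_none(self):
        rep = compute_metrics(ConfusionCounts(0, 0, 5, 5))
        assert rep.SE is None
        assert rep.C == 0.0  # zero-factor convention

    def test_all_zero_errors(self):
        with pytest.raises(ParameterError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_label_swap_symmetry(self, rng):
        for _ in range(50):
            tp, fn, tn, fp = rng.integers(0, 50, size=4)
            if (tp + fn) == 0 or (tn + fp) == 0 or (tp + fp) == 0 or (tn + fn) == 0:
                continue
            a = compute_metrics(ConfusionCounts(int(tp), int(fn), int(tn), int(fp)))
            b = compute_metrics(ConfusionCounts(int(tn), int(fp), int(tp), int(fn)))
            assert a.C == pytest.approx(b.C)
            assert a.SE == pytest.approx(b.SP)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionCounts(-1, 0, 0, 1)

    @given(
        tp=st.integers(0, 200),
        fn=st.integers(0, 200),
        tn=st.integers(0, 200),
        fp=st.integers(0, 200),
    )
    def test_metric_ranges(self, tp, fn, tn, fp):
        if tp + fn + tn + fp == 0:
            return
        rep = compute_metrics(ConfusionCounts(tp, fn, tn, fp))
        for v in (rep.SE, rep.SP, rep.Q_i, rep.Q_ni, rep.Q):
            assert v is None or 0.0 <= v <= 1.0
        assert -1.0 <= rep.C <= 1.0
        # swap symmetry holds everywhere
        swapped = compute_metrics(ConfusionCounts(tn, fp, tp, fn))
        assert swapped.C == pytest.approx(rep.C)


class TestROC:
    def test_perfect_separation(self):
        roc = evalx.roc_auc([3.0, 2.0, -1.0, -2.0], [True, True, False, False])
        assert roc.auc == pytest.approx(1.0)
        assert roc.points[0] == (0.0, 0.0)
        assert roc.points[-1] == (1.0, 1.0)

    def test_all_tied_half(self):
        roc = evalx.roc_auc([1.0] * 6, [True, True, True, False, False, False])
        assert roc.auc == pytest.approx(0.5)

    def test_three_point_example(self):
        roc = evalx.roc_auc([1.0, 2.0, 3.0], [True, False, True])
        assert roc.auc == pytest.approx(0.5)

    def test_monotone_points(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        roc = evalx.roc_auc(scores, labels)
        xs = [p[0] for p in roc.points]
        ys = [p[1] for p in roc.points]
        assert xs == sorted(xs) and ys == sorted(ys)

    def test_pair_count_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.normal(size=n), 1)  # coarse -> ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            auc = evalx.roc_auc(scores, labels).auc
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = rng.normal(size=40)
            labels = rng.random(40) < 0.4
            labels[0], labels[1] = True, False
            assert evalx.roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_single_class_errors(self):
        with pytest.raises(ParameterError):
            evalx.roc_auc([1.0, 2.0], [True, True])


class TestCrossValidate:
    @staticmethod
    def _majority_trainer(train_feats, train_labels):
        maj = bool(np.mean(nbayes.as_binary_labels(train_labels)) >= 0.5)
        return lambda item: maj

    def test_fold_sizes(self):
        feats = list(range(100))
        labels = [i < 80 for i in range(100)]
        per_fold, pooled, _ = evalx.cross_validate(
            self._majority_trainer, feats, labels, k=5, seed=0
        )
        assert len(per_fold) == 5
        assert all(cc.total == 20 for cc, _ in per_fold)

    def test_pooled_is_sum_of_folds(self):
        feats = list(range(60))
        labels = [i % 3 != 0 for i in range(60)]
        per_fold, pooled, _ = evalx.cross_validate(
            self._majority_trainer, feats, labels, k=4, seed=1
        )
        assert pooled.TP == sum(cc.TP for cc, _ in per_fold)
        assert pooled.total == 60

    def test_majority_stub_metrics(self):
        feats = list(range(100))
        labels = [i < 80 for i in range(100)]
        _, _, rep = evalx.cross_validate(self._majority_trainer, feats, labels, k=5, seed=0)
        assert rep.SE == 1.0
        assert rep.SP == 0.0

    def test_stratified_infeasible_names_class(self):
        labels = [True] * 30 + [False] * 2
        with pytest.raises(ParameterError, match="non_inhibitor"):
            evalx.stratified_folds(labels, 5, seed=0)

    def test_folds_deterministic(self):
        labels = [i % 4 != 0 for i in range(40)]
        f1 = evalx.stratified_folds(labels, 5, seed=3)
        f2 = evalx.stratified_folds(labels, 5, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))


class TestLOOBayesScores:
    def test_three_compound_refit_oracle(self):
        sets = [fs("a", "f"), fs("b", "f"), fs("c", "g"), fs("d", "g"), fs("e", "f")]
        labels = [True, True, False, False, True]
        fast = evalx.loo_bayes_scores(sets, labels)
        for i in range(len(sets)):
            model = nbayes.fit(sets[:i] + sets[i + 1 :], labels[:i] + labels[i + 1 :])
            assert fast[i] == pytest.approx(nbayes.score(model, sets[i]).score, abs=1e-12)

    def test_unique_features_neutral(self):
        sets = [fs("u", "unique"), fs("a", "f"), fs("b", "f"), fs("c", "g"), fs("d", "g")]
        labels = [True, True, False, True, False]
        assert evalx.loo_bayes_scores(sets, labels)[0] == 0.0

    def test_duplicate_compound_sign_preserved(self):
        sets = [fs(f"a{i}", "f") for i in range(4)] + [fs(f"n{i}", "g") for i in range(3)]
        labels = [True] * 4 + [False] * 3
        scores = evalx.loo_bayes_scores(sets, labels)
        assert scores[0] > 0  # twin actives keep the evidence positive
        assert scores[-1] < 0


class TestStatistics:
    def test_welch_identical_samples(self):
        t, p = evalx.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_known_value(self):
        t, p = evalx.welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0)
        # df = 8 for equal variances/sizes; p from the t distribution
        assert p == pytest.approx(2 * sps.t.sf(1.0, 8), rel=1e-6)

    def test_welch_antisymmetric(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(loc=0.5, size=9)
        t1, p1 = evalx.welch_t_test(x, y)
        t2, p2 = evalx.welch_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_welch_degenerate_errors(self):
        with pytest.raises(ParameterError):
            evalx.welch_t_test([1.0, 1.0], [2.0, 2.0])

    def test_pooled_flag(self):
        x = [1.0, 2.0, 3.0, 9.0]
        y = [2.0, 2.5, 3.5]
        t_w, _ = evalx.welch_t_test(x, y)
        t_p, _ = evalx.welch_t_test(x, y, pooled=True)
        assert t_w != t_p

    def test_pearson_perfect(self):
        assert evalx.pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert evalx.pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_pearson_hand_computed(self):
        assert evalx.pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9819805, abs=1e-6)

    def test_pearson_zero_variance_errors(self):
        with pytest.raises(ParameterError):
            evalx.pearson_r([1, 1, 1], [1, 2, 3])


class TestRounding:
    def test_half_up(self):
        assert round_half_up(0.5075, 3) == 0.508
        assert round_half_up(0.7645, 3) == 0.765
        assert round_half_up(0.9075, 1) == 0.9


def test_metrics_table_export(tmp_path):
    cc = ConfusionCounts(637, 140, 143, 44)
    rep = compute_metrics(cc)
    path = tmp_path / "metrics.tsv"
    evalx.write_metrics_table(path, {"RP/MP/training": (cc, rep)})
    lines = path.read_text().strip().split("\n")
    assert lines[0].split("\t")[1:5] == ["TP", "FN", "TN", "FP"]
    assert lines[1].split("\t")[1:5] == ["637", "140", "143", "44"]
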