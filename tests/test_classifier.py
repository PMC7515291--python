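"""Redundancy filtering, balanced down-sampling, the shallow bagged network
and its evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dpiscope.classifier import (
    BaggedModel,
    LabeledFeatureMatrix,
    cross_validate,
    downsample_balanced,
    evaluate,
    pairwise_identity,
    redundancy_filter,
    split_holdout,
    train_ann,
    train_bagged,
)
from dpiscope.core_io import ProteinRecord


def _seq_record(pid, seq):
    return ProteinRecord(id=pid, length=len(seq), sequence=seq)


def _random_seqs(n, length, seed):
    rng = np.random.default_rng(seed)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return ["".join(letters[rng.integers(0, 20, length)]) for _ in range(n)]


class TestRedundancyFilter:
    def test_identical_pair_keeps_first_by_length_then_id(self):
        recs = [_seq_record("B", "ACDEFGHIKL"), _seq_record("A", "ACDEFGHIKL")]
        assert redundancy_filter(recs) == ["A"]

    def test_dissimilar_sequences_all_survive(self):
        seqs = _random_seqs(6, 60, seed=0)
        recs = [_seq_record(f"P{i}", s) for i, s in enumerate(seqs)]
        # random 60-mers over 20 letters sit near ~25% pairwise identity
        assert len(redundancy_filter(recs)) == 6

    def test_planted_family_collapses_to_one(self):
        from dpiscope.synthetic_data import plant_homolog_family

        seqs = _random_seqs(20, 80, seed=1)
        recs = [_seq_record(f"P{i:02d}", s) for i, s in enumerate(seqs)]
        plant_homolog_family(recs, ["P00", "P01", "P02"], identity=0.95, seed=2)
        survivors = redundancy_filter(recs)
        assert len(survivors) == 18
        assert len({"P00", "P01", "P02"} & set(survivors)) == 1

    def test_missing_sequence_raises(self):
        with pytest.raises(ValueError, match="P1"):
            redundancy_filter([ProteinRecord(id="P1", length=5)])

    def test_thresholds_must_descend(self):
        recs = [_seq_record("A", "ACDEF")]
        with pytest.raises(ValueError):
            redundancy_filter(recs, thresholds=(0.4, 0.9))

    def test_identity_is_matches_over_alignment_length(self):
        assert pairwise_identity("ACDEF", "ACDEF") == 1.0
        assert pairwise_identity("AAAA", "CCCC") < 0.5


def _toy_matrix(n=200, seed=0, sep=2.0, d_extra=2):
    """1-D separable signal plus noise features."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = np.where(y == 1, 1.0, -1.0) * sep / 2 + rng.normal(0, 0.3, n)
    X = pd.DataFrame({"x": x})
    for j in range(d_extra):
        X[f"n{j}"] = rng.normal(size=n)
    return LabeledFeatureMatrix(X, pd.Series(y))


class TestDownsample:
    def test_imbalanced_becomes_balanced(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.normal(size=110)})
        y = pd.Series([1] * 10 + [0] * 100)
        bal = downsample_balanced(LabeledFeatureMatrix(X, y), seed=1)
        assert len(bal.X) == 20 and bal.y.sum() == 10

    def test_balanced_input_unchanged_up_to_order(self):
        m = _toy_matrix(40)
        bal = downsample_balanced(m, seed=2)
        assert sorted(bal.X.index) == sorted(m.X.index)

    def test_majority_rows_drawn_uniformly(self):
        y = pd.Series([1] * 5 + [0] * 50)
        X = pd.DataFrame({"f": np.arange(55.0)})
        m = LabeledFeatureMatrix(X, y)
        hits = np.zeros(50)
        for seed in range(200):
            bal = downsample_balanced(m, seed=seed)
            for idx in bal.X.index:
                if idx >= 5:
                    hits[idx - 5] += 1
        # each majority row expected 200 * 5/50 = 20 times
        chi = ((hits - 20.0) ** 2 / 20.0).sum()
        assert stats.chi2.sf(chi, df=49) > 0.01

    def test_empty_class_raises(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            downsample_balanced(LabeledFeatureMatrix(X, pd.Series([1, 1])), 0)


class TestTrainAnn:
    def test_separable_toy_high_training_accuracy(self):
        m = _toy_matrix(200, sep=2.0)
        net = train_ann(m, hidden_units=10, epochs=100, seed=0)
        p = net.predict_proba(m.X.to_numpy(float))
        acc = ((p > 0.5).astype(int) == m.y.to_numpy()).mean()
        assert acc >= 0.99

    def test_single_class_raises(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            train_ann(LabeledFeatureMatrix(X, pd.Series([1, 1, 1])), epochs=2)

    def test_same_seed_bitwise_identical(self):
        m = _toy_matrix(80)
        n1 = train_ann(m, hidden_units=8, epochs=20, seed=5)
        n2 = train_ann(m, hidden_units=8, epochs=20, seed=5)
        assert np.array_equal(n1.W1, n2.W1) and np.array_equal(n1.w2, n2.w2)

    def test_training_loss_decreases_on_toy(self):
        m = _toy_matrix(200)
        net = train_ann(m, hidden_units=10, epochs=50, seed=1, validation_fraction=0)
        assert net.loss_curve[-1] < net.loss_curve[0]

    def test_standardization_from_training_rows_only(self):
        m = _toy_matrix(100)
        net = train_ann(m, epochs=2, seed=0, validation_fraction=0)
        assert np.allclose(net.mu, m.X.to_numpy(float).mean(axis=0))
        assert np.allclose(
            net.sd, np.where(m.X.std(ddof=0) == 0, 1, m.X.std(ddof=0))
        )


class _ConstNet:
    """Stub network emitting a fixed probability (duck-types Network)."""

    def __init__(self, p, names=("x",)):
        self.p = p
        self.feature_names = list(names)

    def predict_proba(self, X):
        return np.full(len(X), self.p)


class TestBaggedPredict:
    def _X(self, n=4):
        return pd.DataFrame({"x": np.zeros(n)})

    def test_unanimous_networks(self):
        model = BaggedModel([_ConstNet(0.9), _ConstNet(0.9)])
        assert np.allclose(model.predict(self._X()), 0.9)

    def test_confidence_weighting_ignores_abstainer(self):
        # p = [0.5, 0.9] -> weights [0, 0.8] -> ensemble 0.9
        model = BaggedModel([_ConstNet(0.5), _ConstNet(0.9)])
        assert np.allclose(model.predict(self._X()), 0.9)

    def test_all_abstaining_returns_half(self):
        model = BaggedModel([_ConstNet(0.5), _ConstNet(0.5)])
        assert np.allclose(model.predict(self._X()), 0.5)

    def test_zero_reliability_duplicate_is_ignored(self):
        base = BaggedModel([_ConstNet(0.8)])
        dup = BaggedModel([_ConstNet(0.8), _ConstNet(0.5)])
        X = self._X(6)
        assert np.allclose(base.predict(X), dup.predict(X))

    def test_unknown_feature_raises(self):
        model = BaggedModel([_ConstNet(0.8, names=("missing",))])
        with pytest.raises(KeyError):
            model.predict(pd.DataFrame({"x": [0.0]}))

    def test_single_bag_reduces_to_network(self):
        m = _toy_matrix(100)
        model = train_bagged(m, n_bags=1, seed=3, epochs=30)
        X = m.X
        single = model.networks[0].predict_proba(X.to_numpy(float))
        assert np.allclose(model.predict(X), np.where(single == 0.5, 0.5, single))

    def test_distinct_seeds_distinct_bags(self):
        m = _toy_matrix(100)
        m1 = train_bagged(m, n_bags=2, seed=1, epochs=5)
        m2 = train_bagged(m, n_bags=2, seed=2, epochs=5)
        assert not np.array_equal(m1.networks[0].W1, m2.networks[0].W1)


class TestEvaluate:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        rep = evaluate(scores, labels)
        assert rep.mcc == 1.0 and rep.bac == 1.0 and rep.auc == 1.0
        assert rep.roc[0] == (0.0, 0.0) and rep.roc[-1] == (1.0, 1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(7)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert evaluate(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n_pos, n_neg = rng.integers(3, 30, 2)
            scores = np.round(rng.random(n_pos + n_neg), 1)  # force ties
            labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
            u = stats.mannwhitneyu(
                scores[labels == 1], scores[labels == 0], alternative="two-sided"
            ).statistic
            assert evaluate(scores, labels).auc == pytest.approx(
                u / (n_pos * n_neg), abs=1e-12
            )

    def test_roc_is_monotone(self):
        rng = np.random.default_rng(9)
        scores, labels = rng.random(50), rng.integers(0, 2, 50)
        roc = evaluate(scores, labels).roc
        fpr, tpr = zip(*roc)
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))


class TestCrossValidation:
    def test_separable_data_high_auc(self):
        m = _toy_matrix(240, sep=2.5)
        rep = cross_validate(m, folds=5, seed=0, n_bags=3, epochs=60)
        assert rep.mean["auc"] >= 0.95

    def test_permuted_labels_chance_auc(self):
        rng = np.random.default_rng(10)
        m = _toy_matrix(240, sep=2.5)
        perm = LabeledFeatureMatrix(
            m.X, pd.Series(rng.permutation(m.y.to_numpy()), index=m.y.index)
        )
        rep = cross_validate(perm, folds=5, seed=0, n_bags=3, epochs=40)
        assert 0.4 <= rep.mean["auc"] <= 0.6

    def test_folds_cannot_exceed_minority(self):
        m = _toy_matrix(20)
        with pytest.raises(ValueError):
            cross_validate(m, folds=11)

    def test_holdout_is_stratified_partition(self):
        m = _toy_matrix(100)
        tr, te = split_holdout(m, fraction=0.2, seed=0)
        assert len(te.X) == 20
        assert sorted(list(tr.X.index) + list(te.X.index)) == sorted(m.X.index)
        assert te.y.mean() == pytest.approx(m.y.mean(), abs=0.05)
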