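import itertools
import math

import numpy as np
import pytest

from mlocmrna.ensemble import RFParams
from mlocmrna.io import BinaryDataset, SequenceRecord
from mlocmrna.metrics import (
    ConfusionCounts,
    confusion,
    crossvalidate,
    crossvalidate_xy,
    kmer_ablation,
    mcc_ratio_form,
    point_metrics,
    roc_pr_curves,
)


def pair_counting_auc(y_true, scores):
    """Concordance oracle: fraction of (pos, neg) pairs ranked correctly."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_enumerated_counts(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.n_pos, c.n_neg, c.fn, c.fp) == (2, 2, 1, 1)

    def test_perfect(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fn == 0 and c.fp == 0

    def test_all_positive_prediction(self):
        c = confusion([1, 0, 0], [1, 1, 1])
        assert c.fp == c.n_neg and c.fn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestPointMetrics:
    def test_perfect_prediction(self):
        m = point_metrics(ConfusionCounts(5, 5, 0, 0))
        assert m["sensitivity"] == m["specificity"] == m["accuracy"] == 1
        assert m["mcc"] == 1 and m["f1"] == 1

    def test_total_inversion(self):
        m = point_metrics(ConfusionCounts(3, 3, 3, 3))
        assert m["mcc"] == -1

    def test_worked_example(self):
        m = point_metrics(ConfusionCounts(4, 6, 1, 2))
        assert m["mcc"] == pytest.approx(10 / math.sqrt(600))
        assert m["f1"] == pytest.approx(3 / 4.5)

    def test_undefined_reported_missing(self):
        with pytest.warns(UserWarning):
            m = point_metrics(ConfusionCounts(0, 4, 0, 0))
        assert m["sensitivity"] is None

    def test_accuracy_identity(self):
        # accuracy = (Sn*n_pos + Sp*n_neg) / (n_pos + n_neg)
        for n_pos, n_neg, fn, fp in [(4, 6, 1, 2), (10, 3, 0, 1), (5, 5, 2, 2)]:
            m = point_metrics(ConfusionCounts(n_pos, n_neg, fn, fp))
            lhs = m["accuracy"]
            rhs = (m["sensitivity"] * n_pos + m["specificity"] * n_neg) / (n_pos + n_neg)
            assert lhs == pytest.approx(rhs)

    def test_ratio_form_matches_standard_exhaustively(self):
        """The per-class-rate rearrangement of MCC equals the standard form
        on every confusion table with up to 6 per class."""
        for n_pos, n_neg in itertools.product(range(1, 7), repeat=2):
            for fn, fp in itertools.product(range(n_pos + 1), range(n_neg + 1)):
                c = ConfusionCounts(n_pos, n_neg, fn, fp)
                denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
                if denom == 0:
                    continue
                standard = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
                assert mcc_ratio_form(c) == pytest.approx(standard, abs=1e-12)


class TestCurves:
    def test_perfect_ranking(self):
        roc, _ = roc_pr_curves([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert roc.area == 1.0
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)

    def test_constant_scores(self):
        roc, _ = roc_pr_curves([0, 1, 0, 1], [0.5] * 4)
        assert roc.area == pytest.approx(0.5)

    def test_derived_interleaved_example(self):
        roc, _ = roc_pr_curves([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1])
        assert roc.area == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(25):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            scores = np.round(rng.random(n), 2)  # induce some ties
            roc, _ = roc_pr_curves(y, scores)
            assert roc.area == pytest.approx(pair_counting_auc(y, scores))

    def test_exchangeable_scores_chance_level(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(200):
            y = np.array([1] * 10 + [0] * 10)
            aucs.append(roc_pr_curves(y, rng.random(20))[0].area)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves([1, 1, 1], [0.1, 0.2, 0.3])


def _binary_dataset(n_pos=20, n_neg=40, signal=True, seed=0):
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    for i in range(n_pos):
        core = "CGATCGATCGAT" if signal else ""
        seq = "".join(rng.choice(list("ACGT"), size=60)) + core
        pos.append(SequenceRecord(f"p{i}", seq, frozenset({"nucleus"})))
    for i in range(n_neg):
        neg.append(SequenceRecord(
            f"n{i}", "".join(rng.choice(list("ACGT"), size=70)),
            frozenset({"cytoplasm"})))
    return BinaryDataset("nucleus", pos, neg)


class TestCrossvalidate:
    def test_signal_dataset_beats_chance(self):
        bd = _binary_dataset(signal=True)
        rep = crossvalidate(bd, ["CGAT", "GATC", "ATCG", "TCGA"],
                            RFParams(ntree=30, seed=0), folds=4, seed=0, k_max=4)
        assert rep.means["accuracy"] > 80
        assert rep.means["auc_roc"] > 90
        assert rep.folds == 4

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 6))
        y = np.array([1] * 40 + [0] * 40)
        rep = crossvalidate_xy(X, y, RFParams(ntree=30, seed=1), folds=4, seed=1)
        assert abs(rep.means["accuracy"] - 50) < 12

    def test_deterministic(self):
        bd = _binary_dataset()
        kw = dict(params=RFParams(ntree=10, seed=3), folds=3, seed=3, k_max=2)
        a = crossvalidate(bd, ["AC", "GT", "CG"], **kw)
        b = crossvalidate(bd, ["AC", "GT", "CG"], **kw)
        assert a.means == b.means and a.sds == b.sds

    def test_too_few_per_class(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        y = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            crossvalidate_xy(X, y, RFParams(ntree=5), folds=5)


class TestAblation:
    def test_feature_counts_per_k(self):
        bd = _binary_dataset(n_pos=12, n_neg=24)
        tab = kmer_ablation(bd, k_values=(1, 2), params=RFParams(ntree=10, seed=0),
                            folds=3)
        assert tab.loc[1, "n_features"] == 4
        assert tab.loc[2, "n_features"] == 16

    def test_signal_peaks_at_planted_k(self):
        # planted signal is a repeated 4-mer pattern: k=4 should beat k=1
        bd = _binary_dataset(n_pos=20, n_neg=40, signal=True, seed=4)
        tab = kmer_ablation(bd, k_values=(1, 4), params=RFParams(ntree=30, seed=0),
                            folds=4)
        assert tab.loc[4, "auc_roc"] > tab.loc[1, "auc_roc"]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_ablation(_binary_dataset(), k_values=(0,))
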