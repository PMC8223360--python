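import numpy as np
import pytest

from mlocmrna.ensemble import (
    BalancedForestEnsemble,
    MultiLocalizationClassifier,
    MultiLocModel,
    RFParams,
    predict_ensemble,
    predict_multilabel,
    train_member,
    train_multiloc,
)
from mlocmrna.io import LocalizationCatalog, SequenceRecord


class _StubMember:
    """Forest stand-in returning fixed positive-class probabilities."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        col = np.full(len(X), self.p)
        return np.column_stack([1 - col, col])


def stub_ensemble(probs):
    ens = BalancedForestEnsemble(n_members=len(probs))
    ens.members_ = [_StubMember(p) for p in probs]
    ens.n_features_in_ = 3
    ens.classes_ = np.array([0, 1])
    return ens


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    n_pos, n_neg = 30, 150
    X = rng.normal(size=(n_pos + n_neg, 6))
    X[:n_pos, 0] += 3.0
    y = np.array([1] * n_pos + [0] * n_neg)
    return X, y


class TestTrainMember:
    def test_balanced_training_set_size(self, separable):
        X, y = separable
        forest = train_member(X[y == 1], X[y == 0], RFParams(ntree=20), 1)
        # the forest saw 30 positives + 30 negatives
        assert forest.n_features_in_ == 6

    def test_negative_pool_too_small(self):
        with pytest.raises(ValueError):
            train_member(np.zeros((10, 2)), np.zeros((5, 2)), RFParams(ntree=5), 0)

    def test_default_mtry_is_floor_sqrt(self):
        assert int(np.sqrt(1812)) == 42  # the default rule at p=1812
        X = np.random.default_rng(0).normal(size=(40, 9))
        forest = train_member(X[:20], X[20:], RFParams(ntree=5), 3)
        assert forest.max_features == 3

    def test_distinct_seeds_distinct_subsamples(self, separable):
        X, y = separable
        rng_draws = [
            np.random.default_rng(s).choice(150, size=30, replace=False)
            for s in (1, 2)
        ]
        assert not np.array_equal(rng_draws[0], rng_draws[1])


class TestEnsemble:
    def test_five_members_trained(self, separable):
        X, y = separable
        ens = BalancedForestEnsemble(ntree=20, random_state=0).fit(X, y)
        assert len(ens.members_) == 5
        assert len(set(ens.member_seeds_)) == 5

    def test_vote_and_probability_rule(self):
        ens = stub_ensemble([0.9, 0.8, 0.6, 0.4, 0.3])
        proba, votes, call = predict_ensemble(ens, np.zeros((1, 3)))
        assert votes[0] == 3 and call[0]
        assert proba[0] == pytest.approx(0.6)

    def test_no_votes_no_call(self):
        ens = stub_ensemble([0.0] * 5)
        _, votes, call = predict_ensemble(ens, np.zeros((2, 3)))
        assert votes.tolist() == [0, 0] and not call.any()

    def test_two_of_five_is_no(self):
        ens = stub_ensemble([0.9, 0.7, 0.2, 0.1, 0.1])
        _, votes, call = predict_ensemble(ens, np.zeros((1, 3)))
        assert votes[0] == 2 and not call[0]

    def test_vote_probability_consistency(self, separable):
        X, y = separable
        ens = BalancedForestEnsemble(ntree=20, random_state=1).fit(X, y)
        member_p = ens.member_proba(X)
        calls = ens.predict(X).astype(bool)
        all_yes = (member_p >= 0.5).all(axis=1)
        all_no = (member_p < 0.5).all(axis=1)
        assert calls[all_yes].all()
        assert not calls[all_no].any()

    def test_feature_mismatch_rejected(self, separable):
        X, y = separable
        ens = BalancedForestEnsemble(ntree=10, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            ens.predict(X[:, :4])

    def test_equal_pool_warns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.array([1] * 10 + [0] * 10)
        with pytest.warns(UserWarning, match="same negatives"):
            BalancedForestEnsemble(ntree=5, random_state=0).fit(X, y)

    def test_determinism(self, separable):
        X, y = separable
        a = BalancedForestEnsemble(ntree=20, random_state=9).fit(X, y)
        b = BalancedForestEnsemble(ntree=20, random_state=9).fit(X, y)
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))


def _records_for(catalog, n_per=8, seed=0):
    rng = np.random.default_rng(seed)
    recs = {}
    for loc in catalog.names:
        recs[loc] = [
            SequenceRecord(f"{loc}_{i}",
                           "".join(rng.choice(list("ACGT"), size=60)),
                           frozenset({loc}))
            for i in range(n_per)
        ]
    return recs


class TestMultiLoc:
    @pytest.fixture(scope="class")
    def model(self):
        from mlocmrna.io import assemble_binary_datasets

        catalog = LocalizationCatalog(("nucleus", "cytoplasm", "ribosome"))
        per = _records_for(catalog)
        binary = assemble_binary_datasets(per, catalog)
        features = ["A", "C", "G", "T", "AC", "GT"]
        return train_multiloc(binary, features,
                              RFParams(ntree=10, seed=0), k_max=2), catalog

    def test_one_ensemble_per_localization(self, model):
        m, catalog = model
        assert set(m.ensembles) == set(catalog.names)

    def test_missing_dataset_rejected(self):
        from mlocmrna.io import assemble_binary_datasets

        catalog = LocalizationCatalog(("nucleus", "cytoplasm", "ribosome"))
        per = _records_for(catalog)
        binary = assemble_binary_datasets(per, catalog)[:2]
        with pytest.raises(ValueError, match="ribosome"):
            train_multiloc(binary, ["A", "C"], RFParams(ntree=5), k_max=1,
                           catalog=catalog)

    def test_multilabel_prediction_columns(self, model):
        m, catalog = model
        recs = [SequenceRecord("q1", "ACGT" * 20)]
        df = predict_multilabel(m, recs)
        assert df.shape[0] == 1
        for loc in catalog.names:
            assert f"prob_{loc}" in df and f"call_{loc}" in df
            assert 0 <= df[f"prob_{loc}"].iloc[0] <= 1
        assert df["unassigned"].dtype == bool

    def test_calls_match_vote_threshold(self, model):
        m, catalog = model
        rng = np.random.default_rng(5)
        recs = [SequenceRecord(f"q{i}", "".join(rng.choice(list("ACGT"), 80)))
                for i in range(6)]
        df = predict_multilabel(m, recs)
        for loc in catalog.names:
            votes = df[f"votes_{loc}"].to_numpy()
            calls = df[f"call_{loc}"].to_numpy()
            assert np.array_equal(calls == "yes", votes >= 3)

    def test_empty_input_rejected(self, model):
        m, _ = model
        with pytest.raises(ValueError):
            predict_multilabel(m, [])

    def test_save_load_roundtrip(self, model, tmp_path):
        m, _ = model
        path = tmp_path / "model.joblib"
        m.save(path)
        loaded = MultiLocModel.load(path)
        recs = [SequenceRecord("q", "ACGTACGTAC" * 6)]
        assert predict_multilabel(loaded, recs).equals(predict_multilabel(m, recs))


def test_sklearn_multilabel_front_end(separable):
    X, y = separable
    y2 = np.roll(y, 40)  # second minority label, offset from the first
    Y = np.column_stack([y, y2])
    clf = MultiLocalizationClassifier(n_members=3, ntree=10, random_state=0,
                                      classes=["a", "b"])
    clf.fit(X, Y)
    P = clf.predict_proba(X)
    assert P.shape == (len(X), 2)
    pred = clf.predict(X)
    assert set(np.unique(pred)) <= {0, 1}
    params = clf.get_params()
    assert params["ntree"] == 10
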