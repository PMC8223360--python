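"""Class-balanced random-forest ensembles and the multi-label localizer.

Class imbalance in the one-vs-rest datasets (a location's positives against
the pooled 8 other locations) is countered by training 5 forests per
localization, each on all positives plus an equal-size negative subsample
drawn without replacement from a different seed. The final label is decided
by majority vote (>= 3 of 5 members); the reported probability is the mean
member probability, which can disagree with the vote near 0.5 — the vote is
authoritative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from ._seeds import derive_seed
from .io import LocalizationCatalog
from .kmer import KmerFeaturizer

logger = logging.getLogger(__name__)


@dataclass
class RFParams:
    """Forest hyperparameters: trees per member and features tried per split.

    ``mtry=None`` means the default floor(sqrt(p)).
    """

    ntree: int = 500
    mtry: int | None = None
    n_members: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


def train_member(pos_X, neg_X, params: RFParams, member_seed: int) -> RandomForestClassifier:
    """Train one forest on all positives plus an equal negative subsample."""
    pos_X = np.asarray(pos_X, dtype=float)
    neg_X = np.asarray(neg_X, dtype=float)
    n_pos = pos_X.shape[0]
    if neg_X.shape[0] < n_pos:
        raise ValueError(
            f"negative pool ({neg_X.shape[0]}) smaller than positive set ({n_pos})"
        )
    rng = np.random.default_rng(member_seed)
    neg_idx = rng.choice(neg_X.shape[0], size=n_pos, replace=False)
    X = np.vstack([pos_X, neg_X[neg_idx]])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)])
    assert (y == 1).sum() == (y == 0).sum(), "member training set must be balanced"
    mtry = params.mtry if params.mtry is not None else max(1, int(np.sqrt(X.shape[1])))
    forest = RandomForestClassifier(
        n_estimators=params.ntree, max_features=mtry, bootstrap=True,
        oob_score=True, random_state=member_seed % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB warning on tiny member sets
        forest.fit(X, y)
    if getattr(forest, "oob_score_", None) is not None:
        logger.info("member seed=%d OOB accuracy=%.3f", member_seed, forest.oob_score_)
    return forest


class BalancedForestEnsemble(ClassifierMixin, BaseEstimator):
    """Majority-voted ensemble of class-balanced random forests.

    Parameters
    ----------
    n_members : int
        Number of forests; each sees all positives and a distinct
        equal-size negative subsample (default 5).
    ntree : int
        Trees per forest (default 500).
    mtry : int or None
        Features tried per split; None means floor(sqrt(p)).
    random_state : int
        Master seed; member subsample seeds are derived from it.
    """

    def __init__(self, n_members: int = 5, ntree: int = 500, mtry=None,
                 random_state: int = 0):
        self.n_members = n_members
        self.ntree = ntree
        self.mtry = mtry
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly two classes, got {classes}")
        y01 = (y == classes.max()).astype(int)
        pos_X = X[y01 == 1]
        neg_X = X[y01 == 0]
        if pos_X.shape[0] == 0:
            raise ValueError("no positive instances")
        if neg_X.shape[0] == pos_X.shape[0]:
            warnings.warn(
                "negative pool equals positive count: all members see the same negatives"
            )
        params = RFParams(ntree=self.ntree, mtry=self.mtry,
                          n_members=self.n_members, seed=self.random_state)
        self.member_seeds_ = [
            derive_seed(self.random_state, "member", m) for m in range(self.n_members)
        ]
        self.members_ = [
            train_member(pos_X, neg_X, params, seed) for seed in self.member_seeds_
        ]
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, ensemble was fit with {self.n_features_in_}"
            )
        return X

    def member_proba(self, X) -> np.ndarray:
        """(n_samples, n_members) positive-class probabilities."""
        X = self._check_X(X)
        return np.column_stack([m.predict_proba(X)[:, 1] for m in self.members_])

    def vote_counts(self, X) -> np.ndarray:
        """Members voting positive (own probability >= 0.5) per sample."""
        return (self.member_proba(X) >= 0.5).sum(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        p = self.member_proba(X).mean(axis=1)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        """Majority vote: positive iff > half the members vote positive."""
        return (self.vote_counts(X) >= self.n_members // 2 + 1).astype(int)


def predict_ensemble(ens: BalancedForestEnsemble, X):
    """Per-row (mean probability, vote count, yes/no call)."""
    proba = ens.predict_proba(X)[:, 1]
    votes = ens.vote_counts(X)
    calls = votes >= ens.n_members // 2 + 1
    return proba, votes, calls


def train_balanced_ensemble(bd, feature_names, params: RFParams | None = None,
                            featurizer: KmerFeaturizer | None = None) -> BalancedForestEnsemble:
    """Train the 5-member ensemble for one one-vs-rest dataset of records."""
    if params is None:
        params = RFParams()
    if not bd.positives:
        raise ValueError(f"{bd.localization}: empty positive set")
    if featurizer is None:
        featurizer = KmerFeaturizer(vocabulary=list(feature_names)).fit()
    X_pos = featurizer.transform(bd.positives)
    X_neg = featurizer.transform(bd.negatives)
    ens = BalancedForestEnsemble(
        n_members=params.n_members, ntree=params.ntree, mtry=params.mtry,
        random_state=derive_seed(params.seed, "ensemble", bd.localization),
    )
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(bd.positives), int), np.zeros(len(bd.negatives), int)])
    ens.fit(X, y)
    ens.feature_names_ = list(feature_names)
    ens.localization_ = bd.localization
    return ens


SCHEMA_VERSION = 1


@dataclass
class MultiLocModel:
    """The full multi-label predictor: one balanced ensemble per localization.

    Records are featurized with the selected k-mer vocabulary and scored by
    all ensembles; every localization whose majority vote fires is called, so
    a sequence may receive zero, one, or several locations.
    """

    catalog: LocalizationCatalog
    featurizer: KmerFeaturizer
    ensembles: dict
    threshold: float = 0.5
    selection: object | None = None
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        missing = [n for n in self.catalog.names if n not in self.ensembles]
        if missing:
            raise ValueError(f"missing ensembles for: {missing}")

    def predict_records(self, records) -> pd.DataFrame:
        return predict_multilabel(self, records)

    def save(self, path):
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "MultiLocModel":
        import joblib

        model = joblib.load(path)
        if getattr(model, "schema_version", None) != SCHEMA_VERSION:
            raise ValueError(
                f"model schema version mismatch: expected {SCHEMA_VERSION}, "
                f"got {getattr(model, 'schema_version', None)}"
            )
        return model


def train_multiloc(binary_datasets, selection, params: RFParams | None = None,
                   k_min: int = 1, k_max: int = 6, mode: str = "frequency",
                   catalog: LocalizationCatalog | None = None) -> MultiLocModel:
    """Train one balanced ensemble per localization on the selected-feature union."""
    if params is None:
        params = RFParams()
    names = [bd.localization for bd in binary_datasets]
    if catalog is None:
        catalog = (LocalizationCatalog() if set(names) == set(LocalizationCatalog().names)
                   else LocalizationCatalog(tuple(names)))
    missing = [n for n in catalog.names if n not in names]
    if missing:
        raise ValueError(f"missing binary datasets for: {missing}")
    union = selection.union if hasattr(selection, "union") else list(selection)
    featurizer = KmerFeaturizer(k_min=k_min, k_max=k_max, mode=mode,
                                vocabulary=list(union)).fit()
    ensembles = {}
    for bd in binary_datasets:
        ensembles[bd.localization] = train_balanced_ensemble(
            bd, union, params, featurizer=featurizer
        )
    sel = selection if hasattr(selection, "union") else None
    return MultiLocModel(catalog=catalog, featurizer=featurizer,
                         ensembles=ensembles, selection=sel)


def predict_multilabel(model: MultiLocModel, records) -> pd.DataFrame:
    """Score records with all ensembles; one row per sequence.

    Columns: ``prob_<loc>`` (mean member probability), ``votes_<loc>``,
    ``call_<loc>`` (majority vote at the model threshold), and ``unassigned``
    for rows where no localization is called.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to predict")
    X = model.featurizer.transform(records)
    ids = [r.id if hasattr(r, "id") else f"seq{i}" for i, r in enumerate(records)]
    probs, votes_cols, call_cols = {}, {}, {}
    calls = []
    for name in model.catalog.names:
        ens = model.ensembles[name]
        proba, votes, call = predict_ensemble(ens, X)
        probs[f"prob_{name}"] = proba
        votes_cols[f"votes_{name}"] = votes
        calls.append(call)
        call_cols[f"call_{name}"] = np.where(call, "yes", "no")
    # server-style layout: all probabilities, then votes, then yes/no calls
    df = pd.DataFrame(probs | votes_cols | call_cols,
                      index=pd.Index(ids, name="seq_id"))
    df["unassigned"] = ~np.any(np.column_stack(calls), axis=1)
    return df


class MultiLocalizationClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn multi-label (binary relevance) front end.

    fit(X, Y) with Y an (n_samples, n_locations) 0/1 indicator trains one
    :class:`BalancedForestEnsemble` per column; predict returns the
    indicator of majority-vote calls.
    """

    def __init__(self, n_members: int = 5, ntree: int = 500, mtry=None,
                 threshold: float = 0.5, random_state: int = 0, classes=None):
        self.n_members = n_members
        self.ntree = ntree
        self.mtry = mtry
        self.threshold = threshold
        self.random_state = random_state
        self.classes = classes

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = pd.DataFrame(Y)
        names = (list(self.classes) if self.classes is not None
                 else [str(c) for c in Y.columns])
        self.class_names_ = names
        self.ensembles_ = {}
        for j, name in enumerate(names):
            ens = BalancedForestEnsemble(
                n_members=self.n_members, ntree=self.ntree, mtry=self.mtry,
                random_state=derive_seed(self.random_state, "ensemble", name),
            )
            ens.fit(X, Y.iloc[:, j].to_numpy())
            self.ensembles_[name] = ens
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        return np.column_stack(
            [self.ensembles_[n].predict_proba(X)[:, 1] for n in self.class_names_]
        )

    def predict(self, X) -> np.ndarray:
        return np.column_stack(
            [self.ensembles_[n].predict(X) for n in self.class_names_]
        )
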