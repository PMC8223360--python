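"""Evaluation: confusion-based point metrics, ROC/PR areas, CV protocol.

Point metrics (sensitivity, specificity, accuracy, MCC, F1) are computed from
majority-voted labels; aucROC/aucPR are computed per ensemble member and then
averaged over the members. Cross-validated reports give mean +/- standard
deviation across the folds, on the percent scale. Undefined metrics (an
empty class in the denominator) are reported as missing, never coerced to 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .ensemble import BalancedForestEnsemble, RFParams
from .kmer import KmerFeatureSpec, KmerFeaturizer

logger = logging.getLogger(__name__)

POINT_METRICS = ("sensitivity", "specificity", "accuracy", "mcc", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion in positives/negatives + misclassified counts."""

    n_pos: int
    n_neg: int
    fn: int  # positives misclassified negative
    fp: int  # negatives misclassified positive

    def __post_init__(self):
        if not (0 <= self.fn <= self.n_pos and 0 <= self.fp <= self.n_neg):
            raise ValueError(f"inconsistent counts: {self}")

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp


@dataclass(frozen=True)
class CurvePoints:
    kind: str  # "ROC" or "PR"
    points: tuple  # ordered (x, y) pairs
    area: float


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    return ConfusionCounts(n_pos, n_neg, fn, fp)


def point_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, MCC and F1 on the [0, 1] scale.

    A metric whose denominator vanishes is returned as None with a warning.
    """
    out: dict = {}
    out["sensitivity"] = c.tp / c.n_pos if c.n_pos else _undef("sensitivity")
    out["specificity"] = c.tn / c.n_neg if c.n_neg else _undef("specificity")
    total = c.n_pos + c.n_neg
    out["accuracy"] = (c.tp + c.tn) / total if total else _undef("accuracy")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom > 0:
        out["mcc"] = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        out["mcc"] = _undef("mcc")
    f1_denom = c.tp + 0.5 * (c.fp + c.fn)
    out["f1"] = c.tp / f1_denom if f1_denom else _undef("f1")
    return out


def _undef(name: str):
    warnings.warn(f"{name} undefined (zero denominator); reported as missing")
    return None


def mcc_ratio_form(c: ConfusionCounts) -> float:
    """MCC in its per-class-rate rearrangement.

    numerator 1 - (fn/N+ + fp/N-), denominator
    sqrt((1 + (fp - fn)/N+)(1 + (fn - fp)/N-)); algebraically identical to
    the standard confusion-matrix form whenever both are defined.
    """
    num = 1.0 - (c.fn / c.n_pos + c.fp / c.n_neg)
    d1 = 1.0 + (c.fp - c.fn) / c.n_pos
    d2 = 1.0 + (c.fn - c.fp) / c.n_neg
    if d1 <= 0 or d2 <= 0:
        raise ZeroDivisionError("ratio-form MCC undefined for this table")
    return num / math.sqrt(d1 * d2)


def roc_pr_curves(y_true, scores):
    """ROC and PR curves with trapezoidal areas.

    ROC is the standard threshold sweep from (0,0) to (1,1). The PR area is
    the plain trapezoid over the (recall, precision) points — no precision
    envelope / step interpolation is applied.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    if np.unique(y_true).size < 2:
        raise ValueError("both classes must be present to draw curves")
    fpr, tpr, _ = roc_curve(y_true, scores)
    roc = CurvePoints("ROC", tuple(zip(fpr.tolist(), tpr.tolist())),
                      float(auc(fpr, tpr)))
    precision, recall, _ = precision_recall_curve(y_true, scores)
    # precision_recall_curve returns recall descending; integrate ascending
    order = np.argsort(recall)
    pr_area = float(np.trapezoid(precision[order], recall[order]))
    pr = CurvePoints("PR", tuple(zip(recall.tolist(), precision.tolist())), pr_area)
    return roc, pr


def auc_roc(y_true, scores) -> float:
    return roc_pr_curves(y_true, scores)[0].area


@dataclass
class MetricsReport:
    """Mean +/- sd of the point metrics over folds, percent scale, plus
    member-averaged aucROC/aucPR (also percent)."""

    localization: str
    means: dict
    sds: dict
    n_pos: int
    n_neg: int
    folds: int

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for m in list(POINT_METRICS) + ["auc_roc", "auc_pr"]:
            rows[m] = {"mean": self.means.get(m), "sd": self.sds.get(m)}
        return pd.DataFrame(rows).T


def _fold_member_aucs(ens: BalancedForestEnsemble, X_test, y_test):
    """Per-member aucROC and aucPR on a held-out set, averaged over members."""
    member_p = ens.member_proba(X_test)
    rocs, prs = [], []
    for m in range(member_p.shape[1]):
        roc, pr = roc_pr_curves(y_test, member_p[:, m])
        rocs.append(roc.area)
        prs.append(pr.area)
    return float(np.mean(rocs)), float(np.mean(prs))


def crossvalidate_xy(X, y, params: RFParams | None = None, folds: int = 5,
                     seed: int = 0, localization: str = "") -> MetricsReport:
    """Stratified k-fold CV of the balanced ensemble on a feature matrix."""
    if params is None:
        params = RFParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if (y == 1).sum() < folds or (y == 0).sum() < folds:
        raise ValueError("each class must have at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = {m: [] for m in POINT_METRICS}
    roc_areas, pr_areas = [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("fold with a single class")
        ens = BalancedForestEnsemble(
            n_members=params.n_members, ntree=params.ntree, mtry=params.mtry,
            random_state=derive_seed(params.seed, "cv", localization, fold),
        )
        ens.fit(X[tr], y[tr])
        y_pred = ens.predict(X[te])
        pm = point_metrics(confusion(y[te], y_pred))
        for m in POINT_METRICS:
            if pm[m] is not None:
                per_fold[m].append(pm[m])
        r, p = _fold_member_aucs(ens, X[te], y[te])
        roc_areas.append(r)
        pr_areas.append(p)
    means = {m: 100 * float(np.mean(v)) if v else None for m, v in per_fold.items()}
    sds = {m: 100 * float(np.std(v)) if v else None for m, v in per_fold.items()}
    means["auc_roc"] = 100 * float(np.mean(roc_areas))
    sds["auc_roc"] = 100 * float(np.std(roc_areas))
    means["auc_pr"] = 100 * float(np.mean(pr_areas))
    sds["auc_pr"] = 100 * float(np.std(pr_areas))
    return MetricsReport(localization, means, sds,
                         int((y == 1).sum()), int((y == 0).sum()), folds)


def crossvalidate(bd, selection, params: RFParams | None = None, folds: int = 5,
                  seed: int = 0, k_min: int = 1, k_max: int = 6,
                  mode: str = "frequency") -> MetricsReport:
    """Five-fold CV of one one-vs-rest dataset using the selected features."""
    union = selection.union if hasattr(selection, "union") else list(selection)
    featurizer = KmerFeaturizer(k_min=k_min, k_max=k_max, mode=mode,
                                vocabulary=list(union)).fit()
    X = np.vstack([featurizer.transform(bd.positives),
                   featurizer.transform(bd.negatives)])
    y = np.concatenate([np.ones(len(bd.positives), int),
                        np.zeros(len(bd.negatives), int)])
    if params is None:
        params = RFParams()
    params = RFParams(ntree=params.ntree, mtry=params.mtry,
                      n_members=params.n_members,
                      seed=derive_seed(params.seed, "crossvalidate", bd.localization))
    return crossvalidate_xy(X, y, params, folds=folds, seed=seed,
                            localization=bd.localization)


def evaluate_independent(model, independent, training_ids=None) -> pd.DataFrame:
    """Score an independent set through all ensembles, one report row per location.

    For location L, positives are L's independent records and negatives are
    every other location's records (imbalanced by construction). When
    ``training_ids`` is given, any overlap with the independent ids is an
    error.
    """
    records = list(independent.records)
    if training_ids is not None:
        clash = sorted({r.id for r in records} & set(training_ids))
        if clash:
            raise ValueError(f"independent set shares ids with training: {clash[:10]}")
    X = model.featurizer.transform(records)
    rows = {}
    for name in model.catalog.names:
        y_true = np.array([1 if name in r.labels else 0 for r in records])
        if y_true.sum() == 0:
            logger.warning("%s: no positives in independent set", name)
            rows[name] = {m: None for m in POINT_METRICS} | {
                "auc_roc": None, "auc_pr": None, "n_pos": 0,
                "n_neg": int(len(records)), "note": "no positives",
            }
            continue
        ens = model.ensembles[name]
        y_pred = ens.predict(X)
        pm = point_metrics(confusion(y_true, y_pred))
        r, p = _fold_member_aucs(ens, X, y_true)
        rows[name] = {m: (100 * v if v is not None else None) for m, v in pm.items()}
        rows[name]["auc_roc"] = 100 * r
        rows[name]["auc_pr"] = 100 * p
        rows[name]["n_pos"] = int(y_true.sum())
        rows[name]["n_neg"] = int(len(records) - y_true.sum())
        rows[name]["note"] = ""
    return pd.DataFrame(rows).T


def kmer_ablation(bd, k_values=(1, 2, 3, 4, 5, 6), params: RFParams | None = None,
                  folds: int = 5, seed: int = 0, mode: str = "frequency") -> pd.DataFrame:
    """Per-k CV performance using each single k-block as the feature set."""
    if any(k < 1 or k > 8 for k in k_values):
        raise ValueError("k values must be within 1..8")
    if params is None:
        params = RFParams()
    records = list(bd.positives) + list(bd.negatives)
    y = np.concatenate([np.ones(len(bd.positives), int),
                        np.zeros(len(bd.negatives), int)])
    out = {}
    for k in sorted(k_values):
        spec = KmerFeatureSpec(k, k, mode)
        featurizer = KmerFeaturizer(k_min=k, k_max=k, mode=mode).fit()
        X = featurizer.transform(records)
        rep = crossvalidate_xy(
            X, y,
            RFParams(ntree=params.ntree, mtry=params.mtry,
                     n_members=params.n_members,
                     seed=derive_seed(params.seed, "ablation", bd.localization, k)),
            folds=folds, seed=seed, localization=bd.localization,
        )
        out[k] = {"n_features": spec.n_features,
                  "auc_roc": rep.means["auc_roc"], "auc_pr": rep.means["auc_pr"]}
    return pd.DataFrame(out).T
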