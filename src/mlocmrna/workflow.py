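"""End-to-end workflow: prepare -> select -> train -> evaluate.

These functions chain the library stages behind a single run configuration
and one master seed; the command-line tool is a thin shell over them. Stage
seeds are derived from the master seed and the stage/localization names, so
any stage can be re-run in isolation and reproduce its outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from ._seeds import derive_seed
from .elastic_net import DEFAULT_ALPHA_GRID, ElasticNetSelector, union_selected
from .ensemble import MultiLocModel, RFParams, train_multiloc
from .io import (
    LocalizationCatalog,
    LocalizedDataset,
    assemble_binary_datasets,
    reduce_redundancy,
    remove_overlapping,
    split_train_independent,
)
from .kmer import KmerFeaturizer
from .metrics import crossvalidate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of the pipeline, with the protocol defaults.

    The defaults mirror the full protocol (identity cut-off 0.8, 6-subset
    split, k = 1..6, alpha grid 0.1..1.0, 5-fold CV with 3 repeats, 500
    trees, 5 members, decision threshold 0.5). ``alpha``/``lam`` may be set
    to fixed values to skip tuning.
    """

    identity_threshold: float = 0.8
    n_subsets: int = 6
    k_min: int = 1
    k_max: int = 6
    feature_mode: str = "frequency"
    alpha: float | None = None
    lam: float | None = None
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    cv_folds: int = 5
    repeats: int = 3
    n_lambda: int = 100
    tuning_fraction: float = 0.5
    ntree: int = 500
    n_members: int = 5
    mtry: int | None = None
    threshold: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_grid"] = list(self.alpha_grid)
        return d


@dataclass
class PreparedData:
    """Output of the data-preparation stage."""

    per_loc_train: dict
    per_loc_independent: dict  # held-out split (primary independent test set)
    per_loc_removed: dict  # redundancy-filtered (similarity-sharing test set)
    counts: dict  # stage-by-stage record counts per localization
    catalog: LocalizationCatalog
    removal_report: list = field(default_factory=list)  # (id, reason, representative)


def prepare(dataset: LocalizedDataset, config: RunConfig | None = None) -> PreparedData:
    """Overlap removal -> per-location redundancy reduction -> 6-way split."""
    if config is None:
        config = RunConfig()
    catalog = dataset.catalog
    counts: dict = {"input": len(dataset.records)}
    single = remove_overlapping(dataset)
    counts["single_label"] = len(single.records)
    kept_ids = {r.id for r in single.records}
    removal_report = [(r.id, "overlap", "") for r in dataset.records
                      if r.id not in kept_ids]
    per_loc_train, per_loc_independent, per_loc_removed = {}, {}, {}
    per_loc_counts = {}
    for loc in catalog.names:
        recs = [r for r in single.records if loc in r.labels]
        red = reduce_redundancy(recs, config.identity_threshold)
        if len(red.retained) < config.n_subsets:
            raise ValueError(
                f"{loc}: only {len(red.retained)} non-redundant records; "
                f"cannot split into {config.n_subsets} subsets"
            )
        train, independent = split_train_independent(
            red.retained, config.n_subsets, seed=derive_seed(config.seed, "split", loc)
        )
        per_loc_train[loc] = train
        per_loc_independent[loc] = independent
        per_loc_removed[loc] = red.removed
        removal_report.extend(
            (r.id, "redundancy", red.representatives[r.id]) for r in red.removed
        )
        per_loc_counts[loc] = {
            "single_label": len(recs),
            "non_redundant": len(red.retained),
            "redundant": len(red.removed),
            "train": len(train),
            "independent": len(independent),
        }
        logger.info("%s: %s", loc, per_loc_counts[loc])
    counts["per_localization"] = per_loc_counts
    return PreparedData(per_loc_train, per_loc_independent, per_loc_removed,
                        counts, catalog, removal_report)


def select(prepared: PreparedData, config: RunConfig | None = None):
    """Per-localization elastic-net selection and the de-duplicated union."""
    if config is None:
        config = RunConfig()
    binary = assemble_binary_datasets(prepared.per_loc_train, prepared.catalog)
    featurizer = KmerFeaturizer(config.k_min, config.k_max, config.feature_mode).fit()
    per_loc = {}
    selectors = {}
    for bd in binary:
        X = np.vstack([featurizer.transform(bd.positives),
                       featurizer.transform(bd.negatives)])
        y = np.concatenate([np.ones(len(bd.positives), int),
                            np.zeros(len(bd.negatives), int)])
        sel = ElasticNetSelector(
            alpha=config.alpha, lam=config.lam, alpha_grid=config.alpha_grid,
            folds=config.cv_folds, repeats=config.repeats,
            n_lambda=config.n_lambda, tuning_fraction=config.tuning_fraction,
            feature_names=featurizer.feature_names_,
            random_state=derive_seed(config.seed, "select", bd.localization),
        )
        sel.fit(X, y)
        per_loc[bd.localization] = sel.selected_features_
        selectors[bd.localization] = sel
        logger.info("%s: selected %d features (alpha=%.2f lambda=%.4g)",
                    bd.localization, len(sel.selected_features_),
                    sel.alpha_, sel.lambda_)
    result = union_selected(per_loc)
    logger.info("union: %d non-redundant of %d selected",
                len(result.union), result.n_selected_total)
    return result, selectors, binary


def train(prepared: PreparedData, selection, config: RunConfig | None = None,
          binary=None, with_cv: bool = True):
    """Train the 9 balanced ensembles on the selected union; optional CV report."""
    if config is None:
        config = RunConfig()
    if binary is None:
        binary = assemble_binary_datasets(prepared.per_loc_train, prepared.catalog)
    params = RFParams(ntree=config.ntree, mtry=config.mtry,
                      n_members=config.n_members, seed=config.seed)
    model = train_multiloc(binary, selection, params,
                           k_min=config.k_min, k_max=config.k_max,
                           mode=config.feature_mode, catalog=prepared.catalog)
    model.threshold = config.threshold
    reports = {}
    if with_cv:
        for bd in binary:
            reports[bd.localization] = crossvalidate(
                bd, selection, params, folds=config.cv_folds,
                seed=derive_seed(config.seed, "cvfold", bd.localization),
                k_min=config.k_min, k_max=config.k_max, mode=config.feature_mode,
            )
    return model, reports


def run_pipeline(dataset: LocalizedDataset, config: RunConfig | None = None,
                 with_cv: bool = True):
    """Full chain on an in-memory dataset; returns a result bundle."""
    if config is None:
        config = RunConfig()
    prepared = prepare(dataset, config)
    selection, selectors, binary = select(prepared, config)
    model, reports = train(prepared, selection, config, binary=binary,
                           with_cv=with_cv)
    return {
        "prepared": prepared,
        "selection": selection,
        "selectors": selectors,
        "model": model,
        "cv_reports": reports,
        "config": config,
    }
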