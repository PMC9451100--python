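"""End-to-end K-fold pipeline: dose-response featurization -> oversampling ->
normalization -> train/evaluate per fold -> averaged report.

Two augmentation placements are supported. ``paper_faithful`` augments the
pooled dataset before splitting (the printed procedure: augment, normalise,
then divide into K folds), so synthetic samples can land in test folds.
``leak_free`` splits the original samples first and augments only the
training folds, testing on untouched originals; the provenance of every
synthetic row then stays within its training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .datamodel import MultiLabelDataset, PipelineConfig, ValidationError, concat_datasets
from .dose_response import DoseResponseConfig, build_rmax_features
from .io import normalize_features
from .metrics import EvaluationReport, evaluate
from .mlsmote import MlsmoteConfig, SyntheticProvenance, imbalance_profile, mlsmote_augment
from .rethinknet import RethinkConfig, build_model, predict, train

log = logging.getLogger(__name__)


@dataclass
class CrossValResult:
    fold_reports: list[EvaluationReport]
    aggregate: dict[str, float]
    std: dict[str, float]
    fold_assignment: list[np.ndarray]     # test indices per fold (into the split dataset)
    provenance: list[list[SyntheticProvenance]]  # per fold (leak_free) or single (paper_faithful)


def dataset_from_expression(records, labels, compound_ids, label_names, dr_cfg=None) -> MultiLabelDataset:
    """Fit dose-response curves and assemble the R_max dataset."""
    features, fitted_compounds, retained, _fits = build_rmax_features(records, dr_cfg)
    if fitted_compounds != list(compound_ids):
        order = [fitted_compounds.index(c) for c in compound_ids]
        features = features[order]
    return MultiLabelDataset(
        features=features,
        labels=labels,
        gene_ids=retained,
        label_names=label_names,
        sample_ids=list(compound_ids),
    )


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def _fit_predict(train_ds: MultiLabelDataset, test_ds: MultiLabelDataset,
                 model_cfg: RethinkConfig, normalization: str):
    tr, te, _scaler = normalize_features(train_ds.features, test_ds.features, normalization)
    model = build_model(model_cfg, tr.shape[1], train_ds.L)
    norm_train = MultiLabelDataset(
        tr, train_ds.labels, train_ds.gene_ids, train_ds.label_names,
        train_ds.sample_ids, train_ds.synthetic,
    )
    train(model, norm_train, model_cfg)
    trace = predict(model, te)
    scores = trace.scores[:, -1, :]
    return trace.final_labels, scores


def run_crossval(
    dataset: MultiLabelDataset,
    cfg: PipelineConfig | None = None,
    model_cfg: RethinkConfig | None = None,
    mlsmote_cfg: MlsmoteConfig | None = None,
) -> CrossValResult:
    """K-fold cross-validation of the rethinking model on an R_max dataset.

    Every stochastic step (augmentation, fold shuffling, model init and
    minibatch order) consumes the run seed.
    """
    cfg = cfg or PipelineConfig()
    model_cfg = model_cfg or RethinkConfig(seed=cfg.seed)
    mlsmote_cfg = mlsmote_cfg or MlsmoteConfig(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)

    reports: list[EvaluationReport] = []
    provenances: list[list[SyntheticProvenance]] = []
    if cfg.augment_mode == "paper_faithful":
        log.info("stage augment: %d samples, MeanIR %.3f", dataset.n, imbalance_profile(dataset.labels).mean_ir)
        augmented, prov = mlsmote_augment(dataset, mlsmote_cfg)
        provenances.append(prov)
        log.info("stage split: %d samples into %d folds", augmented.n, cfg.folds)
        folds = _kfold_indices(augmented.n, cfg.folds, rng)
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(augmented.n), test_idx)
            tr_ds, te_ds = augmented.subset(train_idx), augmented.subset(test_idx)
            yhat, scores = _fit_predict(tr_ds, te_ds, model_cfg, cfg.normalization)
            reports.append(evaluate(te_ds.labels, yhat, scores))
            log.info("fold %d/%d: acc %.3f", fi + 1, cfg.folds, reports[-1].acc)
    else:  # leak_free: split originals, augment train folds only
        folds = _kfold_indices(dataset.n, cfg.folds, rng)
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(dataset.n), test_idx)
            tr_ds = dataset.subset(train_idx)
            te_ds = dataset.subset(test_idx)
            tr_aug, prov = mlsmote_augment(tr_ds, mlsmote_cfg)
            provenances.append(prov)
            yhat, scores = _fit_predict(tr_aug, te_ds, model_cfg, cfg.normalization)
            reports.append(evaluate(te_ds.labels, yhat, scores))
            log.info("fold %d/%d (leak_free): acc %.3f", fi + 1, cfg.folds, reports[-1].acc)

    agg, std = _aggregate(reports)
    return CrossValResult(reports, agg, std, folds, provenances)


def _aggregate(reports: list[EvaluationReport]) -> tuple[dict[str, float], dict[str, float]]:
    keys = reports[0].scalars().keys()
    agg, std = {}, {}
    for k in keys:
        vals = np.array([r.scalars()[k] for r in reports], dtype=float)
        agg[k] = float(vals.mean())
        std[k] = float(vals.std(ddof=0))
    lab = np.vstack([np.asarray(r.acc_lab) for r in reports])
    agg["acc_lab"] = lab.mean(axis=0).tolist()
    return agg, std


def run_holdout(
    train_ds: MultiLabelDataset,
    test_ds: MultiLabelDataset,
    cfg: PipelineConfig | None = None,
    model_cfg: RethinkConfig | None = None,
    mlsmote_cfg: MlsmoteConfig | None = None,
) -> EvaluationReport:
    """Held-out evaluation: augment/normalise fitted on train only.

    Mirrors the external-validation workflow where one portion of the data
    is augmented, balanced and used for training while the remainder is an
    untouched test set.
    """
    cfg = cfg or PipelineConfig()
    model_cfg = model_cfg or RethinkConfig(seed=cfg.seed)
    mlsmote_cfg = mlsmote_cfg or MlsmoteConfig(seed=cfg.seed)
    overlap = set(train_ds.sample_ids) & set(test_ds.sample_ids)
    if overlap:
        raise ValidationError(f"train/test sample_ids overlap: {sorted(overlap)[:5]}")
    if train_ds.gene_ids != test_ds.gene_ids:
        raise ValidationError("train/test gene schemas differ")
    tr_aug, _prov = mlsmote_augment(train_ds, mlsmote_cfg)
    yhat, scores = _fit_predict(tr_aug, test_ds, model_cfg, cfg.normalization)
    return evaluate(test_ds.labels, yhat, scores)
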