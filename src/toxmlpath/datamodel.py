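"""Shared domain types for the toxicogenomics multi-label pipeline.

The central container is :class:`MultiLabelDataset`: an ``n x dim`` real
feature matrix (per-compound R_max values, one column per retained gene)
paired with an ``n x L`` binary pathology-finding label matrix. Samples are
flagged ``original`` or ``synthetic`` so that oversampled rows can be traced
and excluded from leak-free evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

DOSE_LEVELS = ("low", "middle", "high")


class ValidationError(ValueError):
    """Raised when an input table or record violates a domain invariant."""


@dataclass(frozen=True)
class ExpressionRecord:
    """One normalized expression intensity for (compound, dose level, gene).

    ``time_point`` is hours post-exposure; the pipeline's scope is the 24 h
    window, but the field is carried so tables remain self-describing.
    """

    compound_id: str
    dose_level: str
    gene_id: str
    value: float
    time_point: float = 24.0

    def __post_init__(self) -> None:
        if self.dose_level not in DOSE_LEVELS:
            raise ValidationError(
                f"dose_level {self.dose_level!r} not in {DOSE_LEVELS} "
                f"(compound {self.compound_id!r}, gene {self.gene_id!r})"
            )
        if not np.isfinite(self.value):
            raise ValidationError(
                f"non-finite expression value for compound {self.compound_id!r}, "
                f"gene {self.gene_id!r}, dose {self.dose_level!r}"
            )


@dataclass
class MultiLabelDataset:
    """Feature matrix + binary label matrix + names/provenance.

    Attributes
    ----------
    features : (n, dim) float array
    labels : (n, L) int array in {0, 1}
    gene_ids : length-dim gene names
    label_names : length-L pathological finding names
    sample_ids : length-n unique sample identifiers
    synthetic : length-n bool array; True for oversampled rows
    """

    features: np.ndarray
    labels: np.ndarray
    gene_ids: list[str]
    label_names: list[str]
    sample_ids: list[str]
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.synthetic is None:
            self.synthetic = np.zeros(self.features.shape[0], dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        self.gene_ids = list(self.gene_ids)
        self.label_names = list(self.label_names)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    def validate(self) -> None:
        n, dim = self.features.shape
        if n < 1 or dim < 1:
            raise ValidationError("dataset needs at least one sample and one feature")
        if self.labels.shape[0] != n:
            raise ValidationError(
                f"labels have {self.labels.shape[0]} rows but features have {n}"
            )
        if self.labels.ndim != 2 or self.labels.shape[1] < 1:
            raise ValidationError("labels must be a non-empty 2-D matrix")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be strictly binary (0/1)")
        self.labels = self.labels.astype(np.int64)
        if len(self.gene_ids) != dim:
            raise ValidationError(f"{len(self.gene_ids)} gene_ids for {dim} features")
        if len(self.label_names) != self.labels.shape[1]:
            raise ValidationError(
                f"{len(self.label_names)} label_names for {self.labels.shape[1]} labels"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample_ids for {n} samples")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicated sample_ids")
        if self.synthetic.shape != (n,):
            raise ValidationError("synthetic flag length mismatch")
        if not np.isfinite(self.features).all():
            raise ValidationError("non-finite feature values")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    @property
    def L(self) -> int:
        return self.labels.shape[1]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "MultiLabelDataset":
        """Row subset preserving names and provenance flags."""
        idx = np.asarray(idx)
        return MultiLabelDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            gene_ids=self.gene_ids,
            label_names=self.label_names,
            sample_ids=[self.sample_ids[i] for i in idx],
            synthetic=self.synthetic[idx],
        )

    def select_genes(self, gene_subset: Sequence[str]) -> "MultiLabelDataset":
        """Column subset by gene name, in the order given."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_subset if g not in pos]
        if missing:
            raise ValidationError(f"unknown genes requested: {missing[:5]}")
        cols = [pos[g] for g in gene_subset]
        return MultiLabelDataset(
            features=self.features[:, cols],
            labels=self.labels,
            gene_ids=list(gene_subset),
            label_names=self.label_names,
            sample_ids=self.sample_ids,
            synthetic=self.synthetic,
        )


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    ``augment_mode`` controls where oversampling sits relative to the CV
    split: ``paper_faithful`` augments the pooled data before splitting
    (the printed procedure); ``leak_free`` splits the original samples first
    and augments only the training folds, testing on originals.
    """

    seed: int = 0
    folds: int = 5
    augment_mode: str = "paper_faithful"
    normalization: str = "zscore"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.augment_mode not in ("paper_faithful", "leak_free"):
            raise ValidationError(f"unknown augment_mode {self.augment_mode!r}")
        if self.normalization not in ("zscore", "none"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")


def concat_datasets(a: MultiLabelDataset, b: MultiLabelDataset) -> MultiLabelDataset:
    """Stack two datasets sharing gene/label names."""
    if a.gene_ids != b.gene_ids or a.label_names != b.label_names:
        raise ValidationError("cannot concatenate datasets with different schemas")
    return MultiLabelDataset(
        features=np.vstack([a.features, b.features]),
        labels=np.vstack([a.labels, b.labels]),
        gene_ids=a.gene_ids,
        label_names=a.label_names,
        sample_ids=a.sample_ids + b.sample_ids,
        synthetic=np.concatenate([a.synthetic, b.synthetic]),
    )


def clone_with(ds: MultiLabelDataset, **kw) -> MultiLabelDataset:
    kw.setdefault("features", ds.features)
    kw.setdefault("labels", ds.labels)
    kw.setdefault("gene_ids", ds.gene_ids)
    kw.setdefault("label_names", ds.label_names)
    kw.setdefault("sample_ids", ds.sample_ids)
    kw.setdefault("synthetic", ds.synthetic)
    return MultiLabelDataset(**kw)
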