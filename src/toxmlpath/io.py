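"""CSV readers/writers and feature normalization.

File dialects (all plain CSV with header):

* expression (long): ``compound_id,dose_level,time_h,gene_id,value``
* labels: ``sample_id`` plus one 0/1 column per pathological finding
* features: ``sample_id`` plus one real column per retained gene
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DOSE_LEVELS, ExpressionRecord, MultiLabelDataset, ValidationError

log = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["compound_id", "dose_level", "time_h", "gene_id", "value"]


def read_expression_table(path) -> list[ExpressionRecord]:
    """Read a long-format expression CSV into validated records.

    Row order is preserved. Every (compound, gene) pair must carry all
    three dose levels; a missing level is reported by name.
    """
    df = pd.read_csv(
        path,
        dtype={"compound_id": str, "gene_id": str, "dose_level": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"expression table missing columns {missing_cols}")
    records: list[ExpressionRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            value = float(row.value)
        except (TypeError, ValueError):
            raise ValidationError(f"non-numeric expression value at row {i}: {row.value!r}")
        records.append(
            ExpressionRecord(
                compound_id=row.compound_id,
                dose_level=row.dose_level,
                gene_id=row.gene_id,
                value=value,
                time_point=float(row.time_h),
            )
        )
    _check_dose_completeness(records)
    _check_uniqueness(records)
    return records


def _check_dose_completeness(records: list[ExpressionRecord]) -> None:
    seen: dict[tuple[str, str], set[str]] = {}
    for r in records:
        seen.setdefault((r.compound_id, r.gene_id), set()).add(r.dose_level)
    for (compound, gene), doses in seen.items():
        gap = set(DOSE_LEVELS) - doses
        if gap:
            raise ValidationError(
                f"compound {compound!r}, gene {gene!r} missing dose level(s) {sorted(gap)}"
            )


def _check_uniqueness(records: list[ExpressionRecord]) -> None:
    keys = [(r.compound_id, r.dose_level, r.gene_id) for r in records]
    if len(set(keys)) != len(keys):
        dupes = pd.Series(keys).value_counts()
        first = dupes.index[0]
        raise ValidationError(f"duplicated (compound, dose, gene) triple: {first}")


def write_expression_table(records: list[ExpressionRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "dose_level": r.dose_level,
                "time_h": r.time_point,
                "gene_id": r.gene_id,
                "value": r.value,
            }
            for r in records
        ],
        columns=EXPRESSION_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def read_label_table(path, expected_label_names: list[str] | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a samples x findings 0/1 CSV.

    Returns (matrix, sample_ids, label_names). When ``expected_label_names``
    is given, columns are reordered to match it and unknown/missing columns
    are an error.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("label table must have a sample_id column")
    sample_ids = df["sample_id"].tolist()
    label_df = df.drop(columns=["sample_id"])
    if expected_label_names is not None:
        unknown = [c for c in label_df.columns if c not in expected_label_names]
        if unknown:
            raise ValidationError(f"unknown label column(s): {unknown}")
        absent = [c for c in expected_label_names if c not in label_df.columns]
        if absent:
            raise ValidationError(f"expected label column(s) missing: {absent}")
        label_df = label_df[expected_label_names]
    mat = label_df.to_numpy()
    if not np.isin(mat, (0, 1)).all():
        bad = mat[~np.isin(mat, (0, 1))][0]
        raise ValidationError(f"label cell outside {{0,1}}: {bad!r}")
    return mat.astype(np.int64), sample_ids, list(label_df.columns)


def write_label_table(labels: np.ndarray, sample_ids: list[str], label_names: list[str], path) -> None:
    df = pd.DataFrame(labels, columns=label_names)
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, index=False)


def read_feature_table(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a samples x genes feature CSV; returns (matrix, sample_ids, gene_ids)."""
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValidationError("feature table must have a sample_id column")
    sample_ids = df["sample_id"].tolist()
    feat = df.drop(columns=["sample_id"])
    mat = feat.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ValidationError("non-finite feature value in table")
    return mat, sample_ids, list(feat.columns)


def write_feature_table(features: np.ndarray, sample_ids: list[str], gene_ids: list[str], path) -> None:
    df = pd.DataFrame(features, columns=gene_ids)
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(features_path, labels_path) -> MultiLabelDataset:
    feats, sids, genes = read_feature_table(features_path)
    labels, lsids, names = read_label_table(labels_path)
    if sids != lsids:
        raise ValidationError("sample_id mismatch between feature and label tables")
    return MultiLabelDataset(feats, labels, genes, names, sids)


def write_dataset(ds: MultiLabelDataset, features_path, labels_path) -> None:
    write_feature_table(ds.features, ds.sample_ids, ds.gene_ids, features_path)
    write_label_table(ds.labels, ds.sample_ids, ds.label_names, labels_path)


@dataclass
class Scaler:
    """Per-gene affine map fitted on a training split."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def normalize_features(
    train_features: np.ndarray,
    other_features: np.ndarray | None = None,
    mode: str = "zscore",
) -> tuple[np.ndarray, np.ndarray | None, Scaler]:
    """Z-score per gene on the train split; apply the same map elsewhere.

    Constant genes are mapped to 0 (scale recorded as 1). ``mode='none'``
    is the identity.
    """
    train_features = np.asarray(train_features, dtype=float)
    if train_features.size == 0:
        raise ValidationError("train_features is empty")
    if mode == "none":
        scaler = Scaler(np.zeros(train_features.shape[1]), np.ones(train_features.shape[1]))
    elif mode == "zscore":
        mean = train_features.mean(axis=0)
        sd = train_features.std(axis=0, ddof=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        scaler = Scaler(mean, sd)
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    out_train = scaler.transform(train_features)
    out_other = scaler.transform(other_features) if other_features is not None else None
    return out_train, out_other, scaler
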