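"""Improved multi-label SMOTE oversampling and imbalance diagnostics.

Pathological-finding label matrices are severely imbalanced: a handful of
findings dominate while most occur in few compounds. MLSMOTE synthesises
minority-class samples by interpolating between a minority "seed" sample
and one of its k nearest neighbours within the same label bag, assigning
labels by neighbour majority vote. The improvement implemented here adds a
guard against the rare case where the vote produces an all-zero label
vector: such a synthetic sample would carry no finding at all, so the
triggering minority label is forced on (default) or the draw is rejected
and retried (``guard='redraw'``).

Imbalance is quantified per label by IRLbl(l) = max_l' count(l') / count(l)
and summarised by MeanIR, the mean of IRLbl over labels with at least one
positive. Passes repeat until MeanIR reaches a target or a round budget is
exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MultiLabelDataset, ValidationError, concat_datasets

log = logging.getLogger(__name__)


@dataclass
class ImbalanceProfile:
    counts: np.ndarray          # per-label positive counts
    irlbl: np.ndarray           # inf where count == 0
    mean_ir: float              # mean of finite irlbl


@dataclass
class MlsmoteConfig:
    k: int = 5
    max_rounds: int = 5
    target_mean_ir: float = 1.5
    guard: str = "force_label"  # or "redraw"
    max_redraws: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.max_rounds < 1:
            raise ValidationError("max_rounds must be >= 1")
        if self.target_mean_ir < 1.0:
            raise ValidationError("target_mean_ir must be >= 1")
        if self.guard not in ("force_label", "redraw"):
            raise ValidationError(f"unknown guard mode {self.guard!r}")


@dataclass
class SyntheticProvenance:
    """Where each synthetic row came from: seed row, neighbour row, mix u."""

    seed_index: int
    neighbor_index: int
    u: float
    triggering_label: int
    guard_fired: bool


def imbalance_profile(labels: np.ndarray) -> ImbalanceProfile:
    """Per-label IRLbl and MeanIR; zero-positive labels flagged infinite."""
    labels = np.asarray(labels)
    counts = labels.sum(axis=0).astype(float)
    if counts.sum() == 0:
        raise ValidationError("all-zero label matrix: nothing to balance")
    max_count = counts.max()
    with np.errstate(divide="ignore"):
        irlbl = np.where(counts > 0, max_count / np.where(counts > 0, counts, 1), np.inf)
    mean_ir = float(irlbl[np.isfinite(irlbl)].mean())
    return ImbalanceProfile(counts=counts, irlbl=irlbl, mean_ir=mean_ir)


def majority_vote_labels(voter_labels: np.ndarray) -> np.ndarray:
    """Ranking rule: a label is set iff present in strictly more than half
    of the voters (seed plus its k nearest bag members)."""
    voter_labels = np.asarray(voter_labels)
    votes = voter_labels.sum(axis=0)
    return (votes * 2 > voter_labels.shape[0]).astype(np.int64)


def apply_zero_label_guard(labels: np.ndarray, triggering_label: int) -> tuple[np.ndarray, bool]:
    """If the vote produced an all-zero vector, force the triggering
    minority label on so the synthetic sample carries at least one finding.

    Note: when voters are drawn from the triggering label's own bag the
    all-zero outcome cannot arise (every voter carries that label); the
    guard protects alternative voter schemes and corrupted inputs.
    """
    labels = np.asarray(labels).copy()
    if labels.sum() == 0:
        labels[triggering_label] = 1
        return labels, True
    return labels, False


def _knn_in_bag(features: np.ndarray, k: int) -> np.ndarray:
    """All-pairs Euclidean k-NN inside a bag; ties broken by row index."""
    d = np.linalg.norm(features[:, None, :] - features[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    # argsort is stable, so equal distances resolve to the lower index
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def mlsmote_augment(
    dataset: MultiLabelDataset,
    cfg: MlsmoteConfig | None = None,
) -> tuple[MultiLabelDataset, list[SyntheticProvenance]]:
    """Oversample minority labels until MeanIR <= target or rounds run out.

    A label is minority when its IRLbl exceeds the current MeanIR. One pass
    visits every minority label; for each sample in that label's positive
    bag it draws a random neighbour among the k nearest bag members and
    interpolates features uniformly along the seed-neighbour segment.
    Synthetic labels are set by strict majority over the seed plus its k
    nearest bag neighbours; the all-zero guard is applied afterwards.
    Original rows are preserved verbatim; synthetic rows are flagged.
    """
    cfg = cfg or MlsmoteConfig()
    rng = np.random.default_rng(cfg.seed)

    out = dataset
    provenance: list[SyntheticProvenance] = []
    for rnd in range(cfg.max_rounds):
        profile = imbalance_profile(out.labels)
        if profile.mean_ir <= cfg.target_mean_ir:
            break
        minority = np.where(
            np.isfinite(profile.irlbl) & (profile.irlbl > profile.mean_ir)
        )[0]
        if minority.size == 0:
            break
        new_feats, new_labels, new_prov = [], [], []
        for lab in minority:
            bag_idx = np.where(out.labels[:, lab] == 1)[0]
            if bag_idx.size < 2:
                log.warning(
                    "label %s has a bag of %d sample(s); skipped", out.label_names[lab], bag_idx.size
                )
                continue
            bag_feats = out.features[bag_idx]
            k_eff = min(cfg.k, bag_idx.size - 1)
            nn = _knn_in_bag(bag_feats, k_eff)
            for pos, seed_row in enumerate(bag_idx):
                for _attempt in range(cfg.max_redraws):
                    pick = int(rng.integers(k_eff))
                    neigh_pos = int(nn[pos, pick])
                    u = float(rng.uniform())
                    feats = bag_feats[pos] + u * (bag_feats[neigh_pos] - bag_feats[pos])
                    # vote over seed + its k nearest bag members
                    voters = out.labels[np.concatenate(([seed_row], bag_idx[nn[pos]]))]
                    labels = majority_vote_labels(voters)
                    guard_fired = False
                    if labels.sum() == 0:
                        if cfg.guard == "redraw":
                            continue
                        labels, guard_fired = apply_zero_label_guard(labels, lab)
                    break
                else:
                    # every redraw produced all-zero labels; fall back to forcing
                    labels = np.zeros(out.L, dtype=np.int64)
                    labels[lab] = 1
                    guard_fired = True
                new_feats.append(feats)
                new_labels.append(labels)
                new_prov.append(
                    SyntheticProvenance(
                        seed_index=int(seed_row),
                        neighbor_index=int(bag_idx[neigh_pos]),
                        u=u,
                        triggering_label=int(lab),
                        guard_fired=guard_fired,
                    )
                )
        if not new_feats:
            break
        start = out.n
        synth = MultiLabelDataset(
            features=np.asarray(new_feats),
            labels=np.asarray(new_labels),
            gene_ids=out.gene_ids,
            label_names=out.label_names,
            sample_ids=[f"synthetic_{start + i}" for i in range(len(new_feats))],
            synthetic=np.ones(len(new_feats), dtype=bool),
        )
        candidate = concat_datasets(out, synth)
        new_mean_ir = imbalance_profile(candidate.labels).mean_ir
        if new_mean_ir > profile.mean_ir:
            # a pass can worsen balance when synthetic votes drag in common
            # co-occurring labels; such a pass is discarded and iteration stops
            log.info(
                "MLSMOTE round %d rolled back (MeanIR %.3f -> %.3f); stopping",
                rnd + 1, profile.mean_ir, new_mean_ir,
            )
            break
        out = candidate
        provenance.extend(new_prov)
        log.info(
            "MLSMOTE round %d: +%d synthetic samples, MeanIR %.3f -> %.3f",
            rnd + 1, len(new_feats), profile.mean_ir, new_mean_ir,
        )
    return out, provenance
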