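"""Multi-label F-statistic gene ranking and fitness-driven subset search.

Genes are scored per label by the one-way two-group ANOVA F statistic
(between-group over within-group variance, positives vs negatives) and
aggregated across labels (mean by default). Subsets of top-ranked genes are
then swept from large to small and scored by the amplified fitness

    Fitness = alpha * ACC + (1 - alpha) * (D_total - lambda * D_selected) / D_total

which rewards accuracy while charging each retained gene lambda-fold, so
that small informative subsets win even when D_selected << D_total. The
second term may go negative when lambda * D_selected exceeds D_total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datamodel import MultiLabelDataset, ValidationError

log = logging.getLogger(__name__)

F_MAX = 1e12  # cap for zero within-group variance with distinct means


@dataclass
class FitnessConfig:
    alpha: float = 0.6
    lam: float = 10.0
    d_total: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if self.lam <= 0:
            raise ValidationError("lam must be positive")
        if self.d_total < 1:
            raise ValidationError("d_total must be >= 1")


@dataclass
class SelectionResult:
    ranked_genes: list[tuple[str, float]]     # gene, aggregated F score (descending)
    curve: list[tuple[int, float, float]]     # (subset size, accuracy, fitness)
    best_size: int
    best_genes: list[str]


def _two_group_f(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorised one-way F over columns of x for groups mask / ~mask."""
    g1, g0 = x[mask], x[~mask]
    n1, n0 = len(g1), len(g0)
    n = n1 + n0
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    gm = x.mean(axis=0)
    ss_between = n1 * (m1 - gm) ** 2 + n0 * (m0 - gm) ** 2
    ss_within = ((g1 - m1) ** 2).sum(axis=0) + ((g0 - m0) ** 2).sum(axis=0)
    ms_between = ss_between / 1.0          # k - 1 = 1
    ms_within = ss_within / (n - 2)
    f = np.full(x.shape[1], 0.0)
    ok = ms_within > 0
    f[ok] = ms_between[ok] / ms_within[ok]
    # zero within-group variance with distinct means: cap, not infinity
    f[~ok & (ms_between > 0)] = F_MAX
    return np.minimum(f, F_MAX)


def multilabel_f_scores(
    features: np.ndarray,
    labels: np.ndarray,
    aggregate: str = "mean",
) -> np.ndarray:
    """Per-gene F statistic aggregated over labels (mean or max).

    Single-class labels carry no grouping information and are excluded with
    a warning.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if aggregate not in ("mean", "max"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    per_label = []
    for l in range(labels.shape[1]):
        mask = labels[:, l] == 1
        if mask.all() or not mask.any():
            log.warning("label %d is single-class; excluded from F aggregation", l)
            continue
        per_label.append(_two_group_f(features, mask))
    if not per_label:
        raise ValidationError("no label with both classes present")
    stack = np.vstack(per_label)
    return stack.mean(axis=0) if aggregate == "mean" else stack.max(axis=0)


def fitness(acc: float, d_selected: int, cfg: FitnessConfig) -> float:
    """Amplified fitness of a feature subset (see module docstring)."""
    if not 0.0 <= acc <= 1.0:
        raise ValidationError("acc must be in [0, 1]")
    if not 0 <= d_selected <= cfg.d_total:
        raise ValidationError("d_selected must be in [0, d_total]")
    return cfg.alpha * acc + (1.0 - cfg.alpha) * (cfg.d_total - cfg.lam * d_selected) / cfg.d_total


def default_sizes_grid(d_total: int, n_points: int = 10) -> list[int]:
    """Descending geometric grid of subset sizes from d_total down to 1."""
    sizes = np.unique(np.round(np.geomspace(1, d_total, n_points)).astype(int))
    return sorted(set(int(s) for s in sizes), reverse=True)


def greedy_subset_search(
    dataset: MultiLabelDataset,
    evaluator: Callable[[Sequence[str]], float],
    sizes_grid: Sequence[int] | None = None,
    cfg: FitnessConfig | None = None,
    aggregate: str = "mean",
) -> SelectionResult:
    """Sweep top-ranked gene subsets from large to small, maximising fitness.

    ``evaluator`` maps a gene-name subset to an accuracy in [0, 1] (the
    caller decides how: typically CV-mean subset accuracy of a baseline).
    Ties in fitness break toward the smaller subset. Evaluator failures
    skip the size with a logged warning.
    """
    cfg = cfg or FitnessConfig(d_total=dataset.dim)
    if cfg.d_total != dataset.dim:
        cfg = FitnessConfig(alpha=cfg.alpha, lam=cfg.lam, d_total=dataset.dim)
    if sizes_grid is None:
        sizes_grid = default_sizes_grid(dataset.dim)
    sizes = list(sizes_grid)
    if any(s < 1 or s > dataset.dim for s in sizes):
        raise ValidationError("sizes_grid entries must lie in [1, d_total]")
    if sorted(sizes, reverse=True) != sizes:
        raise ValidationError("sizes_grid must be descending (deletion order)")

    scores = multilabel_f_scores(dataset.features, dataset.labels, aggregate)
    order = np.argsort(-scores, kind="stable")
    ranked = [(dataset.gene_ids[i], float(scores[i])) for i in order]

    curve: list[tuple[int, float, float]] = []
    best: tuple[float, int] | None = None  # (fitness, size); ties -> smaller size
    for size in sizes:
        genes = [g for g, _ in ranked[:size]]
        try:
            acc = float(evaluator(genes))
        except Exception as exc:
            log.warning("evaluator failed at size %d (%s); skipped", size, exc)
            continue
        fit = fitness(acc, size, cfg)
        curve.append((size, acc, fit))
        if best is None or fit > best[0] or (fit == best[0] and size < best[1]):
            best = (fit, size)
    if best is None:
        raise ValidationError("evaluator failed at every size in the grid")
    best_size = best[1]
    return SelectionResult(
        ranked_genes=ranked,
        curve=curve,
        best_size=best_size,
        best_genes=[g for g, _ in ranked[:best_size]],
    )
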