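"""Synthetic toxicogenomics fixtures.

``simulate_dataset`` emulates the structure of a dose-response expression
study: per-compound expression at three dose levels where informative
genes follow a logistic dose-response whose maximal response shifts when
their associated pathological finding is active, noise genes stay flat
with Gaussian jitter, and the 20-dimensional binary finding vector is
sparse, imbalanced and pairwise correlated. It reproduces structure, not
the marginal distributions of any real platform.

``make_separable_benchmark`` builds a linearly separable per-label dataset
with margin, used as the fixed learning benchmark for the classifier
modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ExpressionRecord, MultiLabelDataset, ValidationError
from .dose_response import logistic_response

log = logging.getLogger(__name__)


def _default_prevalences(L: int) -> np.ndarray:
    # skewed: a few common findings, a long tail of rare ones
    base = np.geomspace(0.4, 0.05, L)
    return base


@dataclass
class SyntheticConfig:
    n_compounds: int = 200
    n_genes: int = 120
    informative_fraction: float = 0.1
    L: int = 20
    label_prevalences: np.ndarray | None = None
    dependency_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 1, 0.3), (2, 3, 0.25)]
    )
    effect_size: float = 1.0
    noise_sd: float = 0.1
    baseline_level: float = 6.0       # flat expression level of noise genes
    response_amplitude: float = 1.5   # r_max - baseline for inactive informative genes
    slope: float = 4.0
    ec50: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.informative_fraction <= 1.0:
            raise ValidationError("informative_fraction must be in (0, 1]")
        if self.label_prevalences is None:
            self.label_prevalences = _default_prevalences(self.L)
        self.label_prevalences = np.asarray(self.label_prevalences, dtype=float)
        if self.label_prevalences.shape != (self.L,):
            raise ValidationError("label_prevalences must have length L")
        if ((self.label_prevalences <= 0) | (self.label_prevalences >= 1)).any():
            raise ValidationError("prevalences must be in (0, 1)")
        for i, j, boost in self.dependency_pairs:
            if not (0 <= i < self.L and 0 <= j < self.L and i != j):
                raise ValidationError(f"bad dependency pair ({i}, {j})")
            if boost <= 0.0 or self.conditional_probability(i, j) > 1.0:
                raise ValidationError(
                    f"dependency boost ({i}->{j}, +{boost}) gives an invalid conditional probability"
                )

    def conditional_probability(self, i: int, j: int) -> float:
        """P(label_j = 1 | label_i = 1) implied by the (i, j, boost) encoding."""
        p_j = float(self.label_prevalences[j])
        boost = next(b for (a, c, b) in self.dependency_pairs if (a, c) == (i, j))
        return p_j + boost * (1.0 - p_j)


@dataclass
class GroundTruth:
    informative_genes: list[str]
    gene_label_map: dict[str, int]          # informative gene -> associated label
    effective_prevalences: np.ndarray       # marginals after dependency boosts
    dependency_pairs: list[tuple[int, int, float]]


def _draw_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n, L = cfg.n_compounds, cfg.L
    labels = (rng.uniform(size=(n, L)) < cfg.label_prevalences).astype(np.int64)
    # pairwise boosts: when i is active, j flips on with probability `boost`,
    # so P(j=1 | i=1) = p_j + boost * (1 - p_j)
    for i, j, boost in cfg.dependency_pairs:
        active = labels[:, i] == 1
        extra = rng.uniform(size=n) < boost
        labels[active & extra, j] = 1
    return labels


def effective_prevalences(cfg: SyntheticConfig) -> np.ndarray:
    """Marginal P(label) implied by base prevalences plus dependency boosts."""
    p = cfg.label_prevalences.copy()
    eff = p.copy()
    for i, j, boost in cfg.dependency_pairs:
        # j flips to 1 with prob boost when i active and j was 0
        eff[j] = p[j] + p[i] * boost * (1.0 - p[j])
    return eff


def simulate_dataset(
    cfg: SyntheticConfig | None = None,
) -> tuple[list[ExpressionRecord], np.ndarray, list[str], list[str], GroundTruth]:
    """Generate (expression records, label matrix, compound ids, label names, truth).

    Informative genes respond to dose with a logistic curve; when their
    associated finding is active in a compound the maximal response is
    shifted by ``effect_size``. Noise genes are flat plus jitter. Every
    compound carries all three dose levels.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = _draw_labels(cfg, rng)
    n_informative = max(1, int(round(cfg.informative_fraction * cfg.n_genes)))
    gene_ids = [f"gene_{g:04d}" for g in range(cfg.n_genes)]
    compound_ids = [f"compound_{c:03d}" for c in range(cfg.n_compounds)]
    label_names = [f"finding_{l:02d}" for l in range(cfg.L)]
    informative = gene_ids[:n_informative]
    gene_label_map = {g: idx % cfg.L for idx, g in enumerate(informative)}

    doses = np.array([1.0, 2.0, 3.0])
    dose_names = ("low", "middle", "high")
    records: list[ExpressionRecord] = []
    for ci, comp in enumerate(compound_ids):
        for g in gene_ids:
            if g in gene_label_map:
                lab = gene_label_map[g]
                r_max = (
                    cfg.baseline_level
                    + cfg.response_amplitude
                    + cfg.effect_size * labels[ci, lab]
                )
                clean = logistic_response(doses, cfg.baseline_level, r_max, cfg.ec50, cfg.slope)
            else:
                clean = np.full(3, cfg.baseline_level)
            noisy = clean + rng.normal(0, cfg.noise_sd, size=3)
            for d, (dn, val) in enumerate(zip(dose_names, noisy)):
                records.append(
                    ExpressionRecord(compound_id=comp, dose_level=dn, gene_id=g, value=float(val))
                )
    truth = GroundTruth(
        informative_genes=list(informative),
        gene_label_map=gene_label_map,
        effective_prevalences=effective_prevalences(cfg),
        dependency_pairs=list(cfg.dependency_pairs),
    )
    return records, labels, compound_ids, label_names, truth


def make_separable_benchmark(n: int = 600, dim: int = 50, L: int = 5, seed: int = 1) -> MultiLabelDataset:
    """Linearly separable multi-label dataset with margin.

    Each label l has a random unit normal w_l; y_l = 1[w_l . x >= 0], and
    points within margin 0.3 of any boundary are pushed outward along that
    boundary's normal, so a linear scorer separates every label exactly.
    Per-label prevalence is ~0.5 by symmetry.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    W = rng.normal(size=(L, dim))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    margin = 0.3
    for l in range(L):
        proj = X @ W[l]
        close = np.abs(proj) < margin
        sign = np.where(proj[close] >= 0, 1.0, -1.0)
        X[close] += np.outer(sign * (margin - np.abs(proj[close])) * 1.01, W[l])
    Y = (X @ W.T >= 0).astype(np.int64)
    return MultiLabelDataset(
        features=X,
        labels=Y,
        gene_ids=[f"feat_{i:03d}" for i in range(dim)],
        label_names=[f"label_{l}" for l in range(L)],
        sample_ids=[f"s{i:04d}" for i in range(n)],
    )
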