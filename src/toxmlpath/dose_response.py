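"""Sigmoid dose-response fitting and R_max feature extraction.

Each gene's expression at the three dose levels (coded 1, 2, 3 on a
log-like axis) is fitted with a three-parameter logistic

    r(d) = baseline + (r_max - baseline) / (1 + exp(-slope * (d - ec50)))

where the steepness ``slope`` is a fixed shape constant of the family
(config, default 4) and (baseline, r_max, ec50) are fitted — three
unknowns against three points, exactly identifiable. With only three dose
levels the steepness cannot be estimated jointly with both asymptotes:
freeing it makes R_max unidentifiable (any monotone triple admits
near-exact step-function fits whose upper asymptote is arbitrary), so it
is pinned by design and documented.

The maximum response R_max summarises the curve and becomes the per-gene
feature. A triple "cannot form a curve" — and is flagged invalid — when
its response range is below ``flat_tolerance`` (no dose signal), when the
best fit leaves a residual sum of squares above ``rss_tolerance`` (e.g.
non-monotone series that no monotone logistic can reach), or when the
fitted maximal response falls below the baseline (no upward response).

The fitter is batched and fully vectorised: for each candidate ec50 on a
fine grid, (baseline, amplitude) enter the model linearly and are solved
in closed form; a parabolic refinement of the grid minimum gives ec50 to
~1e-5. Whole-matrix featurization (all compounds x genes) runs in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .datamodel import DOSE_LEVELS, ExpressionRecord, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseResponseConfig:
    dose_codes: tuple[float, float, float] = (1.0, 2.0, 3.0)
    slope: float = 4.0               # fixed Hill steepness on the coded axis
    rss_tolerance: float = 0.05
    flat_tolerance: float = 0.3
    ec50_bounds: tuple[float, float] = (0.0, 4.0)
    min_valid_fraction: float = 1.0  # fraction of compounds a gene must fit
    grid_size: int = 1201            # ec50 grid resolution

    def __post_init__(self) -> None:
        if self.rss_tolerance <= 0 or self.flat_tolerance <= 0:
            raise ValidationError("tolerances must be positive")
        if self.slope <= 0:
            raise ValidationError("slope must be positive")
        if not (self.dose_codes[0] < self.dose_codes[1] < self.dose_codes[2]):
            raise ValidationError("dose codes must be strictly increasing")
        if not self.ec50_bounds[0] < self.ec50_bounds[1]:
            raise ValidationError("ec50 bounds must be increasing")


@dataclass
class DoseResponseFit:
    """Fitted parameters for one (compound, gene) triple."""

    r_max: float
    ec50: float
    slope: float
    baseline: float
    rss: float
    valid: bool


def logistic_response(d, baseline, r_max, ec50, slope):
    """Three-parameter logistic on the coded dose axis."""
    d = np.asarray(d, dtype=float)
    z = np.clip(slope * (d - ec50), -500, 500)
    return baseline + (r_max - baseline) / (1.0 + np.exp(-z))


def _sigma(z):
    z = np.clip(z, -500, 500)
    return 1.0 / (1.0 + np.exp(-z))


@lru_cache(maxsize=8)
def _grid(cfg: DoseResponseConfig):
    d = np.asarray(cfg.dose_codes)
    ec = np.linspace(cfg.ec50_bounds[0], cfg.ec50_bounds[1], cfg.grid_size)
    sig = _sigma(cfg.slope * (d[:, None] - ec[None, :]))  # (3, G)
    return ec, sig


def _linear_rss(Y: np.ndarray, sig: np.ndarray):
    """For each triple (row of Y) and each ec50 grid cell, solve the linear
    least squares in (baseline, amplitude) and return (rss, b, a).

    Model per cell: y_t = b + a * sig_t. Closed-form 2x2 normal equations,
    vectorised over triples x grid.
    """
    n_pts = sig.shape[0]
    s1 = sig.sum(axis=0)                 # (G,)
    s2 = (sig * sig).sum(axis=0)         # (G,)
    det = n_pts * s2 - s1 * s1           # (G,)
    ybar = Y.sum(axis=1)                 # (N,)
    ysig = Y @ sig                       # (N, G)
    # b = (s2 * ybar - s1 * ysig) / det ; a = (n * ysig - s1 * ybar) / det
    safe_det = np.where(np.abs(det) < 1e-12, 1.0, det)
    b = (s2[None, :] * ybar[:, None] - s1[None, :] * ysig) / safe_det[None, :]
    a = (n_pts * ysig - s1[None, :] * ybar[:, None]) / safe_det[None, :]
    yy = (Y * Y).sum(axis=1)
    rss = yy[:, None] - b * ybar[:, None] - a * ysig
    rss = np.maximum(rss, 0.0)
    degenerate = np.abs(det) < 1e-12
    if degenerate.any():
        rss[:, degenerate] = np.inf
    return rss, b, a


def _fit_batch(Y: np.ndarray, cfg: DoseResponseConfig):
    """Fit every row of Y (N, 3). Returns (r_max, ec50, baseline, rss) arrays."""
    ec_grid, sig = _grid(cfg)
    d = np.asarray(cfg.dose_codes)
    N = Y.shape[0]
    rm = np.empty(N)
    ec = np.empty(N)
    bl = np.empty(N)
    rss = np.empty(N)
    chunk = max(1, int(4e7 // max(1, len(ec_grid))))
    for lo in range(0, N, chunk):
        Yc = Y[lo:lo + chunk]
        rss_g, b_g, a_g = _linear_rss(Yc, sig)
        best = np.argmin(rss_g, axis=1)
        rows = np.arange(len(Yc))
        # parabolic refinement of ec50 around the grid minimum
        inner = (best > 0) & (best < len(ec_grid) - 1)
        ec_c = ec_grid[best].astype(float)
        if inner.any():
            i = best[inner]
            h = ec_grid[1] - ec_grid[0]
            f0 = rss_g[rows[inner], i - 1]
            f1 = rss_g[rows[inner], i]
            f2 = rss_g[rows[inner], i + 1]
            denom = f0 - 2 * f1 + f2
            shift = np.where(np.abs(denom) > 1e-30, 0.5 * (f0 - f2) / np.where(np.abs(denom) > 1e-30, denom, 1.0), 0.0)
            shift = np.clip(shift, -1.0, 1.0)
            ec_c[inner] = ec_grid[i] + shift * h
        # re-solve the linear part at the refined ec50
        sig_c = _sigma(cfg.slope * (d[None, :] - ec_c[:, None]))   # (n, 3)
        rss_c, b_c, a_c = _linear_rss_single(Yc, sig_c)
        bl[lo:lo + chunk] = b_c
        rm[lo:lo + chunk] = b_c + a_c
        ec[lo:lo + chunk] = ec_c
        rss[lo:lo + chunk] = rss_c
    return rm, ec, bl, rss


def _linear_rss_single(Y: np.ndarray, sig: np.ndarray):
    """Per-row linear solve where each row has its own sigma vector (n, 3)."""
    n_pts = sig.shape[1]
    s1 = sig.sum(axis=1)
    s2 = (sig * sig).sum(axis=1)
    det = n_pts * s2 - s1 * s1
    ybar = Y.sum(axis=1)
    ysig = (Y * sig).sum(axis=1)
    safe_det = np.where(np.abs(det) < 1e-12, 1.0, det)
    b = (s2 * ybar - s1 * ysig) / safe_det
    a = (n_pts * ysig - s1 * ybar) / safe_det
    rss = (Y * Y).sum(axis=1) - b * ybar - a * ysig
    rss = np.maximum(rss, 0.0)
    bad = np.abs(det) < 1e-12
    rss[bad] = np.inf
    a[bad] = 0.0
    b[bad] = Y[bad, 0] if bad.any() else b[bad]
    return rss, b, a


def fit_gene_curve(doses, responses, cfg: DoseResponseConfig | None = None) -> DoseResponseFit:
    """Fit the fixed-steepness logistic through exactly three points.

    Validity requires a finite fit with residual sum of squares at or below
    ``rss_tolerance``, a response range of at least ``flat_tolerance``, and
    a fitted maximal response at or above the baseline.
    """
    cfg = cfg or DoseResponseConfig()
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != (3,) or responses.shape != (3,):
        raise ValidationError("fit_gene_curve requires exactly 3 (dose, response) pairs")
    if not np.allclose(doses, cfg.dose_codes):
        cfg = DoseResponseConfig(
            dose_codes=tuple(float(x) for x in doses),
            slope=cfg.slope,
            rss_tolerance=cfg.rss_tolerance,
            flat_tolerance=cfg.flat_tolerance,
            ec50_bounds=cfg.ec50_bounds,
            min_valid_fraction=cfg.min_valid_fraction,
            grid_size=cfg.grid_size,
        )

    if float(responses.max() - responses.min()) < cfg.flat_tolerance:
        b = float(responses[0])
        return DoseResponseFit(b, np.nan, cfg.slope, b, 0.0, False)

    rm, ec, bl, rss = _fit_batch(responses[None, :], cfg)
    valid = bool(
        np.isfinite([rm[0], ec[0], bl[0]]).all()
        and rss[0] <= cfg.rss_tolerance
        and rm[0] >= bl[0]
    )
    return DoseResponseFit(float(rm[0]), float(ec[0]), cfg.slope, float(bl[0]), float(rss[0]), valid)


def build_rmax_features(
    records: list[ExpressionRecord],
    cfg: DoseResponseConfig | None = None,
) -> tuple[np.ndarray, list[str], list[str], dict[tuple[str, str], DoseResponseFit]]:
    """Fit every (compound, gene) triple and assemble the R_max feature matrix.

    A gene is retained iff its fit is valid for at least
    ``cfg.min_valid_fraction`` of compounds (default: all). Returns
    (features, compound_ids, retained_gene_ids, fits).
    """
    cfg = cfg or DoseResponseConfig()
    table: dict[tuple[str, str], dict[str, float]] = {}
    compounds: list[str] = []
    genes: list[str] = []
    seen_c: set[str] = set()
    seen_g: set[str] = set()
    for r in records:
        if r.compound_id not in seen_c:
            seen_c.add(r.compound_id)
            compounds.append(r.compound_id)
        if r.gene_id not in seen_g:
            seen_g.add(r.gene_id)
            genes.append(r.gene_id)
        table.setdefault((r.compound_id, r.gene_id), {})[r.dose_level] = r.value

    pairs = []
    Y = np.empty((len(compounds) * len(genes), 3))
    row = 0
    for gene in genes:
        for compound in compounds:
            triple = table.get((compound, gene))
            if triple is None or set(triple) != set(DOSE_LEVELS):
                raise ValidationError(
                    f"compound {compound!r}, gene {gene!r} lacks a complete dose triple"
                )
            Y[row] = [triple[lvl] for lvl in DOSE_LEVELS]
            pairs.append((compound, gene))
            row += 1

    flat = (Y.max(axis=1) - Y.min(axis=1)) < cfg.flat_tolerance
    rm = Y[:, 0].copy()
    ec = np.full(len(Y), np.nan)
    bl = Y[:, 0].copy()
    rss = np.zeros(len(Y))
    if (~flat).any():
        rm[~flat], ec[~flat], bl[~flat], rss[~flat] = _fit_batch(Y[~flat], cfg)
    valid = (
        ~flat
        & np.isfinite(rm)
        & np.isfinite(bl)
        & (rss <= cfg.rss_tolerance)
        & (rm >= bl)
    )

    fits: dict[tuple[str, str], DoseResponseFit] = {}
    valid_counts = dict.fromkeys(genes, 0)
    for i, (compound, gene) in enumerate(pairs):
        fits[(compound, gene)] = DoseResponseFit(
            float(rm[i]), float(ec[i]), cfg.slope, float(bl[i]), float(rss[i]), bool(valid[i])
        )
        if valid[i]:
            valid_counts[gene] += 1

    n_comp = len(compounds)
    retained = [g for g in genes if valid_counts[g] >= cfg.min_valid_fraction * n_comp]
    log.info(
        "dose-response retained %d/%d genes over %d compounds", len(retained), len(genes), n_comp
    )
    features = np.empty((n_comp, len(retained)))
    comp_pos = {c: i for i, c in enumerate(compounds)}
    for j, gene in enumerate(retained):
        for compound in compounds:
            features[comp_pos[compound], j] = fits[(compound, gene)].r_max
    return features, compounds, retained, fits
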