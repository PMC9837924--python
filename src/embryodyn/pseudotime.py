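"""Developmental-time-unit (DTU) trajectory and circular gene ordering.

Stage samples are projected by PCA; the DTU of each stage is the cumulative
straight-line distance between consecutive stages in the leading PCs,
rescaled to [0, 10].  Per-gene profiles are loess-smoothed onto 500 uniform
grid points over [0, 10], z-scored, and ordered by the angle
atan2(PC2, PC1) of a gene-level PCA, exploiting the near-circular
arrangement of phase-shifted standardized profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .matrix import StageMatrix

log = logging.getLogger(__name__)


@dataclass
class StageTrajectory:
    stages: list[str]
    pcs: np.ndarray        # n_stages x n_pcs sample coordinates
    dtu: np.ndarray        # per-stage float in [0, 10], non-decreasing


@dataclass
class GeneOrder:
    gene_id: str
    angle: float           # radians in (-pi, pi]
    rank: int
    smoothed_profile: np.ndarray


def _pca_scores(x: np.ndarray, k: int) -> np.ndarray:
    """Scores of the first k principal components (observations in rows).

    Deterministic sign convention: each component's loading vector has a
    positive entry of largest absolute value.
    """
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(k, vt.shape[0])
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    return u[:, :k] * s[:k]


def trajectory_from_points(points: np.ndarray,
                           stages: list[str]) -> StageTrajectory:
    """DTU from explicit per-stage PC coordinates: cumulative adjacent
    Euclidean distances rescaled so the path ends at 10."""
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1))
    total = d.sum()
    if total == 0:
        raise ValueError("zero total path length: all stage points coincide")
    dtu = np.concatenate([[0.0], np.cumsum(d)]) / total * 10.0
    return StageTrajectory(stages=list(stages), pcs=pts, dtu=dtu)


def compute_dtu(expr: StageMatrix, n_pcs: int = 2) -> StageTrajectory:
    """PCA on per-gene z-scored stage means (stages as observations), then
    cumulative adjacent distances in the first n_pcs PCs scaled to [0, 10]."""
    if len(expr.stages) < 3:
        raise ValueError("need >= 3 stages")
    z = expr.zscored_stage_means()
    pcs = _pca_scores(z.values.T, n_pcs)   # stages x n_pcs
    return trajectory_from_points(pcs, expr.stages)


def loess_smoother_matrix(dtu: np.ndarray, n_points: int = 500,
                          span: float = 0.75, degree: int = 2) -> tuple:
    """Linear smoother L (n_points x n) with tricube local-polynomial rows.

    For each uniform grid point over [0, 10], at least
    max(degree + 1, ceil(span * n)) nearest design points receive tricube
    weights and a degree-`degree` weighted polynomial is fitted; the
    evaluation is linear in the responses, so smoothing a profile is L @ y.
    """
    x = np.asarray(dtu, dtype=float)
    n = x.size
    if n < degree + 2:
        raise ValueError("need more design points than polynomial degree + 1")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all dtu values equal")
    grid = np.linspace(0.0, 10.0, n_points)
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    L = np.zeros((n_points, n))
    powers = np.arange(degree + 1)
    for gi, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(np.max(d), 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        w[d <= h] = np.maximum(w[d <= h], 1e-12)  # keep k points in the fit
        X = ((x - x0)[:, None]) ** powers
        WX = X * w[:, None]
        # row of the hat matrix: e0^T (X^T W X)^+ X^T W
        beta_map = np.linalg.pinv(X.T @ WX) @ WX.T
        L[gi] = beta_map[0]
    return grid, L


def smooth_profile(values, dtu, n_points: int = 500, span: float = 0.75,
                   degree: int = 2) -> np.ndarray:
    """Loess-family smoothed curve of one profile on the uniform [0,10] grid."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(dtu, dtype=float)
    if y.size != x.size or y.size < 4:
        raise ValueError("values and dtu must have equal length >= 4")
    _, L = loess_smoother_matrix(x, n_points, span, degree)
    return L @ y


def angular_order(expr: StageMatrix, trajectory: StageTrajectory | None = None,
                  n_points: int = 500, span: float = 0.75, degree: int = 2,
                  use_smoothed_pca: bool = False) -> list[GeneOrder]:
    """Rank genes around the circle of standardized temporal profiles.

    Gene-level PCA runs over the z-scored stage-mean profiles (or, with
    ``use_smoothed_pca``, over the 500-point smoothed curves); the angle is
    atan2(PC2, PC1).  Rank 0 goes to the gene whose smoothed profile peaks
    earliest in DTU, and the direction of travel is chosen so that peak time
    increases with rank; ties keep input order.
    """
    if len(expr.stages) < 3:
        raise ValueError("need >= 3 stages")
    z = expr.zscored_stage_means()
    dropped = set(expr.gene_ids) - set(z.index)
    if dropped:
        log.info("angular_order: excluded %d zero-variance genes", len(dropped))
    if z.shape[0] < 3:
        raise ValueError("need >= 3 genes with non-constant profiles")
    traj = trajectory or compute_dtu(expr)
    _, L = loess_smoother_matrix(traj.dtu, n_points, span, degree)
    curves = z.values @ L.T
    # z-score the smoothed curves for the heatmap representation
    c_mu = curves.mean(axis=1, keepdims=True)
    c_sd = curves.std(axis=1, keepdims=True)
    c_sd[c_sd == 0] = 1.0
    curves_z = (curves - c_mu) / c_sd

    scores = _pca_scores(curves_z if use_smoothed_pca else z.values, 2)
    angles = np.arctan2(scores[:, 1], scores[:, 0])

    peak_idx = curves.argmax(axis=1)
    earliest = int(np.lexsort((np.arange(len(peak_idx)), peak_idx))[0])

    best = None
    for direction in (1.0, -1.0):
        rel = np.mod(direction * (angles - angles[earliest]), 2 * np.pi)
        order = np.lexsort((np.arange(rel.size), rel))
        ranks = np.empty(rel.size, dtype=int)
        ranks[order] = np.arange(rel.size)
        rho = spearmanr(ranks, peak_idx).statistic
        if best is None or rho > best[0]:
            best = (rho, ranks)
    ranks = best[1]

    return [
        GeneOrder(gene_id=gid, angle=float(a), rank=int(r),
                  smoothed_profile=curves_z[i])
        for i, (gid, a, r) in enumerate(zip(z.index, angles, ranks))
    ]


def order_heatmap_matrix(orders: list[GeneOrder]) -> pd.DataFrame:
    """Genes (sorted by rank) x 500-grid matrix of z-scored smoothed curves."""
    ordered = sorted(orders, key=lambda o: o.rank)
    return pd.DataFrame(
        [o.smoothed_profile for o in ordered],
        index=[o.gene_id for o in ordered],
    )


def circular_rank_agreement(ranks: np.ndarray, phases: np.ndarray) -> float:
    """Best Spearman correlation between a circular ranking and planted
    phases over all rotations of the circle (both directions)."""
    ranks = np.asarray(ranks)
    phase_rank = np.argsort(np.argsort(phases, kind="stable"), kind="stable")
    n = ranks.size
    best = -1.0
    for direction in (1, -1):
        r = (direction * ranks) % n
        for shift in range(n):
            rho = spearmanr((r + shift) % n, phase_rank).statistic
            best = max(best, rho)
    return float(best)
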