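"""Pseudotime trajectory smoothing, clustering and timing categories.

Pseudotime values are inputs (the ordering itself is inferred upstream).
Each gene's expression is binned over pseudotime (60 equal-width bins),
smoothed with a cubic smoothing spline (stiffness by generalized
cross-validation), min-max scaled to [0, 1], clustered by K-medians under
cosine similarity (k = 25 by default), and each cluster is labeled early /
transition / late by the argmax bin of its median profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

logger = logging.getLogger(__name__)


@dataclass
class TrajectorySet:
    gene_ids: pd.Index
    bin_centers: np.ndarray            # length n_bins, strictly increasing
    scaled: pd.DataFrame               # genes x bins, rows in [0, 1]
    constant: pd.Series                # flagged all-constant genes
    cluster: pd.Series | None = None   # 1..k
    category: pd.Series | None = None  # per cluster


def bin_smooth_trajectory(
    expr,
    pseudotime,
    n_bins: int = 60,
    lam: float | None = None,
) -> tuple[np.ndarray, bool]:
    """Smoothed, min-max scaled pseudotime profile for one gene.

    Cells are partitioned into ``n_bins`` equal-width bins over the
    observed pseudotime range; a cubic smoothing spline (GCV stiffness
    unless ``lam`` is given) is fit to the non-empty bin means and
    evaluated at every bin center, then scaled to [0, 1].  A constant
    profile cannot be scaled and is returned as all zeros with a flag.
    Fewer than 4 non-empty bins is an error.
    """
    e = np.asarray(expr, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    if np.unique(pt).size < 4:
        raise ValueError("need >= 4 distinct pseudotime values")
    lo, hi = pt.min(), pt.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    which = np.clip(np.digitize(pt, edges[1:-1]), 0, n_bins - 1)
    sums = np.bincount(which, weights=e, minlength=n_bins)
    cnts = np.bincount(which, minlength=n_bins)
    nonempty = cnts > 0
    if nonempty.sum() < 4:
        raise ValueError("fewer than 4 non-empty pseudotime bins")
    x = centers[nonempty]
    y = sums[nonempty] / cnts[nonempty]
    if np.ptp(y) == 0:  # constant profile: 0/0 scaling undefined
        return np.zeros(n_bins), True
    if nonempty.sum() >= 5:
        spline = make_smoothing_spline(x, y, lam=lam)
    else:  # 4 points: interpolating cubic (GCV needs 5+)
        spline = CubicSpline(x, y)
    smooth = np.asarray(spline(centers), dtype=float)
    rng_ = smooth.max() - smooth.min()
    if rng_ == 0:
        return np.zeros(n_bins), True
    return (smooth - smooth.min()) / rng_, False


def smooth_trajectories(
    expr: pd.DataFrame, pseudotime, n_bins: int = 60, lam: float | None = None
) -> TrajectorySet:
    """Apply :func:`bin_smooth_trajectory` to every gene (rows of ``expr``,
    columns = cells)."""
    mat = np.empty((expr.shape[0], n_bins))
    const = np.zeros(expr.shape[0], dtype=bool)
    pt = np.asarray(pseudotime, dtype=float)
    for i in range(expr.shape[0]):
        mat[i], const[i] = bin_smooth_trajectory(
            expr.iloc[i].to_numpy(), pt, n_bins=n_bins, lam=lam
        )
    lo, hi = pt.min(), pt.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    scaled = pd.DataFrame(mat, index=expr.index, columns=range(1, n_bins + 1))
    logger.info(
        "smooth_trajectories: %d genes x %d bins (%d constant rows flagged)",
        *scaled.shape, int(const.sum()),
    )
    return TrajectorySet(
        expr.index, centers, scaled, pd.Series(const, index=expr.index)
    )


def _cosine_sim(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    Xn = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
    Mn = medians / np.maximum(np.linalg.norm(medians, axis=1, keepdims=True), 1e-12)
    return Xn @ Mn.T


def kmedians_cosine(
    trajectories: pd.DataFrame,
    k: int = 25,
    seed: int = 0,
    max_iter: int = 100,
) -> tuple[pd.Series, np.ndarray, list[float]]:
    """K-medians clustering under cosine similarity.

    Assignment: maximal cosine similarity to a cluster median; update:
    coordinate-wise median of members; initialization: k-means++-style
    seeding by cosine distance.  An empty cluster is re-seeded from the
    worst-fit point (logged).  Iteration stops when assignments stop
    changing, at ``max_iter``, or if an update would increase the summed
    cosine distance (monotone safeguard — the update is reverted).

    Returns (assignment as 0-based labels, cluster medians k x n_bins,
    objective value per iteration).
    """
    X = trajectories.to_numpy(dtype=float)
    n = X.shape[0]
    if k > np.unique(X, axis=0).shape[0]:
        raise ValueError("k exceeds the number of distinct trajectories")
    rng = np.random.default_rng(seed)
    # k-means++-style init on cosine distance
    first = int(rng.integers(n))
    centers = [X[first]]
    for _ in range(1, k):
        d = 1 - _cosine_sim(X, np.array(centers)).max(axis=1)
        d = np.maximum(d, 0)
        if d.sum() == 0:
            probs = np.full(n, 1 / n)
        else:
            probs = d / d.sum()
        centers.append(X[int(rng.choice(n, p=probs))])
    medians = np.array(centers)
    labels = np.full(n, -1)
    objective: list[float] = []
    for it in range(max_iter):
        sim = _cosine_sim(X, medians)
        new_labels = sim.argmax(axis=1)
        obj = float((1 - sim[np.arange(n), new_labels]).sum())
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int((sim[np.arange(n), new_labels]).argmin())
                new_labels[worst] = c
                logger.info("kmedians_cosine: empty cluster %d re-seeded", c)
        if objective and obj > objective[-1] + 1e-12:
            break  # monotone safeguard: revert the last median update
        objective.append(obj)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        medians = np.array(
            [np.median(X[labels == c], axis=0) for c in range(k)]
        )
    logger.info(
        "kmedians_cosine: k=%d, %d iterations, final objective %.4f",
        k, len(objective), objective[-1],
    )
    return pd.Series(labels, index=trajectories.index), medians, objective


def categorize_clusters(
    cluster_medians: np.ndarray, boundaries=(20, 40)
) -> list[str]:
    """early / transition / late per cluster from the argmax bin of its
    median profile (1-based bins; ties resolve to the earliest bin)."""
    lo, hi = boundaries
    out = []
    for row in np.atleast_2d(cluster_medians):
        peak = int(np.argmax(row)) + 1
        out.append("early" if peak <= lo else "transition" if peak <= hi else "late")
    return out


def select_trajectory_genes(
    de_results: pd.DataFrame,
    p_cutoff: float = 0.001,
    top_n: int = 5000,
    p_column: str = "p",
) -> pd.Index:
    """Genes changing over pseudotime: p < cutoff, ranked ascending by p
    (lexical tie-break), top_n kept."""
    sig = de_results[de_results[p_column] < p_cutoff]
    sig = sig.sort_index().sort_values(p_column, kind="mergesort")
    return sig.index[:top_n]
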