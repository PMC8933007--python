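"""Motif statistics for accessibility change.

Two complementary views of transcription-factor involvement:

* a gene-centric binomial enrichment of each motif among peaks near a gene
  set of interest, against the frequency in all other peaks; and
* a gene-independent L2-penalized (ridge) logistic regression that scores
  every motif by how predictive its presence is of a peak gaining vs.
  losing accessibility over the time course.  A single split fit reports
  held-out AUC; coefficient estimates are averaged over bootstrap refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)


def peaks_near_genes(
    peaks, genes, window: int = 50_000
) -> pd.DataFrame:
    """Assign each peak to its nearest gene body within ``window`` bp.

    Distance is 0 for any overlap, else the gap between peak and gene body.
    Peaks farther than ``window`` from every gene are labeled intergenic
    (gene = None).  Ties break to the smaller gene start, then the
    lexically smaller gene id.
    """
    gdf = genes.df
    rows = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in gdf.groupby("chrom")}
    pdf = peaks.df
    for i, (chrom, ps, pe) in enumerate(zip(pdf["chrom"], pdf["start"], pdf["end"])):
        peak_id = pdf["name"].iat[i] or f"peak_{i}"
        g = by_chrom.get(chrom)
        if g is None:
            rows.append((peak_id, None, np.nan))
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        # 0 on overlap, else the gap between peak and gene body (half-open)
        dist = np.where((gs < pe) & (ge > ps), 0, np.maximum(gs - pe, ps - ge))
        best = dist.min()
        if best > window:
            rows.append((peak_id, None, np.nan))
            continue
        cand = np.flatnonzero(dist == best)
        order = sorted(cand, key=lambda j: (gs[j], g["name"].iat[j]))
        j = order[0]
        rows.append((peak_id, g["name"].iat[j], float(best)))
    out = pd.DataFrame(rows, columns=["peak_id", "gene", "distance"])
    n_inter = int(out["gene"].isna().sum())
    logger.info(
        "peaks_near_genes: %d peaks, %d assigned, %d intergenic (window=%d bp)",
        len(out), len(out) - n_inter, n_inter, window,
    )
    return out


def motif_enrichment_binomial(
    target_peaks, background_peaks, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-motif binomial enrichment of target peaks vs. background peaks.

    For each motif the background presence frequency p0 is the null; the
    p-value is the inclusive upper tail of Binomial(|targets|, p0) at the
    observed target hit count.  Degenerate p0 (0 or 1) is handled exactly:
    the certain event gives p = 1, an impossible observed event p = 0 with
    a flag.  Target and background must be disjoint and non-empty.
    """
    t = pd.Index(target_peaks)
    b = pd.Index(background_peaks)
    if len(t) == 0 or len(b) == 0:
        raise ValueError("target and background must be non-empty")
    if len(t.intersection(b)):
        raise ValueError("target and background peak sets overlap")
    Mt = matrix.loc[t].to_numpy()
    Mb = matrix.loc[b].to_numpy()
    n = len(t)
    k = Mt.sum(axis=0)
    p0 = Mb.mean(axis=0)
    pvals = np.empty(matrix.shape[1])
    flagged = np.zeros(matrix.shape[1], dtype=bool)
    for j in range(matrix.shape[1]):
        if p0[j] == 0.0:
            pvals[j] = 1.0 if k[j] == 0 else 0.0
            flagged[j] = k[j] > 0
        elif p0[j] == 1.0:
            pvals[j] = 1.0 if k[j] == n else 0.0
            flagged[j] = k[j] < n
        else:
            pvals[j] = stats.binom.sf(k[j] - 1, n, p0[j])
    return pd.DataFrame(
        {
            "fraction_in_target": k / n,
            "background_freq": p0,
            "p": pvals,
            "degenerate": flagged,
        },
        index=matrix.columns.rename("motif_id"),
    )


def prepare_labels(
    trend_results: pd.DataFrame,
    p_cutoff: float = 0.001,
    p_column: str = "q",
    fc_column: str = "beta1",
) -> pd.Series:
    """Label peaks 'up'/'down' from per-peak significance and signed change.

    up = significant and positive change; down = significant and negative;
    everything else is excluded from the returned series.
    """
    sig = trend_results[p_column] < p_cutoff
    fc = trend_results[fc_column]
    labels = pd.Series(index=trend_results.index, dtype=object)
    labels[sig & (fc > 0)] = "up"
    labels[sig & (fc < 0)] = "down"
    out = labels.dropna()
    logger.info(
        "prepare_labels: %d peaks -> %d up, %d down",
        len(trend_results), int((out == "up").sum()), int((out == "down").sum()),
    )
    return out


@dataclass
class MotifModelResult:
    """Ridge-model outputs: per-model coefficients, their mean and rank, the
    held-out AUC of the split fit, and the penalty/seeds used."""

    coefficients: pd.DataFrame  # motifs x models
    mean_coefficient: pd.Series
    rank: pd.Series  # 1 = largest mean coefficient
    auc: float | None
    penalty: float
    seeds: list = field(default_factory=list)


def _fit_ridge(X: np.ndarray, y: np.ndarray, penalty: float) -> LogisticRegression:
    # C is the inverse regularization strength; intercept unpenalized,
    # features kept as raw binaries (coefficients read as per-motif log-odds).
    clf = LogisticRegression(C=1.0 / penalty, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    return clf


def rank_auc(scores_pos, scores_neg) -> float:
    """AUC by the rank statistic: P(random positive outscores a random
    negative), ties counting half."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def ridge_motif_model(
    matrix: pd.DataFrame,
    labels: pd.Series,
    split_fraction: float = 2 / 3,
    penalty: float = 1.0,
    seed: int = 0,
) -> MotifModelResult:
    """Split fit: train on ``split_fraction`` of the labeled peaks
    (stratified), report held-out AUC for separating up from down peaks.
    """
    if labels.empty or labels.nunique() < 2:
        raise ValueError("both classes must be present; no peaks to fit")
    X = matrix.loc[labels.index].to_numpy(dtype=float)
    y = (labels == "up").to_numpy().astype(int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_fraction, stratify=y, random_state=seed
    )
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("single-class split; try a different seed")
    clf = _fit_ridge(X_tr, y_tr, penalty)
    scores = clf.decision_function(X_te)
    auc = rank_auc(scores[y_te == 1], scores[y_te == 0])
    coef = pd.Series(clf.coef_[0], index=matrix.columns, name="model_0")
    coefs = coef.to_frame()
    mean = coefs.mean(axis=1)
    rank = mean.rank(ascending=False, method="first").astype(int)
    logger.info("ridge_motif_model: held-out AUC %.3f (penalty %.3g)", auc, penalty)
    return MotifModelResult(coefs, mean, rank, auc, penalty, [seed])


def aggregate_coefficients(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_models: int = 10,
    penalty: float = 1.0,
    seed: int = 0,
    bootstrap: bool = True,
) -> MotifModelResult:
    """Average per-motif coefficients over ``n_models`` refits on all
    labeled peaks.

    Each refit uses a bootstrap resample of the peaks (so averaging is
    informative); ``bootstrap=False`` gives the degenerate reading of
    n identical full-data fits.  A single-class bootstrap draw is redrawn
    (logged).  Motifs are ranked by mean coefficient, 1 = largest.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if labels.empty or labels.nunique() < 2:
        raise ValueError("both classes must be present; no peaks to fit")
    X = matrix.loc[labels.index].to_numpy(dtype=float)
    y = (labels == "up").to_numpy().astype(int)
    rng = np.random.default_rng(seed)
    cols = {}
    seeds = []
    for m in range(n_models):
        if bootstrap:
            for attempt in range(100):
                idx = rng.integers(0, len(y), size=len(y))
                if len(np.unique(y[idx])) == 2:
                    break
                logger.warning("bootstrap %d: single-class draw, redrawing", m)
            else:
                raise ValueError("could not draw a two-class bootstrap sample")
            Xm, ym = X[idx], y[idx]
        else:
            Xm, ym = X, y
        clf = _fit_ridge(Xm, ym, penalty)
        cols[f"model_{m}"] = clf.coef_[0]
        seeds.append(seed)
    coefs = pd.DataFrame(cols, index=matrix.columns)
    mean = coefs.mean(axis=1)
    rank = mean.rank(ascending=False, method="first").astype(int)
    return MotifModelResult(coefs, mean, rank, None, penalty, seeds)


def select_ridge_penalty(
    matrix: pd.DataFrame,
    labels: pd.Series,
    grid=(0.1, 0.3, 1.0, 3.0, 10.0),
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the ridge penalty by 5-fold cross-validated log-loss."""
    X = matrix.loc[labels.index].to_numpy(dtype=float)
    y = (labels == "up").to_numpy().astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best, best_loss = None, np.inf
    for penalty in grid:
        loss = 0.0
        for tr, te in skf.split(X, y):
            clf = _fit_ridge(X[tr], y[tr], penalty)
            p = clf.predict_proba(X[te])[:, 1]
            eps = 1e-12
            loss -= np.mean(
                y[te] * np.log(p + eps) + (1 - y[te]) * np.log(1 - p + eps)
            )
        if loss < best_loss:
            best, best_loss = penalty, loss
    logger.info("select_ridge_penalty: chose %.3g", best)
    return float(best)
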