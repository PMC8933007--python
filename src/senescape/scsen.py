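"""Single-cell senescence stages.

Cells live in an AnnData (cells x genes, raw counts in .X, covariates in
.obs: pdl, line, phase, pseudotime).  The stages are: control-matched
module scoring, S/G2M/G1 phase assignment from the two cycle scores,
signature specificity between two perturbations, pseudobulk aggregation
with the >15-cell and top-8000-gene filters, and within-phase CPM+1 log2
fold changes against each phase's earliest PDL.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse

logger = logging.getLogger(__name__)

SCORE_LAYER = "lognorm"


def _dense(X) -> np.ndarray:
    return X.toarray() if scipy.sparse.issparse(X) else np.asarray(X)


def normalize_for_scoring(adata: ad.AnnData) -> None:
    """Add a log1p, library-size-normalized layer used for module scoring.

    Counts are scaled per cell to the median library size, then log1p
    transformed — a monotone normalized scale standing in for heavier
    variance-stabilizing transforms, which scoring does not need.
    """
    X = _dense(adata.X).astype(float)
    lib = X.sum(axis=1)
    if (lib <= 0).any():
        raise ValueError("cells with zero counts cannot be normalized")
    target = np.median(lib)
    adata.layers[SCORE_LAYER] = np.log1p(X * (target / lib)[:, None])


def module_score(
    adata: ad.AnnData,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    rng: np.random.Generator | None = None,
    layer: str = SCORE_LAYER,
) -> np.ndarray:
    """Control-matched module score per cell.

    score = mean expression over the gene set minus mean over a control
    pool drawn per set gene from the same average-expression bin (``n_bins``
    equal-count bins over all genes), ``n_ctrl`` controls per gene, without
    replacement within a bin where possible (a bin smaller than n_ctrl is
    used whole).
    """
    rng = rng if rng is not None else np.random.default_rng()
    genes = pd.Index(adata.var_names)
    set_genes = pd.Index(gene_set).intersection(genes)
    if len(set_genes) == 0:
        raise ValueError("gene set does not intersect the matrix genes")
    X = adata.layers[layer] if layer in adata.layers else _dense(adata.X).astype(float)
    X = _dense(X)
    avg = X.mean(axis=0)
    if np.unique(avg).size == 1:
        bins = np.zeros(len(genes), dtype=int)
    else:
        bins = pd.qcut(
            pd.Series(avg, index=genes).rank(method="first"), q=n_bins, labels=False
        ).to_numpy()
    bin_of = pd.Series(bins, index=genes)
    ctrl_cols: list[np.ndarray] = []
    for g in set_genes:
        b = bin_of[g]
        pool = np.flatnonzero(bins == b)
        if len(pool) <= n_ctrl:
            chosen = pool
        else:
            chosen = rng.choice(pool, size=n_ctrl, replace=False)
        ctrl_cols.append(chosen)
    ctrl_idx = np.concatenate(ctrl_cols)
    set_idx = genes.get_indexer(set_genes)
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return score


def assign_phase(s_score, g2m_score) -> pd.Series:
    """Phase call per cell from the S and G2M module scores.

    Both scores <= 0 -> G1; otherwise the phase of the larger score; an
    exact tie of positive scores resolves to S (logged).
    """
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    if np.isnan(s).any() or np.isnan(g).any():
        raise ValueError("missing phase score")
    phase = np.where((s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M"))
    ties = int(((s == g) & (s > 0)).sum())
    if ties:
        logger.info("assign_phase: %d positive-score ties resolved to S", ties)
    return pd.Series(phase)


def specific_signature(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    fc_cutoff: float = 0.5,
    p_cutoff: float = 0.01,
    p_column: str = "q",
    fc_column: str = "beta1",
) -> tuple[pd.Index, pd.Index]:
    """Genes induced uniquely in perturbation A or B.

    A gene is induced when p < p_cutoff and log2FC > fc_cutoff; unique-to-A
    means induced in A and not induced in B (and symmetrically).  The two
    tables must share a gene universe.
    """
    common = de_a.index.intersection(de_b.index)
    if len(common) == 0:
        raise ValueError("DE tables have disjoint gene universes")
    ind_a = de_a.loc[common].query(f"{p_column} < @p_cutoff and {fc_column} > @fc_cutoff").index
    ind_b = de_b.loc[common].query(f"{p_column} < @p_cutoff and {fc_column} > @fc_cutoff").index
    return ind_a.difference(ind_b), ind_b.difference(ind_a)


def pseudobulk_by_group(
    adata: ad.AnnData,
    group_keys=("pdl", "phase"),
    min_cells: int = 15,
    top_n_genes: int = 8000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum counts into (PDL, phase) pseudobulk profiles.

    Groups with <= ``min_cells`` cells are dropped (strictly more than 15
    cells are required to keep a group).  Genes are ranked by total summed
    counts across the kept groups — lexically tie-broken — and only the top
    ``top_n_genes`` retained.  Returns (pseudobulk genes x groups, group
    metadata with the grouping fields and cell counts).
    """
    obs = adata.obs
    for k in group_keys:
        if k not in obs.columns:
            raise ValueError(f"missing grouping field {k!r}")
    X = _dense(adata.X)
    groups = obs.groupby(list(group_keys), observed=True).indices
    cols, meta_rows = {}, []
    for key, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if len(idx) <= min_cells:
            continue
        name = "_".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        cols[name] = X[idx].sum(axis=0)
        meta_rows.append(
            dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
            | {"group": name, "n_cells": len(idx)}
        )
    if not cols:
        raise ValueError("no group passes the cell-count filter")
    pb = pd.DataFrame(cols, index=adata.var_names)
    totals = pb.sum(axis=1)
    # deterministic: total counts descending, gene id ascending on ties
    ranked = totals.sort_index().sort_values(ascending=False, kind="mergesort")
    keep = ranked.index[:top_n_genes]
    pb = pb.loc[keep]
    meta = pd.DataFrame(meta_rows).set_index("group")
    logger.info(
        "pseudobulk_by_group: %d groups kept, %d genes retained",
        pb.shape[1], pb.shape[0],
    )
    return pb, meta


def cpm_log2fc(
    pseudobulk: pd.DataFrame, group_meta: pd.DataFrame
) -> pd.DataFrame:
    """Within-phase log2 fold change of CPM+1 against the phase's earliest PDL.

    CPM_gs = 1e6 * c_gs / sum_g c_gs; value = log2((CPM+1)/(CPM_ref+1)).
    The reference group per phase is its earliest PDL; reference columns are
    identically 0 and retained for the caller to drop.
    """
    lib = pseudobulk.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size in pseudobulk")
    cpm = pseudobulk * (1e6 / lib)
    out = pd.DataFrame(index=pseudobulk.index, dtype=float)
    for phase, g in group_meta.groupby("phase", observed=True):
        ref_group = g["pdl"].astype(float).idxmin()
        ref = cpm[ref_group]
        for grp in g.index:
            out[grp] = np.log2((cpm[grp] + 1) / (ref + 1))
    return out[pseudobulk.columns.intersection(out.columns)]
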