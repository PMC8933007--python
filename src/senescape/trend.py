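"""Per-feature linear trend testing, FDR control, and the paired-control
normalizations used for metabolite time courses.

The core model, fit independently per feature (metabolite, protein, FRiP,
...), is ordinary least squares on a single timepoint covariate

    y_it = beta0 + beta1 * T_t + eps_it

with a two-sided t-test on beta1 at n - 2 degrees of freedom and
Benjamini-Hochberg adjustment across features.  No shrinkage or moderation
is applied across features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrixio import SampleMeta

logger = logging.getLogger(__name__)


def pdl_increment(seeded: float, harvested: float) -> float:
    """Population doublings accrued in one passage: log2(harvested/seeded).

    Additive over serial passages.  Both counts must be positive.
    """
    if seeded <= 0 or harvested <= 0:
        raise ValueError("cell counts must be positive")
    return float(np.log2(harvested / seeded))


def linear_trend_test(values: pd.DataFrame, covariate) -> pd.DataFrame:
    """OLS linear-trend test per feature.

    Parameters
    ----------
    values
        feature x sample matrix of log-scale abundances.
    covariate
        timepoint covariate T_t, one value per sample (column), used exactly
        as given.

    Returns a DataFrame with columns beta0, beta1, se1, t, p, q indexed by
    feature.  Requires >= 3 distinct covariate values (else the residual
    degrees of freedom cannot support the test); a constant covariate makes
    the slope unidentifiable and is an error.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape[0] != values.shape[1]:
        raise ValueError("covariate length != number of samples")
    if np.unique(x).size < 2:
        raise ValueError("constant covariate: slope unidentifiable")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct covariate values")
    y = values.to_numpy(dtype=float)
    n = x.size
    xbar = x.mean()
    xc = x - xbar
    sxx = float(xc @ xc)
    b1 = (y @ xc) / sxx
    b0 = y.mean(axis=1) - b1 * xbar
    resid = y - (b0[:, None] + np.outer(b1, x))
    rss = (resid**2).sum(axis=1)
    df = n - 2
    s2 = rss / df
    se1 = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se1 > 0, b1 / se1, np.where(b1 == 0, 0.0, np.inf * np.sign(b1)))
    p = 2 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {"beta0": b0, "beta1": b1, "se1": se1, "t": t, "p": p},
        index=values.index.rename("feature_id"),
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    logger.info("linear_trend_test: %d features, %d samples, df=%d", len(out), n, df)
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def protein_normalize(
    raw: pd.DataFrame, meta: SampleMeta, multiply: bool = True
) -> pd.DataFrame:
    """Scale each sample by its group's protein-concentration factor.

    The factor for group g (one cell line at one timepoint) is
    median_conc(g) / median_conc(all samples of that line); each raw value is
    multiplied by its group's factor (``multiply=False`` divides instead, for
    the alternative reading of the normalization direction).
    """
    m = meta.df
    if "protein_conc" not in m.columns or m["protein_conc"].isna().any():
        raise ValueError("every sample needs a protein concentration")
    factors = pd.Series(index=m.index, dtype=float)
    for line, g in m.groupby("line"):
        overall = g["protein_conc"].median()
        for _, gg in g.groupby("timepoint"):
            f = gg["protein_conc"].median() / overall
            factors.loc[gg.index] = f
    missing = [s for s in raw.columns if s not in factors.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    f = factors.reindex(raw.columns)
    return raw * f.to_numpy() if multiply else raw / f.to_numpy()


def paired_batch_correct(
    wt: pd.DataFrame,
    ctrl: pd.DataFrame,
    meta: SampleMeta,
    reference_timepoint: float,
) -> pd.DataFrame:
    """Divide each WT sample by its temporally paired control, then express
    as log2 fold change against the reference timepoint.

    Pairs are matched by replicate index within a timepoint; if the control
    has a different replicate count, the per-timepoint control mean is used
    instead.  The returned matrix holds log2(r_mt / r_m,ref) per metabolite
    and WT sample, with the reference columns (identically zero) dropped.
    A shared multiplicative batch factor applied to both members of a pair
    cancels exactly.  Zero or missing control values are hard errors.
    """
    m = meta.df
    wt_meta = m[m["line"] == "WT"]
    ctrl_meta = m[m["line"] == "control"]
    if not set(wt.columns) <= set(wt_meta.index):
        raise ValueError("WT matrix contains samples not in metadata")
    ratios = pd.DataFrame(index=wt.index, dtype=float)
    for tp, g in wt_meta.loc[list(wt.columns)].groupby("timepoint"):
        cg = ctrl_meta[ctrl_meta["timepoint"] == tp]
        if cg.empty:
            raise ValueError(f"no control sample at timepoint {tp}")
        csamples = [s for s in cg.index if s in ctrl.columns]
        if not csamples:
            raise ValueError(f"control samples for timepoint {tp} missing from matrix")
        by_rep = {int(cg.loc[s, "replicate"]): s for s in csamples}
        same_reps = len(csamples) == len(g)
        for s in g.index:
            rep = int(g.loc[s, "replicate"])
            if same_reps and rep in by_rep:
                denom = ctrl[by_rep[rep]]
            else:
                denom = ctrl[csamples].mean(axis=1)
            _check_positive(denom, tp)
            _check_positive(wt[s], tp)
            ratios[s] = wt[s] / denom
    ref_samples = wt_meta[wt_meta["timepoint"] == reference_timepoint]
    ref_cols = [s for s in ref_samples.index if s in ratios.columns]
    if not ref_cols:
        raise ValueError(f"reference timepoint {reference_timepoint} not present")
    ref = ratios[ref_cols].mean(axis=1)
    out = np.log2(ratios.div(ref, axis=0))
    out = out.drop(columns=ref_cols)
    logger.info(
        "paired_batch_correct: %d metabolites, %d WT samples (%d reference dropped)",
        out.shape[0], ratios.shape[1], len(ref_cols),
    )
    return out


def _check_positive(col: pd.Series, tp) -> None:
    bad = ~(col > 0)
    if bad.any():
        name = col.index[bad.to_numpy()][0]
        raise ValueError(
            f"zero/missing abundance for metabolite {name!r} at timepoint {tp}"
        )
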