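"""Chromatin-state accounting for ATAC peaks and reads.

Peaks are assigned to the 25-state genome segmentation with the strict
containment rule: a peak entirely inside one state instance is "inside"; a
peak that fully contains one or more instances of a single state, touching
no bp of any other state, is "inside_feature"; everything else (spanning a
state boundary, or partially overlapping a single instance without
containing it) is discarded.  Per-state signal fractions, quantile
normalization, per-state median fold-change summaries and the FRiP trend
round out the module.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .intervals import ChromatinStateMap, IntervalSet
from .matrixio import SampleMeta
from .trend import linear_trend_test

logger = logging.getLogger(__name__)


def assign_peaks_to_states(
    peaks: IntervalSet, states: ChromatinStateMap
) -> pd.DataFrame:
    """Assign each peak to a chromatin state or discard it.

    Returns a DataFrame with columns peak_id, state, relation
    ({inside, inside_feature, discarded}) and category.  A peak on a
    chromosome absent from the state map is a hard error (fixture mismatch).
    """
    by_chrom = {}
    for chrom, g in states.intervals.by_chrom().items():
        g = g.sort_values("start")
        by_chrom[chrom] = (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["name"].to_numpy(),
        )
    rows = []
    pdf = peaks.df
    names = pdf["name"].to_numpy()
    for i, (chrom, ps, pe) in enumerate(
        zip(pdf["chrom"], pdf["start"], pdf["end"])
    ):
        if chrom not in by_chrom:
            raise ValueError(f"peak chromosome {chrom!r} absent from state map")
        starts, ends, snames = by_chrom[chrom]
        i0 = int(np.searchsorted(ends, ps, side="right"))
        i1 = int(np.searchsorted(starts, pe, side="left"))
        peak_id = names[i] if names[i] else f"peak_{i}"
        if i1 <= i0:  # no overlap at all (gap in the tiling)
            rows.append((peak_id, "discarded", "discarded", None))
            continue
        ov_states = set(snames[i0:i1])
        if i1 - i0 == 1 and ps >= starts[i0] and pe <= ends[i0]:
            state = snames[i0]
            rows.append((peak_id, state, "inside", states.category_of(state)))
        elif len(ov_states) == 1 and any(
            ps <= starts[j] and pe >= ends[j] for j in range(i0, i1)
        ):
            state = snames[i0]
            rows.append(
                (peak_id, state, "inside_feature", states.category_of(state))
            )
        else:
            rows.append((peak_id, "discarded", "discarded", None))
    out = pd.DataFrame(rows, columns=["peak_id", "state", "relation", "category"])
    n_kept = int((out["relation"] != "discarded").sum())
    logger.info(
        "assign_peaks_to_states: %d peaks in, %d assigned, %d discarded",
        len(out), n_kept, len(out) - n_kept,
    )
    return out


def state_signal_fractions(
    signal: pd.DataFrame,
    instance_states: pd.Series,
    states: ChromatinStateMap,
    grouping: str = "state",
) -> pd.DataFrame:
    """Per-sample fraction of signal in each state (or 4-way category).

    ``signal`` is per-state-instance counts (instances x samples);
    ``instance_states`` maps each instance id to its state.  Instances of
    the same state are summed before normalization, so fractions over the
    grouping sum to 1 per sample.
    """
    if (signal.to_numpy() < 0).any():
        raise ValueError("negative signal counts")
    key = instance_states.reindex(signal.index)
    if key.isna().any():
        raise ValueError("instances without a state label")
    if grouping == "category":
        key = key.map(states.state_categories)
    elif grouping != "state":
        raise ValueError("grouping must be 'state' or 'category'")
    summed = signal.groupby(key.to_numpy()).sum()
    totals = summed.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[(totals == 0).to_numpy()][0]
        raise ValueError(f"all-zero sample {bad!r}")
    return summed / totals


def depth_normalize(matrix: pd.DataFrame, depths) -> pd.DataFrame:
    """Scale each sample by its sequencing depth (relative library size),
    preserving the mean depth so counts stay on their original scale.

    Depth is an external per-sample observable (total sequenced reads);
    unlike distribution-matching normalizations it stays unbiased when
    accessibility genuinely shifts one way across the genome.
    """
    d = np.asarray(depths, dtype=float)
    if (d <= 0).any():
        raise ValueError("depths must be positive")
    if d.size != matrix.shape[1]:
        raise ValueError("one depth per sample required")
    return matrix * (d.mean() / d)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to a common distribution.

    Every output column holds the per-rank row means of the column-sorted
    input; within-column order is preserved and ties receive the mean of
    the reference values their ranks span.  A single-column matrix is
    returned unchanged with a warning.
    """
    if matrix.isna().any().any():
        raise ValueError("missing values not allowed")
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    cs = np.concatenate(([0.0], np.cumsum(ref)))
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # tie-group boundaries in sorted order
        boundary = np.concatenate(([True], sorted_col[1:] != sorted_col[:-1]))
        group = np.cumsum(boundary) - 1
        firsts = np.flatnonzero(boundary)
        lasts = np.concatenate((firsts[1:], [n])) - 1
        gmeans = (cs[lasts + 1] - cs[firsts]) / (lasts - firsts + 1)
        vals = gmeans[group]
        out[order, j] = vals
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def state_fc_summary(
    normalized: pd.DataFrame,
    assignment: pd.DataFrame,
    trend_results: pd.DataFrame,
    meta: SampleMeta,
    sig_cutoff: float = 0.001,
    p_column: str = "q",
) -> pd.DataFrame:
    """Median log2 fold change per state per sample over significant peaks.

    Fold changes are computed from the (quantile-normalized) counts with a
    +1 pseudocount against the mean of the reference-timepoint replicates
    (the earliest timepoint of each line).  Only peaks with
    ``trend_results[p_column] < sig_cutoff`` contribute; states with no
    qualifying peak get NaN, never 0.
    """
    if not 0 < sig_cutoff <= 1:
        raise ValueError("significance cutoff must be in (0, 1]")
    sig_peaks = trend_results.index[trend_results[p_column] < sig_cutoff]
    kept = assignment[
        (assignment["relation"] != "discarded")
        & assignment["peak_id"].isin(sig_peaks)
    ]
    m = meta.df.loc[list(normalized.columns)]
    fc = pd.DataFrame(index=normalized.index, dtype=float)
    for line, g in m.groupby("line"):
        ref_tp = g["timepoint"].min()
        ref_cols = g.index[g["timepoint"] == ref_tp]
        ref_mean = normalized[ref_cols].mean(axis=1)
        for s in g.index:
            fc[s] = np.log2((normalized[s] + 1) / (ref_mean + 1))
    fc = fc[normalized.columns]
    rows = {}
    for state, gg in kept.groupby("state"):
        rows[state] = fc.loc[gg["peak_id"]].median(axis=0)
    out = pd.DataFrame(rows).T.reindex(columns=normalized.columns)
    out.index.name = "state"
    logger.info(
        "state_fc_summary: %d significant assigned peaks over %d states",
        len(kept), out.shape[0],
    )
    return out


def frip_trend(
    reads_in_peaks, total_reads, meta: SampleMeta
) -> tuple[np.ndarray, float, float]:
    """FRiP per sample and its linear trend against the PDL covariate.

    Returns (frip values, slope, p).  FRiP = reads_in_peaks / total in
    [0, 1]; the slope and p-value come from the per-feature OLS trend test
    applied to the single FRiP "feature".
    """
    rip = np.asarray(reads_in_peaks, dtype=float)
    tot = np.asarray(total_reads, dtype=float)
    if (tot <= 0).any():
        raise ValueError("total read counts must be positive")
    if (rip > tot).any():
        raise ValueError("reads in peaks exceed total reads")
    f = rip / tot
    values = pd.DataFrame([f], index=["FRiP"], columns=meta.df.index)
    res = linear_trend_test(values, meta.df["timepoint"].to_numpy())
    return f, float(res["beta1"].iloc[0]), float(res["p"].iloc[0])
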