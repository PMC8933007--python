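"""Domain-overlap statistics.

Permutation overlap tests with expression-matched nulls (genes resampled
from the same expression distribution as the targets, in deciles), the
rank-sum shift test for fold changes inside vs. outside a domain class,
hypergeometric motif-in-domain enrichment, and the OLS interaction test
for greater-than-additive motif x domain effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, overlap_flags

logger = logging.getLogger(__name__)


@dataclass
class OverlapTestResult:
    observed: int
    null_draws: np.ndarray
    z: float
    p_emp: float
    alternative: str
    degenerate_sd: bool = False

    @property
    def null_mean(self) -> float:
        return float(self.null_draws.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_draws.std(ddof=1))


def expression_matched_sample(
    universe: pd.Index | list,
    expression: pd.Series,
    targets: pd.Index | list,
    rng: np.random.Generator,
    n_bins: int = 10,
) -> np.ndarray:
    """Sample |targets| genes from the universe, matching the targets'
    per-expression-decile counts.

    Bins are equal-count quantile bins of the universe's expression score
    (single bin when all scores tie, reducing to simple random sampling).
    Drawing is without replacement within each bin; a bin with fewer
    universe genes than the targets require is an error.
    """
    pools, counts = _matched_pools(universe, expression, targets, n_bins)
    sampled = [
        rng.choice(pool, size=cnt, replace=False) for pool, cnt in zip(pools, counts)
    ]
    return np.concatenate(sampled) if sampled else np.array([], dtype=object)


def _matched_pools(universe, expression, targets, n_bins: int = 10):
    """Per-expression-bin universe pools and target counts (precomputable)."""
    universe = pd.Index(universe)
    targets = pd.Index(targets)
    if not targets.isin(universe).all():
        raise ValueError("targets must be a subset of the universe")
    expr = expression.reindex(universe)
    if expr.isna().any():
        raise ValueError("every universe gene needs an expression score")
    if expr.nunique() == 1:
        bins = pd.Series(0, index=universe)
    else:
        bins = pd.Series(
            pd.qcut(expr.rank(method="first"), q=n_bins, labels=False), index=universe
        )
    pools, counts = [], []
    target_bins = bins.reindex(targets)
    for b, cnt in target_bins.value_counts().items():
        pool = universe[(bins == b).to_numpy()].to_numpy()
        if len(pool) < cnt:
            raise ValueError(
                f"expression bin {b} has {len(pool)} genes, {cnt} required"
            )
        pools.append(pool)
        counts.append(int(cnt))
    return pools, counts


def permutation_overlap_test(
    targets,
    domains: IntervalSet,
    universe: IntervalSet,
    expression: pd.Series | None = None,
    n_perm: int = 1000,
    alternative: str = "greater",
    rng: np.random.Generator | None = None,
    matched: bool = True,
) -> OverlapTestResult:
    """Permutation test for target genes overlapping a domain set.

    ``targets`` are gene names drawn from ``universe`` (an IntervalSet of
    gene bodies with unique names).  The observed statistic is the number
    of target genes with >= 1 bp inside any domain.  Null draws resample
    gene sets of the same size from the universe — expression-matched in
    deciles when ``matched`` (requires ``expression``), simple random
    otherwise.  z = (obs - mean)/sd of the null; the empirical p-value uses
    the add-one rule so it is never 0.  sd = 0 nulls are flagged and
    reported with z = 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(universe) == 0:
        raise ValueError("empty universe")
    targets = pd.Index(targets)
    if len(targets) == 0:
        raise ValueError("empty target set")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = rng if rng is not None else np.random.default_rng()
    names = pd.Index(universe.df["name"])
    if names.has_duplicates:
        raise ValueError("universe gene names must be unique")
    flags = pd.Series(overlap_flags(universe, domains), index=names)
    if not targets.isin(names).all():
        raise ValueError("targets not all present in universe")
    observed = int(flags.reindex(targets).sum())
    null = np.empty(n_perm, dtype=np.int64)
    if matched:
        if expression is None:
            raise ValueError("expression scores required for matched sampling")
        pools, counts = _matched_pools(names, expression, targets)
        flag_pools = [flags.reindex(pool).to_numpy() for pool in pools]
        for i in range(n_perm):
            null[i] = sum(
                int(fp[rng.choice(fp.size, size=cnt, replace=False)].sum())
                for fp, cnt in zip(flag_pools, counts)
            )
    else:
        flag_arr = flags.to_numpy()
        for i in range(n_perm):
            idx = rng.choice(len(names), size=len(targets), replace=False)
            null[i] = int(flag_arr[idx].sum())
    sd = null.std(ddof=1)
    degenerate = sd == 0
    z = 0.0 if degenerate else float((observed - null.mean()) / sd)
    if alternative == "greater":
        extreme = int((null >= observed).sum())
    else:
        extreme = int((null <= observed).sum())
    p_emp = (1 + extreme) / (1 + n_perm)
    logger.info(
        "permutation_overlap_test: obs=%d null_mean=%.2f z=%.2f p=%.4g (n_perm=%d)",
        observed, null.mean(), z, p_emp, n_perm,
    )
    return OverlapTestResult(observed, null, z, p_emp, alternative, degenerate)


def domain_shift_test(
    peak_log2fc,
    in_domain,
    alternative: str = "two-sided",
) -> tuple[float, float, float, float]:
    """Wilcoxon rank-sum test of fold-change shift inside vs. outside a domain.

    Returns (median_in, median_out, W, p) where W is the rank sum of the
    in-domain group.  Exact enumeration is used for tie-free groups of
    size <= 25; otherwise the tie-corrected normal approximation.
    """
    fc = np.asarray(peak_log2fc, dtype=float)
    mask = np.asarray(in_domain, dtype=bool)
    x, y = fc[mask], fc[~mask]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(fc).size < fc.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U1 -> rank sum
    return float(np.median(x)), float(np.median(y)), w, float(res.pvalue)


def motif_domain_enrichment(motif_flags, domain_flags) -> float:
    """One-sided (greater) hypergeometric p for motif peaks inside a domain.

    Urn: all peaks; successes: peaks carrying the motif; draws: peaks in
    the domain; p is the upper tail at the observed in-domain motif count,
    inclusive.
    """
    m = np.asarray(motif_flags, dtype=bool)
    d = np.asarray(domain_flags, dtype=bool)
    if m.size != d.size:
        raise ValueError("flag vectors differ in length")
    if m.size == 0:
        raise ValueError("empty peak set")
    N, K, n = m.size, int(m.sum()), int(d.sum())
    k = int((m & d).sum())
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def interaction_test(
    peak_log2fc, motif_flag, domain_flag
) -> tuple[pd.Series, float]:
    """OLS test for a greater-than-additive motif x domain accessibility gain.

    Fits log2FC ~ 1 + motif + domain + motif*domain and returns the
    coefficient series (intercept, motif, domain, interaction) together
    with the one-sided p-value for interaction > 0.  All four cells of the
    2x2 design must be populated.
    """
    y = np.asarray(peak_log2fc, dtype=float)
    m = np.asarray(motif_flag, dtype=float)
    d = np.asarray(domain_flag, dtype=float)
    for mm in (0, 1):
        for dd in (0, 1):
            if not np.any((m == mm) & (d == dd)):
                raise ValueError(f"empty design cell (motif={mm}, domain={dd})")
    X = np.column_stack([np.ones_like(y), m, d, m * d])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = y.size - 4
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(XtX)
    se_int = np.sqrt(cov[3, 3])
    t = beta[3] / se_int
    p_one_sided = float(stats.t.sf(t, df))
    coefs = pd.Series(beta, index=["intercept", "motif", "domain", "interaction"])
    return coefs, p_one_sided
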