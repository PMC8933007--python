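"""Synthetic fixtures with the statistical structure of a replicative-
senescence multiomics time course.

Every generator is a pure function of its spec (including the seed):
identical inputs give identical outputs.  Each dataset ships with a truth
table sufficient to compute recovery metrics downstream.

The planted structure mirrors the study design the analyses assume:

* a 25-state genome segmentation with a large, gene-poor "undefined" state
  that NADs and LADs preferentially occupy;
* negative-binomial ATAC counts whose planted per-peak log2 fold changes
  over the PDL covariate are concentrated in NAD-/LAD-overlapping peaks
  (default medians 0.98 in NADs, 0.24 in LADs outside NADs, 0 elsewhere);
* a binary peak x motif matrix with a planted logistic coefficient vector
  generating up/down accessibility labels;
* single cells whose senescence-program expression rises deterministically
  with PDL in every cell-cycle phase, on top of a PDL-dependent phase
  schedule;
* WT/control metabolite pairs sharing an exact per-timepoint batch factor,
  with linear trends planted only in the WT line;
* pseudotime expression profiles drawn from bump archetypes peaking in the
  early / middle / late third of pseudotime.

Counts use the (mean, dispersion) negative binomial with
Var = mu + alpha * mu^2; alpha -> 0 recovers Poisson.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .intervals import (
    DEFAULT_STATE_CATEGORIES,
    UNDEFINED_STATE,
    ChromatinStateMap,
    IntervalSet,
    overlap_flags,
    write_bed,
)
from .matrixio import SampleMeta, write_matrix

logger = logging.getLogger(__name__)


def _default_state_proportions() -> dict[str, float]:
    # undefined state holds half the genome; the rest is split evenly
    props = {s: 0.5 / 24 for s in DEFAULT_STATE_CATEGORIES}
    props[UNDEFINED_STATE] = 0.5
    return props


@dataclass
class GenomeSpec:
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    state_proportions: dict[str, float] = field(
        default_factory=_default_state_proportions
    )
    undefined_chunk_bp: int = 250_000  # undefined state laid down in long runs
    other_chunk_bp: int = 10_000
    n_nads: int = 10           # per chromosome
    n_lads: int = 10
    domain_length: int = 150_000
    placement_bias: float = 0.9  # fraction of domains forced inside undefined runs
    n_genes: int = 1000
    gene_length: int = 5000
    nad_gene_density_ratio: float = 0.25  # genes per bp in NADs vs. outside
    expr_log_mean: float = 1.0  # log-normal expression score parameters
    expr_log_sd: float = 1.0


@dataclass
class AtacSpec:
    n_peaks: int = 5000
    peak_length: int = 400
    # ATAC peaks concentrate in open chromatin: only this fraction of peaks
    # is placed inside undefined-state territory (where NADs/LADs sit)
    frac_peaks_undefined: float = 0.15
    pdls: tuple = (20, 25, 30, 35, 40, 45, 50)
    n_replicates: int = 3
    median_l2fc_nad: float = 0.98   # planted medians by domain class
    median_l2fc_lad: float = 0.24
    median_l2fc_bg: float = 0.0
    l2fc_sd_domain: float = 0.25
    l2fc_sd_bg: float = 0.10
    dispersion: float = 0.02
    baseline_log_mean: float = np.log(150.0)
    baseline_log_sd: float = 0.5
    library_size_range: tuple = (0.8, 1.2)


@dataclass
class MotifSpec:
    n_peaks: int = 5000
    n_motifs: int = 100
    presence_freq: float = 0.1
    # one strongly predictive motif: with intercept -4 and coefficient +8 the
    # planted motif nearly determines the label (analytic AUC ~ 0.93)
    planted_coefficients: np.ndarray | None = None
    planted_index: int = 0
    planted_value: float = 8.0
    intercept: float = -4.0

    def coefficients(self) -> np.ndarray:
        if self.planted_coefficients is not None:
            beta = np.asarray(self.planted_coefficients, dtype=float)
            if beta.size != self.n_motifs:
                raise ValueError("coefficient vector length != n_motifs")
            return beta
        beta = np.zeros(self.n_motifs)
        beta[self.planted_index] = self.planted_value
        return beta


@dataclass
class CellsSpec:
    pdls: tuple = (25, 30, 35, 40, 45, 50)
    cells_per_pdl: int = 500
    n_genes: int = 2000
    program_size: int = 200
    n_phase_markers: int = 50     # per S and G2M marker set
    program_slope: float = 1.0    # log2 units over the full PDL range
    program_noise_sd: float = 0.1
    cycling_start: float = 0.55   # S+G2M fraction at the first PDL ...
    cycling_end: float = 0.10     # ... and at the last
    phase_marker_l2fc: float = 1.5
    base_log_mean: float = np.log(0.5)
    base_log_sd: float = 1.0
    dispersion: float = 0.1


@dataclass
class MetabSpec:
    n_metabolites: int = 100
    timepoints: tuple = (33, 37, 46, 50)  # the sampled passage vector
    n_replicates: int = 3
    frac_null: float = 0.5
    slope_range: tuple = (0.5, 1.5)  # |trend| for non-null metabolites
    batch_sd: float = 0.5
    noise_sd: float = 0.1
    base_log_mean: float = 8.0
    base_log_sd: float = 1.0
    protein_conc_sd: float = 0.05


@dataclass
class PseudotimeSpec:
    n_cells: int = 3000
    genes_per_archetype: int = 100
    centers: tuple = (0.15, 0.5, 0.85)  # bump peaks in each third
    width: float = 0.12
    noise_sd: float = 0.1


@dataclass
class SimulationSpec:
    """Bundle of all generator parameters plus the master seed."""

    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    atac: AtacSpec = field(default_factory=AtacSpec)
    motif: MotifSpec = field(default_factory=MotifSpec)
    cells: CellsSpec = field(default_factory=CellsSpec)
    metab: MetabSpec = field(default_factory=MetabSpec)
    pt: PseudotimeSpec = field(default_factory=PseudotimeSpec)

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-component sub-stream of the master seed."""
        streams = ["genome", "atac", "motif", "cells", "metab", "pt"]
        child = np.random.SeedSequence(self.seed).spawn(len(streams))
        return np.random.default_rng(child[streams.index(stream)])


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial draws with Var = mu + alpha mu^2 (Poisson at alpha=0)."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _clear_of(domains: IntervalSet, chrom: str, start: int, end: int) -> bool:
    """True when [start, end) on chrom touches no domain bp."""
    if len(domains) == 0:
        return True
    d = domains.df
    m = d["chrom"] == chrom
    return not ((d.loc[m, "start"] < end) & (d.loc[m, "end"] > start)).any()


# ---------------------------------------------------------------------------
# genome fixture


def make_genome_fixture(
    spec: SimulationSpec,
) -> tuple[ChromatinStateMap, IntervalSet, IntervalSet, IntervalSet]:
    """Chromatin-state tiling, NADs, LADs and scored gene bodies.

    The segmentation is built by chunking each state's bp share (undefined
    in long runs, other states in short chunks) and shuffling chunk order,
    so state bp proportions are exact up to chunk rounding.  A fixed count
    ceil(bias * n) of NADs (and LADs) is placed wholly inside undefined
    runs, guaranteeing the undefined-bp fraction of domain territory is at
    least the placement bias.  Genes avoid NADs at the configured density
    ratio and carry log-normal expression scores.
    """
    g = spec.genome
    rng = spec.rng("genome")
    props = g.state_proportions
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"state proportions sum to {total}, expected 1")
    state_rows = []
    undefined_runs: list[tuple[str, int, int]] = []
    for ci in range(g.n_chrom):
        chrom = f"chr{ci + 1}"
        chunks: list[tuple[str, int]] = []
        for state, p in sorted(props.items(), key=lambda kv: int(kv[0])):
            bp = int(round(p * g.chrom_length))
            size = g.undefined_chunk_bp if state == UNDEFINED_STATE else g.other_chunk_bp
            n_chunks, rem = divmod(bp, size)
            chunks += [(state, size)] * n_chunks
            if rem > 0:
                chunks.append((state, rem))
        order = rng.permutation(len(chunks))
        pos = 0
        rows_here = []
        for idx in order:
            state, size = chunks[idx]
            end = min(pos + size, g.chrom_length)
            if end <= pos:
                break
            rows_here.append((chrom, pos, end, state))
            pos = end
        if pos < g.chrom_length:  # chunk rounding: stretch the final segment
            chrom_, s_, _, state_ = rows_here[-1]
            rows_here[-1] = (chrom_, s_, g.chrom_length, state_)
        for chrom_, s_, e_, state_ in rows_here:
            state_rows.append((chrom_, s_, e_, state_))
            if state_ == UNDEFINED_STATE and e_ - s_ >= g.domain_length:
                undefined_runs.append((chrom_, s_, e_))
    states = ChromatinStateMap(IntervalSet.from_records(state_rows))

    def place_domains(n_per_chrom: int, label: str) -> IntervalSet:
        rows = []
        n_total = n_per_chrom * g.n_chrom
        n_biased = int(np.ceil(g.placement_bias * n_total))
        runs = list(undefined_runs)
        if n_biased > 0 and not runs:
            raise ValueError("no undefined run long enough to host a domain")
        run_choice = rng.choice(len(runs), size=n_biased, replace=len(runs) < n_biased)
        for i in range(n_total):
            if i < n_biased:
                chrom, rs, re_ = runs[run_choice[i]]
                start = int(rng.integers(rs, re_ - g.domain_length + 1))
            else:
                chrom = f"chr{rng.integers(g.n_chrom) + 1}"
                start = int(rng.integers(0, g.chrom_length - g.domain_length))
            rows.append((chrom, start, start + g.domain_length, f"{label}_{i}"))
        return IntervalSet.from_records(rows)

    nads = (
        place_domains(g.n_nads, "NAD") if g.n_nads > 0 else IntervalSet.from_records([])
    )
    lads = (
        place_domains(g.n_lads, "LAD") if g.n_lads > 0 else IntervalSet.from_records([])
    )

    # genes: reduced density inside NADs, log-normal expression scores
    nad_bp_frac = 0.0
    if len(nads):
        nad_bp_frac = min(
            1.0, nads.total_bp() / (g.n_chrom * g.chrom_length)
        )
    n_in = int(np.floor(g.nad_gene_density_ratio * nad_bp_frac * g.n_genes))
    gene_rows = []
    for i in range(g.n_genes):
        name = f"G{i:05d}"
        if i < n_in and len(nads):
            j = int(rng.integers(len(nads)))
            rec = nads.df.iloc[j]
            start = int(rng.integers(rec["start"], rec["end"] - g.gene_length))
            gene_rows.append((rec["chrom"], start, start + g.gene_length, name))
        else:
            for _ in range(1000):
                chrom = f"chr{rng.integers(g.n_chrom) + 1}"
                start = int(rng.integers(0, g.chrom_length - g.gene_length))
                if _clear_of(nads, chrom, start, start + g.gene_length):
                    gene_rows.append((chrom, start, start + g.gene_length, name))
                    break
            else:
                raise RuntimeError("could not place gene outside NADs")
    scores = rng.lognormal(g.expr_log_mean, g.expr_log_sd, size=g.n_genes)
    genes = IntervalSet.from_records(
        [(c, s, e, n, sc) for (c, s, e, n), sc in zip(gene_rows, scores)]
    ).sort()
    logger.info(
        "make_genome_fixture: %d state instances, %d NADs, %d LADs, %d genes",
        len(states.intervals), len(nads), len(lads), len(genes),
    )
    return states, nads, lads, genes


def _sample_in_intervals(
    rng: np.random.Generator, intervals: pd.DataFrame, n: int, length: int
) -> list[tuple[str, int]]:
    """Uniformly sample n start positions of ``length``-bp windows within a
    set of intervals (bp-weighted over intervals that can host a window)."""
    host = intervals[(intervals["end"] - intervals["start"]) >= length]
    if host.empty:
        raise ValueError("no interval long enough to host a peak")
    span = (host["end"] - host["start"]).to_numpy()
    probs = span / span.sum()
    picks = rng.choice(len(host), size=n, p=probs)
    out = []
    for j in picks:
        rec = host.iloc[j]
        # windows may run past the interval end (peaks straddle state
        # boundaries at the natural edge rate)
        start = int(rng.integers(rec["start"], rec["end"]))
        out.append((rec["chrom"], start))
    return out


# ---------------------------------------------------------------------------
# ATAC counts


def simulate_atac(
    spec: SimulationSpec,
    nads: IntervalSet,
    lads: IntervalSet,
    states: ChromatinStateMap | None = None,
) -> tuple[IntervalSet, pd.DataFrame, SampleMeta, pd.DataFrame]:
    """Peaks, NB count matrix, sample metadata and the planted truth table.

    Counts follow mu_ps = L_s * b_p * 2^(f_p * x_s) with x_s the PDL scaled
    to [0, 1]; f_p is drawn from a domain-dependent normal whose medians
    default to the NAD / LAD / background values above.  When a state map
    is given, peak placement is accessibility-weighted: only
    ``frac_peaks_undefined`` of peaks land in undefined-state territory
    (where the domains sit), the rest in the remainder of the genome —
    peaks are called where chromatin is open, so unchanged background
    peaks dominate the atlas as they do in real data.
    """
    a = spec.atac
    g = spec.genome
    rng = spec.rng("atac")
    if not all(lo > 0 for lo in a.library_size_range):
        raise ValueError("library sizes must be positive")
    if states is not None:
        sdf = states.intervals.df
        und = sdf[sdf["name"] == states.undefined_state]
        other = sdf[sdf["name"] != states.undefined_state]
        n_und = int(round(a.frac_peaks_undefined * a.n_peaks))
        positions = _sample_in_intervals(
            rng, und, n_und, a.peak_length
        ) + _sample_in_intervals(rng, other, a.n_peaks - n_und, a.peak_length)
        order = rng.permutation(a.n_peaks)
        positions = [
            (c, min(s, g.chrom_length - a.peak_length))
            for c, s in (positions[i] for i in order)
        ]
    else:
        chroms = rng.integers(g.n_chrom, size=a.n_peaks) + 1
        starts = rng.integers(0, g.chrom_length - a.peak_length, size=a.n_peaks)
        positions = [(f"chr{c}", int(s)) for c, s in zip(chroms, starts)]
    peaks = IntervalSet.from_records(
        [
            (chrom, s, s + a.peak_length, f"peak_{i:05d}")
            for i, (chrom, s) in enumerate(positions)
        ]
    )
    in_nad = overlap_flags(peaks, nads) if len(nads) else np.zeros(a.n_peaks, bool)
    in_lad = overlap_flags(peaks, lads) if len(lads) else np.zeros(a.n_peaks, bool)
    f = rng.normal(a.median_l2fc_bg, a.l2fc_sd_bg, size=a.n_peaks)
    lad_only = in_lad & ~in_nad
    f[in_nad] = rng.normal(a.median_l2fc_nad, a.l2fc_sd_domain, size=int(in_nad.sum()))
    f[lad_only] = rng.normal(
        a.median_l2fc_lad, a.l2fc_sd_domain, size=int(lad_only.sum())
    )
    baseline = rng.lognormal(a.baseline_log_mean, a.baseline_log_sd, size=a.n_peaks)
    pdls = np.repeat(a.pdls, a.n_replicates).astype(float)
    reps = np.tile(np.arange(1, a.n_replicates + 1), len(a.pdls))
    sample_ids = [f"WT_PDL{int(p)}_r{r}" for p, r in zip(pdls, reps)]
    x = (pdls - pdls.min()) / (pdls.max() - pdls.min())
    lib = rng.uniform(*a.library_size_range, size=len(pdls))
    mu = lib[None, :] * baseline[:, None] * 2 ** (f[:, None] * x[None, :])
    counts = pd.DataFrame(
        nb_counts(rng, mu, a.dispersion),
        index=peaks.df["name"].to_numpy(),
        columns=sample_ids,
    )
    meta = SampleMeta(
        pd.DataFrame(
            {
                "line": "WT",
                "timepoint": pdls,
                "replicate": reps,
                "library_size": lib,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = pd.DataFrame(
        {"planted_l2fc": f, "in_nad": in_nad, "in_lad": in_lad},
        index=pd.Index(peaks.df["name"].to_numpy(), name="peak_id"),
    )
    logger.info(
        "simulate_atac: %d peaks x %d samples (%d NAD, %d LAD-only peaks)",
        a.n_peaks, len(sample_ids), int(in_nad.sum()), int(lad_only.sum()),
    )
    return peaks, counts, meta, truth


# ---------------------------------------------------------------------------
# motif labels


def simulate_motif_labels(
    spec: SimulationSpec, n_peaks: int | None = None
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Binary peak x motif matrix plus up/down labels from a planted
    logistic model.

    Presence is i.i.d. Bernoulli(presence_freq); the label is Bernoulli on
    logistic(intercept + m_p . beta).  Returns (matrix, labels, beta)."""
    m = spec.motif
    n = n_peaks if n_peaks is not None else m.n_peaks
    rng = spec.rng("motif")
    beta = m.coefficients()
    M = (rng.random((n, m.n_motifs)) < m.presence_freq).astype(np.int8)
    logit = m.intercept + M @ beta
    p_up = 1.0 / (1.0 + np.exp(-logit))
    up = rng.random(n) < p_up
    peak_ids = [f"peak_{i:05d}" for i in range(n)]
    motif_ids = [f"motif_{j:03d}" for j in range(m.n_motifs)]
    matrix = pd.DataFrame(M, index=peak_ids, columns=motif_ids)
    labels = pd.Series(np.where(up, "up", "down"), index=peak_ids)
    return matrix, labels, beta


# ---------------------------------------------------------------------------
# single cells


def simulate_cells(spec: SimulationSpec) -> ad.AnnData:
    """Gene x cell NB counts with a PDL-dependent phase schedule and a
    senescence program that rises with PDL in every phase.

    The returned AnnData (cells x genes) carries obs columns pdl, phase
    (truth), program_intensity (truth) and uns entries naming the program
    and S/G2M marker gene sets.
    """
    c = spec.cells
    rng = spec.rng("cells")
    if c.program_size <= 0:
        raise ValueError("program gene set must be non-empty")
    if c.program_size + 2 * c.n_phase_markers > c.n_genes:
        raise ValueError("program and phase-marker sets exceed the gene count")
    genes = [f"G{i:05d}" for i in range(c.n_genes)]
    program = genes[: c.program_size]
    s_markers = genes[c.program_size : c.program_size + c.n_phase_markers]
    g2m_markers = genes[
        c.program_size + c.n_phase_markers : c.program_size + 2 * c.n_phase_markers
    ]
    base = rng.lognormal(c.base_log_mean, c.base_log_sd, size=c.n_genes)
    pdls = np.asarray(c.pdls, dtype=float)
    xs = (pdls - pdls.min()) / max(pdls.max() - pdls.min(), 1e-12)
    rows, obs_rows = [], []
    prog_idx = np.arange(c.program_size)
    s_idx = np.arange(c.program_size, c.program_size + c.n_phase_markers)
    g2m_idx = np.arange(
        c.program_size + c.n_phase_markers, c.program_size + 2 * c.n_phase_markers
    )
    for pdl, x in zip(pdls, xs):
        cyc = c.cycling_start + (c.cycling_end - c.cycling_start) * x
        probs = np.array([1 - cyc, cyc / 2, cyc / 2])  # G1, S, G2M
        phases = rng.choice(["G1", "S", "G2M"], size=c.cells_per_pdl, p=probs)
        intensity = c.program_slope * x + rng.normal(
            0, c.program_noise_sd, size=c.cells_per_pdl
        )
        lib = rng.lognormal(0.0, 0.2, size=c.cells_per_pdl)
        for j in range(c.cells_per_pdl):
            mu = base * lib[j]
            mu = mu.copy()
            mu[prog_idx] *= 2.0 ** intensity[j]
            if phases[j] == "S":
                mu[s_idx] *= 2.0**c.phase_marker_l2fc
            elif phases[j] == "G2M":
                mu[g2m_idx] *= 2.0**c.phase_marker_l2fc
            rows.append(nb_counts(rng, mu, c.dispersion))
            obs_rows.append((pdl, phases[j], intensity[j]))
    X = np.asarray(rows)
    obs = pd.DataFrame(
        obs_rows,
        columns=["pdl", "phase", "program_intensity"],
        index=[f"cell_{i:05d}" for i in range(X.shape[0])],
    )
    obs["line"] = "WT"
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    adata.uns["program_genes"] = list(program)
    adata.uns["s_genes"] = list(s_markers)
    adata.uns["g2m_genes"] = list(g2m_markers)
    logger.info(
        "simulate_cells: %d cells x %d genes over PDLs %s",
        X.shape[0], X.shape[1], list(map(int, pdls)),
    )
    return adata


# ---------------------------------------------------------------------------
# metabolites


def simulate_metabolites(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, SampleMeta, pd.Series]:
    """Paired WT/control metabolite tables sharing exact batch factors.

    value = exp(a_m + trend_m * x_t + batch_t + noise); the control line
    has trend 0 but the identical batch_t of its temporally paired WT
    sample.  x_t scales the timepoint vector to [0, 1].  Returns
    (wt, ctrl, meta, truth slopes in natural-log units per unit x).
    """
    s = spec.metab
    rng = spec.rng("metab")
    tps = np.asarray(s.timepoints, dtype=float)
    x = (tps - tps.min()) / (tps.max() - tps.min())
    n_null = int(round(s.frac_null * s.n_metabolites))
    slopes = np.zeros(s.n_metabolites)
    n_alt = s.n_metabolites - n_null
    mags = rng.uniform(*s.slope_range, size=n_alt)
    signs = rng.choice([-1.0, 1.0], size=n_alt)
    slopes[n_null:] = mags * signs
    base = rng.normal(s.base_log_mean, s.base_log_sd, size=s.n_metabolites)
    batch = rng.normal(0, s.batch_sd, size=len(tps))
    mids = [f"M{i:03d}" for i in range(s.n_metabolites)]
    wt_cols, ctrl_cols, meta_rows = {}, {}, []
    for t, (tp, xt) in enumerate(zip(tps, x)):
        for rep in range(1, s.n_replicates + 1):
            noise_wt = rng.normal(0, s.noise_sd, size=s.n_metabolites)
            noise_ct = rng.normal(0, s.noise_sd, size=s.n_metabolites)
            wt_id, ct_id = f"WT_T{int(tp)}_r{rep}", f"CTRL_T{int(tp)}_r{rep}"
            wt_cols[wt_id] = np.exp(base + slopes * xt + batch[t] + noise_wt)
            ctrl_cols[ct_id] = np.exp(base + batch[t] + noise_ct)
            conc = 1.0 + rng.normal(0, s.protein_conc_sd)
            meta_rows.append((wt_id, "WT", tp, rep, conc))
            meta_rows.append((ct_id, "control", tp, rep, conc))
    wt = pd.DataFrame(wt_cols, index=mids)
    ctrl = pd.DataFrame(ctrl_cols, index=mids)
    meta = SampleMeta(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "line", "timepoint", "replicate", "protein_conc"],
        ).set_index("sample_id")
    )
    truth = pd.Series(slopes, index=mids, name="trend")
    return wt, ctrl, meta, truth


# ---------------------------------------------------------------------------
# pseudotime profiles


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((t - center) ** 2) / (2 * width**2))


def simulate_pseudotime_profiles(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Per-gene expression over pseudotime from bump archetypes.

    Genes belong to one of len(centers) archetypes peaking in the early /
    middle / late third of pseudotime; per-cell expression is
    archetype(pseudotime) + Gaussian noise.  Returns (expression genes x
    cells, pseudotime per cell, truth archetype per gene as 0-based ints).
    """
    p = spec.pt
    rng = spec.rng("pt")
    pt = np.sort(rng.random(p.n_cells))
    rows, archetypes = [], []
    gene_ids = []
    for a_i, center in enumerate(p.centers):
        curve = _bump(pt, center, p.width)
        for gi in range(p.genes_per_archetype):
            rows.append(curve + rng.normal(0, p.noise_sd, size=p.n_cells))
            archetypes.append(a_i)
            gene_ids.append(f"A{a_i}_G{gi:03d}")
    expr = pd.DataFrame(
        rows, index=gene_ids, columns=[f"cell_{i:05d}" for i in range(p.n_cells)]
    )
    truth = pd.Series(archetypes, index=gene_ids, name="archetype")
    return expr, pt, truth


# ---------------------------------------------------------------------------
# fixture writing (CLI `simulate`)


def write_fixtures(spec: SimulationSpec, out_dir) -> None:
    """Write all generated fixtures plus truth/ tables under ``out_dir``."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    states, nads, lads, genes = make_genome_fixture(spec)
    write_bed(states.intervals, out / "states.bed")
    write_bed(nads, out / "nads.bed")
    write_bed(lads, out / "lads.bed")
    write_bed(genes, out / "genes.bed")
    peaks, counts, meta, truth = simulate_atac(spec, nads, lads, states)
    write_bed(peaks, out / "peaks.bed")
    write_matrix(counts, out / "atac_counts.tsv")
    meta.write(out / "atac_meta.tsv")
    truth.to_csv(out / "truth" / "atac_truth.tsv", sep="\t")
    matrix, labels, beta = simulate_motif_labels(spec)
    write_matrix(matrix, out / "motif_matrix.tsv")
    labels.rename("label").to_csv(out / "motif_labels.tsv", sep="\t")
    pd.Series(beta, index=matrix.columns, name="beta").to_csv(
        out / "truth" / "motif_beta.tsv", sep="\t"
    )
    wt, ctrl, mmeta, slopes = simulate_metabolites(spec)
    write_matrix(wt, out / "metab_wt.tsv")
    write_matrix(ctrl, out / "metab_ctrl.tsv")
    mmeta.write(out / "metab_meta.tsv")
    slopes.to_csv(out / "truth" / "metab_trend.tsv", sep="\t")
    adata = simulate_cells(spec)
    write_matrix(
        pd.DataFrame(adata.X.T, index=adata.var_names, columns=adata.obs_names),
        out / "sc_counts.tsv",
    )
    adata.obs.to_csv(out / "sc_cells.tsv", sep="\t")
    expr, pt, arch = simulate_pseudotime_profiles(spec)
    write_matrix(expr, out / "pt_expr.tsv")
    pd.Series(pt, index=expr.columns, name="pseudotime").to_csv(
        out / "pt_pseudotime.tsv", sep="\t"
    )
    arch.to_csv(out / "truth" / "pt_archetype.tsv", sep="\t")
    logger.info("write_fixtures: fixtures written to %s (seed %d)", out, spec.seed)


def spec_from_dict(d: dict) -> SimulationSpec:
    """Build a SimulationSpec from a nested mapping (YAML config)."""
    kwargs = {}
    sections = {f.name: f.type for f in dataclasses.fields(SimulationSpec)}
    for name in d:
        if name == "seed":
            kwargs["seed"] = int(d["seed"])
        elif name in sections:
            cls = {
                "genome": GenomeSpec, "atac": AtacSpec, "motif": MotifSpec,
                "cells": CellsSpec, "metab": MetabSpec, "pt": PseudotimeSpec,
            }[name]
            kwargs[name] = cls(**d[name])
        else:
            raise ValueError(f"unknown simulation section {name!r}")
    return SimulationSpec(**kwargs)
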