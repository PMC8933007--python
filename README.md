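# senescape

Statistics for replicative-senescence multiomics time courses.

Primary fibroblasts passaged to their proliferative limit (tracked as the
population doubling level, PDL = Σ log2(harvested/seeded)) undergo a
characteristic remodeling: DNA accessibility rises inside
nucleolar-associated and lamin-associated domains (NADs/LADs), particular
transcription-factor motifs mark the peaks that open, metabolite and
protein abundances drift linearly with passage, and single cells ramp up a
senescence expression program gradually, in every cell-cycle phase.
`senescape` implements the statistical procedures needed to quantify each
of these claims, for computational biologists analyzing such time courses
or building simulation-validated pipelines around them:

- **chromstate** — peak↔chromatin-state assignment under the strict
  containment/discard rule, per-state signal fractions, quantile and
  depth normalization, per-state median log2 fold-change summaries, FRiP
  trend testing.
- **overlap** — permutation overlap tests with expression-matched
  (decile-resampled) nulls and z-scores, the Wilcoxon domain-shift test,
  hypergeometric motif-in-domain enrichment, and the OLS motif × domain
  interaction test for greater-than-additive accessibility gains.
- **motifreg** — nearest-gene assignment (50 kb window), binomial motif
  enrichment, and an L2-penalized logistic model scoring motifs by how
  well their presence predicts accessibility gain vs. loss (held-out AUC
  from a stratified 2/3 split; coefficients averaged over 10 bootstrap
  refits).
- **trend** — the per-feature linear model y_it = β0 + β1·T_t + ε_it with
  two-sided t-tests on β1 and Benjamini–Hochberg FDR control;
  protein-concentration normalization; paired-control division that
  cancels shared per-timepoint batch factors exactly.
- **scsen** — control-matched module scoring, S/G2M/G1 phase calls,
  perturbation-specific signatures, pseudobulk aggregation (>15-cell
  groups, top-8000 genes) and within-phase CPM+1 log2 fold changes.
- **trajectory** — 60-bin cubic-smoothing-spline pseudotime profiles
  scaled to [0,1], K-medians clustering under cosine similarity (k=25),
  and early/transition/late timing categories.
- **synthio** — seeded generators for every input above, with planted
  effects and truth tables: a 25-state genome with domain-biased NAD/LAD
  placement, negative-binomial ATAC counts with domain-concentrated
  log2FCs, motif matrices with planted predictive coefficients, single
  cells with a gradual senescence program, batch-paired metabolite
  tables, and archetypal pseudotime profiles.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate an ATAC time course on the synthetic genome and test whether
peaks inside NADs/LADs gain accessibility between PDL 20 and PDL 50:

```python
import numpy as np
from senescape.synthio import SimulationSpec, make_genome_fixture, simulate_atac
from senescape import chromstate, overlap

spec = SimulationSpec(seed=1)
states, nads, lads, genes = make_genome_fixture(spec)
peaks, counts, meta, truth = simulate_atac(spec, nads, lads, states)

norm = chromstate.depth_normalize(counts, meta.df["library_size"].to_numpy())
tp = meta.df["timepoint"]
fc = np.log2((norm[tp.index[tp == 50]].mean(axis=1) + 1)
             / (norm[tp.index[tp == 20]].mean(axis=1) + 1))

for label, mask in [("NAD", truth["in_nad"]),
                    ("LAD-only", truth["in_lad"] & ~truth["in_nad"])]:
    med_in, med_out, W, p = overlap.domain_shift_test(
        fc.to_numpy(), mask.to_numpy(), "greater")
    print(f"{label}: n={int(mask.sum())}  median log2FC {med_in:.2f} "
          f"vs {med_out:.2f} outside  (rank-sum p {max(p, 1e-300):.2g})")
```

```
NAD: n=609  median log2FC 0.97 vs 0.01 outside  (rank-sum p 1e-300)
LAD-only: n=118  median log2FC 0.25 vs 0.04 outside  (rank-sum p 9.1e-11)
```

The 609 NAD-overlapping peaks gain a median 0.97 log2 units of
accessibility over the time course while peaks outside NADs are flat — the
generator plants median effects of 0.98 (NAD) and 0.24 (LAD outside NADs),
and the depth-normalized fold-change estimator recovers both, with the
rank-sum test confirming the shift.

## Command line

A thin CLI wraps the library:

```sh
senescape --seed 1 --out-dir fixtures simulate          # write fixtures + truth/
senescape chromstate --peaks peaks.bed --states states.bed \
    --counts atac_counts.tsv --meta atac_meta.tsv
senescape overlap --targets genes.txt --domains nads.bed --universe genes.bed
senescape motif model --matrix motif_matrix.tsv --labels motif_labels.tsv
senescape trend --values metab_wt.tsv --meta metab_meta.tsv \
    --paired-control metab_ctrl.tsv
senescape sc pseudobulk --counts sc_counts.tsv --meta sc_cells.tsv
senescape trajectory --counts pt_expr.tsv --pseudotime pt_pseudotime.tsv
```

Global flags `--config` (YAML of analysis thresholds; defaults in
`senescape.config.SCHEMA`), `--seed`, `--out-dir`, `--log-level`.

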