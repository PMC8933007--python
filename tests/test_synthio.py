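"""Generator contracts: determinism, planted structure, limiting behavior."""

import numpy as np
import pandas as pd
import pytest

from senescape.intervals import IntervalSet, overlap_flags, overlapped_bp
from senescape.synthio import (
    AtacSpec,
    CellsSpec,
    GenomeSpec,
    MetabSpec,
    MotifSpec,
    SimulationSpec,
    make_genome_fixture,
    nb_counts,
    simulate_atac,
    simulate_cells,
    simulate_metabolites,
    simulate_motif_labels,
    simulate_pseudotime_profiles,
    write_fixtures,
)
from senescape.trend import linear_trend_test, paired_batch_correct


def test_genome_fixture_structure(genome, sim_spec):
    states, nads, lads, genes = genome
    g = sim_spec.genome
    # states tile each chromosome completely
    for chrom, grp in states.intervals.by_chrom().items():
        grp = grp.sort_values("start")
        assert grp["start"].iloc[0] == 0
        assert grp["end"].iloc[-1] == g.chrom_length
        assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()
    # NAD bp fraction inside the undefined state >= placement bias
    und = IntervalSet(states.intervals.df[states.intervals.df["name"] == "25"])
    frac = overlapped_bp(nads, und).sum() / nads.total_bp()
    assert frac >= g.placement_bias
    # gene density strictly lower inside NADs
    in_nad = overlap_flags(genes, nads)
    nad_frac = nads.total_bp() / (g.n_chrom * g.chrom_length)
    dens_in = in_nad.sum() / nads.total_bp()
    dens_out = (~in_nad).sum() / ((1 - nad_frac) * g.n_chrom * g.chrom_length)
    assert dens_in < dens_out
    # expression scores positive (log-normal draw)
    assert (genes.df["score"] > 0).all()


def test_genome_placement_bias_one_and_empty_nads():
    spec = SimulationSpec(
        seed=3, genome=GenomeSpec(n_nads=4, n_lads=2, placement_bias=1.0)
    )
    states, nads, _, _ = make_genome_fixture(spec)
    und = IntervalSet(states.intervals.df[states.intervals.df["name"] == "25"])
    assert overlapped_bp(nads, und).sum() == nads.total_bp()
    spec0 = SimulationSpec(seed=3, genome=GenomeSpec(n_nads=0))
    _, nads0, _, genes0 = make_genome_fixture(spec0)
    assert len(nads0) == 0 and len(genes0) > 0  # pipeline still runs


def test_genome_bad_proportions_rejected():
    props = {str(i): 0.0 for i in range(1, 26)}
    props["25"] = 0.5
    with pytest.raises(ValueError, match="sum"):
        make_genome_fixture(
            SimulationSpec(genome=GenomeSpec(state_proportions=props))
        )


def test_generators_are_deterministic(sim_spec):
    spec_a = SimulationSpec(seed=7)
    spec_b = SimulationSpec(seed=7)
    sa, na, la, ga = make_genome_fixture(spec_a)
    sb, nb, lb, gb = make_genome_fixture(spec_b)
    pd.testing.assert_frame_equal(sa.intervals.df, sb.intervals.df)
    pd.testing.assert_frame_equal(ga.df, gb.df)
    pa, ca, ma, ta = simulate_atac(spec_a, na, la, sa)
    pb_, cb, mb, tb = simulate_atac(spec_b, nb, lb, sb)
    pd.testing.assert_frame_equal(ca, cb)
    pd.testing.assert_frame_equal(ta, tb)
    m1, l1, _ = simulate_motif_labels(spec_a)
    m2, l2, _ = simulate_motif_labels(spec_b)
    pd.testing.assert_frame_equal(m1, m2)
    assert (l1 == l2).all()
    w1, c1, _, s1 = simulate_metabolites(spec_a)
    w2, c2, _, s2 = simulate_metabolites(spec_b)
    pd.testing.assert_frame_equal(w1, w2)
    np.testing.assert_array_equal(s1, s2)
    e1, p1, a1 = simulate_pseudotime_profiles(spec_a)
    e2, p2, a2 = simulate_pseudotime_profiles(spec_b)
    pd.testing.assert_frame_equal(e1, e2)
    np.testing.assert_array_equal(p1, p2)


def test_nb_poisson_limit_and_ratio():
    rng = np.random.default_rng(0)
    # dispersion -> 0 with large mean: counts proportional to library size
    mean = np.full(200, 5e4)
    draws = nb_counts(rng, mean, 0.0)
    assert np.abs(draws / 5e4 - 1).max() < 0.02
    # planted l2fc = 1 between x=0 and x=1, equal libraries: ratio 2
    spec = SimulationSpec(
        seed=1,
        atac=AtacSpec(
            n_peaks=2000, pdls=(20, 50), n_replicates=1, dispersion=0.0,
            median_l2fc_bg=1.0, l2fc_sd_bg=0.0, median_l2fc_nad=1.0,
            median_l2fc_lad=1.0, l2fc_sd_domain=0.0,
            library_size_range=(1.0, 1.0),
            baseline_log_mean=np.log(5e3), baseline_log_sd=0.0,
        ),
    )
    empty = IntervalSet.from_records([])
    _, counts, meta, truth = simulate_atac(spec, empty, empty)
    ratio = counts.iloc[:, 1].mean() / counts.iloc[:, 0].mean()
    assert ratio == pytest.approx(2.0, rel=0.01)


def test_atac_domain_medians_planted(genome, sim_spec):
    states, nads, lads, _ = genome
    _, _, _, truth = simulate_atac(sim_spec, nads, lads, states)
    in_nad = truth["in_nad"]
    lad_only = truth["in_lad"] & ~in_nad
    assert truth.loc[in_nad, "planted_l2fc"].median() == pytest.approx(0.98, abs=0.05)
    assert truth.loc[lad_only, "planted_l2fc"].median() == pytest.approx(0.24, abs=0.1)
    bg = ~(truth["in_nad"] | truth["in_lad"])
    assert truth.loc[bg, "planted_l2fc"].median() == pytest.approx(0.0, abs=0.02)


def test_motif_null_and_saturated_labels():
    null = SimulationSpec(
        seed=2, motif=MotifSpec(planted_coefficients=np.zeros(100), intercept=-1.0)
    )
    _, labels, _ = simulate_motif_labels(null)
    # label frequency ~ logistic(-1) = 0.269
    assert (labels == "up").mean() == pytest.approx(0.269, abs=0.03)
    sat = SimulationSpec(
        seed=2, motif=MotifSpec(planted_value=50.0, intercept=-25.0)
    )
    m, lab, _ = simulate_motif_labels(sat)
    assert ((lab == "up") == (m["motif_000"] == 1)).all()
    with pytest.raises(ValueError, match="length"):
        SimulationSpec(
            motif=MotifSpec(planted_coefficients=np.zeros(3), n_motifs=100)
        ).motif.coefficients()


def test_cells_phase_schedule_recovered():
    """Drawn phase fractions match the schedule within binomial error (+-3%)."""
    spec = SimulationSpec(seed=4, cells=CellsSpec(cells_per_pdl=2000, n_genes=300))
    adata = simulate_cells(spec)
    c = spec.cells
    pdls = np.asarray(c.pdls, dtype=float)
    xs = (pdls - pdls.min()) / (pdls.max() - pdls.min())
    for pdl, x in zip(pdls, xs):
        cyc = c.cycling_start + (c.cycling_end - c.cycling_start) * x
        grp = adata.obs[adata.obs["pdl"] == pdl]
        frac_cycling = (grp["phase"] != "G1").mean()
        assert frac_cycling == pytest.approx(cyc, abs=0.03)
        assert (grp["phase"] == "S").mean() == pytest.approx(cyc / 2, abs=0.03)


def test_cells_null_slope_gives_no_pseudobulk_trend():
    """With program slope 0, the trend test on program-gene pseudobulk is
    non-significant at alpha = 0.01 in >= 95% of seeds."""
    from senescape.scsen import pseudobulk_by_group

    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        spec = SimulationSpec(
            seed=100 + seed,
            cells=CellsSpec(cells_per_pdl=60, n_genes=300, program_size=30,
                            program_slope=0.0),
        )
        adata = simulate_cells(spec)
        pb, meta = pseudobulk_by_group(adata, min_cells=15, top_n_genes=300)
        cpm = np.log2(pb * 1e6 / pb.sum(axis=0) + 1)
        res = linear_trend_test(cpm, meta["pdl"].to_numpy())
        prog = [g for g in adata.uns["program_genes"] if g in res.index]
        hits += (res.loc[prog, "p"] < 0.01).mean() > 0.05
    assert hits / n_seeds <= 0.05


def test_metabolites_exact_structure(sim_spec):
    # noise 0, trend 0: paired correction output identically zero
    spec0 = SimulationSpec(
        seed=5, metab=MetabSpec(noise_sd=0.0, frac_null=1.0)
    )
    wt, ctrl, meta, truth = simulate_metabolites(spec0)
    out = paired_batch_correct(wt, ctrl, meta, reference_timepoint=33.0)
    np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)
    # noise 0, trend 1 (natural log): corrected log2 ratio = x_t / ln 2
    spec1 = SimulationSpec(
        seed=5, metab=MetabSpec(noise_sd=0.0, frac_null=0.0, slope_range=(1.0, 1.0))
    )
    wt, ctrl, meta, truth = simulate_metabolites(spec1)
    out = paired_batch_correct(wt, ctrl, meta, reference_timepoint=33.0)
    tps = np.array([33.0, 37.0, 46.0, 50.0])
    for col in out.columns:
        tp = meta.df.loc[col, "timepoint"]
        x_t = (tp - 33.0) / 17.0
        expected = np.sign(truth.to_numpy()) * x_t / np.log(2)
        np.testing.assert_allclose(out[col].to_numpy(), expected, atol=1e-10)


def test_pseudotime_profiles_peak_in_correct_third():
    from senescape.synthio import PseudotimeSpec
    from senescape.trajectory import bin_smooth_trajectory

    spec = SimulationSpec(
        seed=6, pt=PseudotimeSpec(n_cells=500, genes_per_archetype=1, noise_sd=0.0)
    )
    expr, pt, truth = simulate_pseudotime_profiles(spec)
    for gene, arch in truth.items():
        scaled, _ = bin_smooth_trajectory(expr.loc[gene].to_numpy(), pt)
        peak_bin = int(np.argmax(scaled))
        assert arch * 20 <= peak_bin < (arch + 1) * 20


def test_write_fixtures_round_trip(tmp_path):
    from senescape.intervals import read_bed
    from senescape.matrixio import read_matrix

    spec = SimulationSpec(
        seed=8,
        genome=GenomeSpec(n_genes=50),
        atac=AtacSpec(n_peaks=100),
        motif=MotifSpec(n_peaks=100, n_motifs=10),
        cells=CellsSpec(cells_per_pdl=20, n_genes=100, program_size=20,
                        n_phase_markers=10),
        metab=MetabSpec(n_metabolites=10),
    )
    import dataclasses

    spec = dataclasses.replace(
        spec, pt=dataclasses.replace(spec.pt, n_cells=200, genes_per_archetype=5)
    )
    write_fixtures(spec, tmp_path)
    assert len(read_bed(tmp_path / "peaks.bed")) == 100
    counts = read_matrix(tmp_path / "atac_counts.tsv")
    assert counts.shape[0] == 100
    truth = pd.read_csv(tmp_path / "truth" / "atac_truth.tsv", sep="\t", index_col=0)
    assert len(truth) == 100
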