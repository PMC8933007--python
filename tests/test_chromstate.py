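"""Peak-state assignment, signal fractions, quantile normalization, FRiP."""

import numpy as np
import pandas as pd
import pytest

from senescape.chromstate import (
    assign_peaks_to_states,
    depth_normalize,
    frip_trend,
    quantile_normalize,
    state_fc_summary,
    state_signal_fractions,
)
from senescape.intervals import ChromatinStateMap, IntervalSet
from senescape.matrixio import SampleMeta


def bp_oracle_assignment(peaks, states):
    """Brute-force per-basepair labeling on small fixtures."""
    out = []
    sdf = states.intervals.df
    for _, p in peaks.df.iterrows():
        labels = {}
        for _, s in sdf[sdf["chrom"] == p["chrom"]].iterrows():
            for bp in range(max(p["start"], s["start"]), min(p["end"], s["end"])):
                labels.setdefault(s["name"], set()).add(bp)
        if not labels:
            out.append("discarded")
            continue
        if len(labels) > 1:
            out.append("discarded")
            continue
        state = next(iter(labels))
        inside = any(
            p["start"] >= s["start"] and p["end"] <= s["end"]
            for _, s in sdf[(sdf["chrom"] == p["chrom"]) & (sdf["name"] == state)].iterrows()
        )
        contains = any(
            p["start"] <= s["start"] and p["end"] >= s["end"]
            for _, s in sdf[(sdf["chrom"] == p["chrom"]) & (sdf["name"] == state)].iterrows()
        )
        out.append("inside" if inside else ("inside_feature" if contains else "discarded"))
    return out


def test_assignment_rules(toy_states):
    peaks = IntervalSet.from_records(
        [
            ("chr1", 100, 200, "inside_25"),
            ("chr1", 900, 1100, "spans_two"),
            ("chr2", 100, 2900, "inside_13"),
        ]
    )
    res = assign_peaks_to_states(peaks, toy_states)
    res = res.set_index("peak_id")
    assert res.loc["inside_25", ["state", "relation"]].tolist() == ["25", "inside"]
    assert res.loc["spans_two", "relation"] == "discarded"
    assert res.loc["inside_13", "relation"] == "inside"


def test_assignment_matches_bp_oracle():
    states = ChromatinStateMap(
        IntervalSet.from_records(
            [
                ("chr1", 0, 300, "1"),
                ("chr1", 300, 350, "2"),
                ("chr1", 350, 700, "1"),
                ("chr1", 700, 1000, "25"),
            ]
        )
    )
    peaks = IntervalSet.from_records(
        [
            ("chr1", 10, 50, "a"),          # inside state 1
            ("chr1", 290, 360, "b"),        # touches 1,2,1 -> discarded
            ("chr1", 250, 800, "c"),        # multiple states -> discarded
            ("chr1", 280, 690, "d"),        # contains the 2-instance -> discarded (two states)
            ("chr1", 700, 1000, "e"),       # exactly the 25 instance -> inside
            ("chr1", 650, 720, "f"),        # 1 then 25 -> discarded
        ]
    )
    res = assign_peaks_to_states(peaks, states)
    assert list(res["relation"]) == bp_oracle_assignment(peaks, states)


def test_assignment_inside_feature_and_oracle_agreement():
    # a peak that fully contains both instances of one state and nothing else
    states = ChromatinStateMap(
        IntervalSet.from_records(
            [("chr1", 100, 150, "3"), ("chr1", 180, 220, "3")]
        )
    )
    peaks = IntervalSet.from_records(
        [("chr1", 90, 230, "encompassing"), ("chr1", 120, 200, "partial")]
    )
    res = assign_peaks_to_states(peaks, states).set_index("peak_id")
    assert res.loc["encompassing", "relation"] == "inside_feature"
    assert res.loc["partial", "relation"] == "discarded"
    assert list(
        assign_peaks_to_states(peaks, states)["relation"]
    ) == bp_oracle_assignment(peaks, states)


def test_assignment_unknown_chromosome(toy_states):
    peaks = IntervalSet.from_records([("chr9", 0, 10, "x")])
    with pytest.raises(ValueError, match="chr9"):
        assign_peaks_to_states(peaks, toy_states)


def test_state_signal_fractions(toy_states):
    ids = toy_states.instance_ids()
    signal = pd.DataFrame(
        {"s1": [10, 0, 0, 30, 0], "s2": [1, 1, 1, 1, 1]}, index=ids.to_numpy()
    )
    inst_states = pd.Series(
        toy_states.intervals.df["name"].to_numpy(), index=ids.to_numpy()
    )
    fr = state_signal_fractions(signal, inst_states, toy_states)
    assert fr.loc["25", "s1"] == pytest.approx(1.0)  # instances summed
    assert fr["s1"].sum() == pytest.approx(1.0, abs=1e-12)
    assert fr["s2"].sum() == pytest.approx(1.0, abs=1e-12)
    cat = state_signal_fractions(signal, inst_states, toy_states, grouping="category")
    # category fractions = sums of member-state fractions
    assert cat.loc["miscellaneous", "s2"] == pytest.approx(
        fr.loc["25", "s2"], abs=1e-12
    )
    assert cat["s2"].sum() == pytest.approx(1.0, abs=1e-12)


def test_quantile_normalize_hand_example_and_invariants():
    m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    out = quantile_normalize(m)
    np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
    np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.lognormal(size=(40, 5)))
    qn = quantile_normalize(x)
    # identical sorted values per column
    ref = np.sort(qn.to_numpy()[:, 0])
    for j in range(5):
        np.testing.assert_allclose(np.sort(qn.to_numpy()[:, j]), ref, atol=1e-12)
    # idempotent
    np.testing.assert_allclose(
        quantile_normalize(qn).to_numpy(), qn.to_numpy(), atol=1e-12
    )
    # fixed point on identical columns
    same = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
    pd.testing.assert_frame_equal(quantile_normalize(same), same)


def test_quantile_normalize_ties_span_reference_values():
    m = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [10.0, 20.0, 30.0]})
    out = quantile_normalize(m)
    ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [5.5, 10.5, 16.0]
    assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
    assert out["a"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)


def test_quantile_normalize_single_column_warns():
    m = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.warns(UserWarning):
        out = quantile_normalize(m)
    pd.testing.assert_frame_equal(out, m)


def _atac_meta(n_tp=3, n_rep=2):
    rows = []
    for tp in range(n_tp):
        for r in range(1, n_rep + 1):
            rows.append((f"s{tp}_{r}", "WT", 20.0 + 5 * tp, r))
    return SampleMeta(
        pd.DataFrame(
            rows, columns=["sample_id", "line", "timepoint", "replicate"]
        ).set_index("sample_id")
    )


def test_state_fc_summary_median_and_missing():
    meta = _atac_meta(n_tp=2, n_rep=1)
    norm = pd.DataFrame(
        {
            "s0_1": [10.0, 10.0, 10.0, 10.0],
            "s1_1": [2 ** -1 * 11 - 1, 10.0, 2**3 * 11 - 1, 10.0],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    assignment = pd.DataFrame(
        {
            "peak_id": ["p1", "p2", "p3", "p4"],
            "state": ["1", "1", "1", "2"],
            "relation": ["inside"] * 4,
            "category": ["promoter"] * 4,
        }
    )
    trend_res = pd.DataFrame(
        {"q": [1e-5, 1e-5, 1e-5, 0.5]}, index=["p1", "p2", "p3", "p4"]
    )
    out = state_fc_summary(norm, assignment, trend_res, meta, sig_cutoff=0.001)
    # state 1 log2FCs at s1_1: {-1, 0, 3} -> median 0
    assert out.loc["1", "s1_1"] == pytest.approx(0.0, abs=1e-12)
    # state 2 has no significant peak: missing, never 0
    assert "2" not in out.index or np.isnan(out.loc["2", "s1_1"])
    with pytest.raises(ValueError, match="cutoff"):
        state_fc_summary(norm, assignment, trend_res, meta, sig_cutoff=0.0)


def test_depth_normalize_scales_and_validates():
    m = pd.DataFrame({"a": [10.0], "b": [20.0]})
    out = depth_normalize(m, [1.0, 2.0])
    assert out.loc[0, "a"] == pytest.approx(15.0)
    assert out.loc[0, "b"] == pytest.approx(15.0)
    with pytest.raises(ValueError):
        depth_normalize(m, [1.0, -1.0])


def test_frip_trend_exact_linear():
    meta = _atac_meta(n_tp=5, n_rep=1)
    pdls = meta.df["timepoint"].to_numpy()
    f_true = 0.5 - 0.001 * pdls
    total = np.full(5, 1_000_000.0)
    f, slope, p = frip_trend(f_true * total, total, meta)
    np.testing.assert_allclose(f, f_true, atol=1e-15)
    assert slope == pytest.approx(-0.001, abs=1e-12)
    const = np.full(5, 0.3)
    _, slope0, _ = frip_trend(const * total, total, meta)
    assert slope0 == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="exceed"):
        frip_trend(total * 2, total, meta)


def test_frip_trend_power_with_noise():
    """A planted relative 5% decline is detected (p < 0.05) in >= 90% of seeds."""
    meta = _atac_meta(n_tp=9, n_rep=1)
    pdls = meta.df["timepoint"].to_numpy()
    x = (pdls - pdls.min()) / (pdls.max() - pdls.min())
    detected = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        f_true = 0.30 * (1 - 0.05 * x) + rng.normal(0, 0.003, size=9)
        total = np.full(9, 1e6)
        _, slope, p = frip_trend(np.clip(f_true, 0, 1) * total, total, meta)
        detected += (slope < 0) and (p < 0.05)
    assert detected / n_seeds >= 0.90
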