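"""Promoter windows, binned signal, k-means states, labeling, persistence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gametrace.chromatin_state import (
    LabelThresholds,
    PromoterSignalMatrix,
    cluster_promoters,
    label_clusters,
    label_thresholds,
    promoter_windows,
    signal_matrix,
    expression_by_state,
    trace_states,
)
from gametrace.io_formats import Biotype, CoverageTrack, TranscriptRecord


def _tx(tid="t1", start=40_000, end=45_000, strand="+", chrom="chr1"):
    return TranscriptRecord(tid, tid, Biotype.lincRNA, chrom, start, end, strand)


def _track(df, mark="H3K4me3", compartment="sperm"):
    return CoverageTrack(mark, compartment, df)


# ---------------------------------------------------------------------------
# windows


def test_plus_strand_window_layout():
    (w,) = promoter_windows([_tx(start=50_000, end=55_000)], flank=10_000, bin_size=100)
    assert (w.window_start, w.window_end, w.bins) == (40_000, 60_000, 200)
    assert w.bin_edges[0] == 40_000 and w.bin_edges[1] == 40_100


def test_minus_strand_bin_zero_is_upstream_in_transcription_direction():
    # tss = end - 1 = 50_000; bin 0 covers the most downstream genomic bin
    (w,) = promoter_windows(
        [_tx(start=45_001, end=50_001, strand="-")], flank=10_000, bin_size=100
    )
    assert (w.window_start, w.window_end) == (40_000, 60_000)
    assert not w.missing_bins.any()


def test_window_clamped_at_chromosome_start_flags_missing_bins():
    (w,) = promoter_windows([_tx(start=4_000, end=9_000)], flank=10_000, bin_size=100)
    assert w.window_start == -6_000
    assert w.missing_bins.sum() == 60
    assert w.missing_bins[:60].all()


def test_window_validation_errors():
    with pytest.raises(ValueError):
        promoter_windows([_tx()], flank=0)
    with pytest.raises(ValueError):
        promoter_windows([_tx()], flank=10_000, bin_size=333)


# ---------------------------------------------------------------------------
# signal matrix


def test_uniform_track_closed_form():
    df = pd.DataFrame(
        {"chrom": ["chr1"], "start": [0], "end": [100_000], "value": [3.0]}
    )
    track = _track(df)
    windows = promoter_windows([_tx(start=50_000, end=55_000)])
    sm = signal_matrix(track, windows)
    expected = np.log2(1 + 3.0 * 1e6 / track.library_size)
    np.testing.assert_allclose(sm.matrix, expected)


def test_empty_region_gives_zero_bins():
    df = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100], "value": [5.0]})
    windows = promoter_windows([_tx(start=50_000, end=55_000)])
    sm = signal_matrix(_track(df), windows)
    assert (sm.matrix == 0).all()


def test_zero_library_size_rejected():
    empty = _track(pd.DataFrame(columns=["chrom", "start", "end", "value"]))
    with pytest.raises(ValueError):
        signal_matrix(empty, promoter_windows([_tx()]))


def _brute_force_bin_means(track, window, genome_length=20_000):
    """Per-base enumeration oracle for the mean bin coverage."""
    per_base = np.zeros(genome_length)
    sub = track.intervals[track.intervals.chrom == window.chrom]
    for _, row in sub.iterrows():
        for base in range(int(row.start), int(row.end)):
            per_base[base] = row.value
    means = []
    for b in range(window.bins):
        a = window.window_start + b * window.bin_size
        vals = [per_base[p] for p in range(a, a + window.bin_size) if p >= 0]
        means.append(sum(vals) / window.bin_size)
    means = np.array(means)
    return means if window.strand == "+" else means[::-1]


def test_signal_matches_per_base_brute_force_oracle():
    rng = np.random.default_rng(42)
    starts = np.sort(rng.choice(np.arange(0, 4000, 20), size=60, replace=False))
    widths = rng.integers(5, 20, size=60)
    ends = np.minimum(starts + widths, np.r_[starts[1:], 10**9])
    keep = ends > starts
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts[keep],
            "end": ends[keep],
            "value": rng.uniform(0, 5, size=keep.sum()),
        }
    )
    track = _track(df)
    txs = [
        _tx(f"t{i}", s, s + 500, strand=("+" if i % 2 else "-"))
        for i, s in enumerate(rng.integers(300, 3500, size=8))
    ]
    windows = promoter_windows(txs, flank=500, bin_size=50)
    sm = signal_matrix(track, windows)
    scale = 1e6 / track.library_size
    for w, row in zip(windows, sm.matrix):
        oracle = np.log2(1 + _brute_force_bin_means(track, w) * scale)
        np.testing.assert_allclose(row, oracle, atol=1e-9)


def test_doubling_values_is_cpm_invariant_but_doubles_raw_means():
    df = pd.DataFrame(
        {"chrom": ["chr1"] * 2, "start": [0, 50_000], "end": [50_000, 100_000],
         "value": [2.0, 4.0]}
    )
    df2 = df.assign(value=df.value * 2)
    windows = promoter_windows([_tx(start=50_000, end=55_000)])
    m1 = signal_matrix(_track(df), windows).matrix
    m2 = signal_matrix(_track(df2), windows).matrix
    np.testing.assert_allclose(m1, m2)  # CPM divides the doubling out
    t1, t2 = _track(df), _track(df2)
    edges = np.array([40_000, 60_000])
    assert t2.integral("chr1", edges)[1] == 2 * t1.integral("chr1", edges)[1]


def test_strand_reversal_reverses_bin_vector_exactly():
    rng = np.random.default_rng(1)
    starts = np.arange(0, 100_000, 100)
    df = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 100,
         "value": rng.uniform(0, 3, len(starts))}
    )
    track = _track(df)
    plus = promoter_windows([_tx("p", 50_000, 55_000, "+")])
    minus = promoter_windows([_tx("m", 45_001, 50_001, "-")])  # same tss
    mp = signal_matrix(track, plus).matrix[0]
    mm = signal_matrix(track, minus).matrix[0]
    np.testing.assert_array_equal(mp, mm[::-1])


# ---------------------------------------------------------------------------
# clustering


def _toy_matrices(n_per_state, amps, seed=0, bins=40):
    rng = np.random.default_rng(seed)
    rows_k4, rows_k27, states = [], [], []
    centre = np.exp(-0.5 * ((np.arange(bins) - bins / 2 + 0.5) / 4) ** 2)
    for state, (a4, a27) in amps.items():
        for _ in range(n_per_state):
            rows_k4.append(a4 * centre + rng.normal(0, 0.05, bins))
            rows_k27.append(a27 * centre + rng.normal(0, 0.05, bins))
            states.append(state)
    ids = [f"t{i}" for i in range(len(states))]
    mk = dict(bin_size=100, flank=bins * 100 // 2)
    k4 = PromoterSignalMatrix("H3K4me3", "sperm", ids, np.abs(rows_k4), **mk)
    k27 = PromoterSignalMatrix("H3K27me3", "sperm", ids, np.abs(rows_k27), **mk)
    return k4, k27, np.array(states)


def test_two_well_separated_states_recovered_perfectly():
    k4, k27, states = _toy_matrices(30, {"on": (3.0, 0.0), "off": (0.0, 0.0)})
    clusters = cluster_promoters(k4, k27, k=2, seed=0)
    assert adjusted_rand_score(states, clusters) == 1.0


def test_identical_rows_collapse_to_one_cluster_with_warning():
    ids = ["a", "b", "c"]
    mat = np.ones((3, 10))
    k4 = PromoterSignalMatrix("H3K4me3", "sperm", ids, mat, bin_size=100, flank=500)
    k27 = PromoterSignalMatrix("H3K27me3", "sperm", ids, mat, bin_size=100, flank=500)
    with pytest.warns(UserWarning):
        clusters = cluster_promoters(k4, k27, k=2, seed=0)
    assert (clusters == 0).all()


def test_k_larger_than_n_rejected():
    k4, k27, _ = _toy_matrices(2, {"on": (3.0, 0.0), "off": (0.0, 0.0)})
    with pytest.raises(ValueError):
        cluster_promoters(k4, k27, k=10, seed=0)


def test_clustering_is_seed_deterministic(sperm_signal, bundle):
    k4, k27 = sperm_signal
    ids = bundle.truth.df.index[:300].tolist()
    a = cluster_promoters(k4.subset(ids), k27.subset(ids), k=3, seed=11)
    b = cluster_promoters(k4.subset(ids), k27.subset(ids), k=3, seed=11)
    np.testing.assert_array_equal(a, b)


def test_auto_k_recovers_three_lincRNA_states(bundle, group_assignments):
    """lincRNA promoter groups carry three planted chromatin states and
    auto-k selects exactly three clusters for them."""
    clusters, _ = group_assignments[("Sp", "lincRNA")]
    assert len(np.unique(clusters)) == 3


def test_auto_k_recovers_four_pcg_states(group_assignments):
    clusters, _ = group_assignments[("Sp", "protein_coding")]
    assert len(np.unique(clusters)) == 4


# ---------------------------------------------------------------------------
# labeling


def _const_matrix(ids, value_k4, value_k27, bins=40):
    mk = dict(bin_size=100, flank=bins * 100 // 2)
    k4 = PromoterSignalMatrix(
        "H3K4me3", "sperm", ids, np.full((len(ids), bins), value_k4, float), **mk
    )
    k27 = PromoterSignalMatrix(
        "H3K27me3", "sperm", ids, np.full((len(ids), bins), value_k27, float), **mk
    )
    return k4, k27


def test_label_rule_high_k4():
    thr = LabelThresholds(k4_q50=1.0, k4_q75=2.0, k27_q50=1.0, k27_q75=2.0)
    k4, k27 = _const_matrix(["a"], 5.0, 0.1)
    asn = label_clusters(np.array([0]), k4, k27, thresholds=thr)
    assert asn.cluster_states == {0: "high_K4"}


def test_label_rule_bivalent_takes_precedence():
    thr = LabelThresholds(k4_q50=1.0, k4_q75=2.0, k27_q50=1.0, k27_q75=2.0)
    k4, k27 = _const_matrix(["a"], 5.0, 5.0)
    asn = label_clusters(np.array([0]), k4, k27, thresholds=thr)
    assert asn.cluster_states == {0: "bivalent"}


@pytest.mark.parametrize(
    "v4,expected",
    [(1.5, "low_K4"), (0.5, "K4minus_K27minus")],
)
def test_label_rule_low_and_absent(v4, expected):
    thr = LabelThresholds(k4_q50=1.0, k4_q75=2.0, k27_q50=1.0, k27_q75=2.0)
    k4, k27 = _const_matrix(["a"], v4, 0.1)
    asn = label_clusters(np.array([0]), k4, k27, thresholds=thr)
    assert asn.cluster_states == {0: expected}


def test_increasing_k4_never_demotes_high_to_low():
    """Label monotonicity in the K4 signal."""
    thr = LabelThresholds(k4_q50=1.0, k4_q75=2.0, k27_q50=1.0, k27_q75=2.0)
    for bump in [0.5, 2.0, 10.0]:
        k4, k27 = _const_matrix(["a"], 3.0 + bump, 0.1)
        asn = label_clusters(np.array([0]), k4, k27, thresholds=thr)
        assert asn.cluster_states[0] == "high_K4"


def test_bundle_state_labels_match_truth(bundle, group_assignments):
    preds = pd.concat(
        [asn.df["state_label"] for _, asn in group_assignments.values()]
    )
    truth = bundle.truth.df.loc[preds.index, "chromatin_state"]
    assert (preds == truth).mean() >= 0.9


# ---------------------------------------------------------------------------
# expression by state / persistence


def test_expression_by_state_reproduces_k4_ordering(bundle, group_assignments):
    _, asn = group_assignments[("Sp", "protein_coding")]
    table, rho = expression_by_state(
        bundle.expression, bundle.sheet, asn, compartments=["sperm"]
    )
    med = table.set_index("state")["median"]
    assert med["high_K4"] > med["low_K4"] > med["K4minus_K27minus"]
    assert rho > 0.5


def test_permuted_states_kill_the_correlation(bundle, group_assignments):
    rng = np.random.default_rng(0)
    _, asn = group_assignments[("Sp", "protein_coding")]
    shuffled = asn.df.copy()
    shuffled["central_K4"] = rng.permutation(shuffled["central_K4"].to_numpy())
    from gametrace.chromatin_state import ChromatinAssignment

    perm = ChromatinAssignment(shuffled, asn.cluster_states)
    _, rho = expression_by_state(
        bundle.expression, bundle.sheet, perm, compartments=["sperm"]
    )
    assert abs(rho) < 0.1


def test_trace_identity_compartment_is_maintained(sperm_signal, group_assignments):
    k4, k27 = sperm_signal
    _, asn = group_assignments[("Sp", "protein_coding")]
    out = trace_states(asn, {"sperm_copy": (k4, k27)})
    assert (out.status == "maintained").all()


def test_trace_missing_compartment_matrices_rejected(group_assignments, sperm_signal):
    _, asn = group_assignments[("Sp", "lincRNA")]
    with pytest.raises(ValueError):
        trace_states(asn, {})
    k4, k27 = sperm_signal
    short_ids = [t for t in k4.transcript_ids[:10]]
    with pytest.raises(ValueError, match="lacks windows"):
        trace_states(asn, {"x": (k4.subset(short_ids), k27.subset(short_ids))})
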