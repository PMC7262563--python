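"""Hypergeometric machinery, promoter sequences, and PWM scanning."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from gametrace.enrichment import (
    extract_promoter_seqs,
    hypergeom_test,
    motif_enrichment,
    scan_pwm,
    term_enrichment,
    tf_target_correlation,
)
from gametrace.io_formats import PWM, Biotype, TermSets, TranscriptRecord
from gametrace.simulate import simulate_motif_sequences


def enum_hypergeom(k, K, n, N):
    """Exhaustive enumeration oracle: sum of draw counts with >= k overlap."""
    total = comb(N, n)
    s = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return Fraction(s, total)


# ---------------------------------------------------------------------------
# hypergeometric


def test_hypergeom_matches_frozen_enumeration_example():
    # enumeration over all C(20,6) draws gives 9/646
    assert hypergeom_test(4, 5, 6, 20) == pytest.approx(9 / 646, abs=1e-12)


def test_hypergeom_degenerate_cases():
    assert hypergeom_test(0, 5, 6, 20) == 1.0  # P(X >= 0)
    assert hypergeom_test(6, 20, 6, 20) == 1.0  # K = N forces k = n


def test_hypergeom_monotone_in_k():
    ps = [hypergeom_test(k, 8, 10, 30) for k in range(0, 9)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_hypergeom_matches_enumeration_on_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(300):
        N = int(rng.integers(1, 26))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        assert hypergeom_test(k, K, n, N) == pytest.approx(
            float(enum_hypergeom(k, K, n, N)), abs=1e-12
        )


def test_hypergeom_rejects_invalid_instances():
    with pytest.raises(ValueError):
        hypergeom_test(5, 3, 4, 10)  # k > K
    with pytest.raises(ValueError):
        hypergeom_test(1, 11, 4, 10)  # K > N


# ---------------------------------------------------------------------------
# term enrichment


def _terms(**kw):
    return TermSets({k: (k, frozenset(v)) for k, v in kw.items()})


def test_fully_contained_term_ranks_first():
    universe = [f"g{i}" for i in range(100)]
    query = universe[:10]
    terms = _terms(hit=universe[:10], half=universe[5:25], none=universe[50:70])
    res = term_enrichment(query, terms, universe, report_all=True)
    assert res.iloc[0]["term_id"] == "hit"
    assert "none" not in set(res["term_id"])  # k = 0 dropped


def test_term_enrichment_rejects_query_outside_universe():
    with pytest.raises(ValueError):
        term_enrichment(["x"], _terms(t=["g1"]), ["g1"])
    with pytest.raises(ValueError):
        term_enrichment([], _terms(t=["g1"]), [])


def test_bh_fdr_is_monotone_when_sorted_by_p():
    universe = [f"g{i}" for i in range(200)]
    rng = np.random.default_rng(1)
    terms = _terms(
        **{f"t{i}": rng.choice(universe, 30, replace=False).tolist() for i in range(15)}
    )
    res = term_enrichment(universe[:50], terms, universe, report_all=True)
    fdrs = res.sort_values("p_value")["fdr"].to_numpy()
    assert (np.diff(fdrs) >= -1e-12).all()


def test_null_permutation_calibration_quick():
    """~200 shuffled queries: the p < 0.05 fraction sits near the nominal
    level (the full 1000-permutation check runs in the acceptance suite)."""
    rng = np.random.default_rng(9)
    universe = [f"g{i}" for i in range(2000)]
    terms = _terms(
        **{
            f"t{i}": rng.choice(universe, 100, replace=False).tolist()
            for i in range(50)
        }
    )
    frac = []
    for _ in range(200):
        query = rng.choice(universe, 500, replace=False).tolist()
        res = term_enrichment(query, terms, universe, report_all=True)
        frac.append((res["p_value"] < 0.05).sum() / 50)
    assert 0.02 <= np.mean(frac) <= 0.08


# ---------------------------------------------------------------------------
# promoter sequences


def _rec(tid, tss, strand, chrom="chr1"):
    if strand == "+":
        return TranscriptRecord(tid, tid, Biotype.lincRNA, chrom, tss, tss + 500, strand)
    return TranscriptRecord(tid, tid, Biotype.lincRNA, chrom, tss - 499, tss + 1, strand)


def test_promoter_extraction_is_direct_slice():
    rng = np.random.default_rng(2)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
    for tss in [300, 1000, 2500]:
        (seq,) = extract_promoter_seqs([_rec("t", tss, "+")], genome, flank=250).values()
        assert seq == genome["chr1"][max(0, tss - 250) : tss + 250]


def test_minus_strand_is_reverse_complement_of_plus_extraction():
    genome = {"chr1": "ACGTACGTAC" * 200}
    fwd = extract_promoter_seqs([_rec("p", 1000, "+")], genome, flank=50)["p"]
    rev = extract_promoter_seqs([_rec("m", 1000, "-")], genome, flank=50)["m"]
    complement = str.maketrans("ACGT", "TGCA")
    assert rev == fwd.translate(complement)[::-1]


def test_missing_chromosome_rejected():
    with pytest.raises(KeyError):
        extract_promoter_seqs([_rec("t", 300, "+", chrom="chrX")], {"chr1": "A" * 1000})


# ---------------------------------------------------------------------------
# PWM scanning


def _consensus_pwm(consensus="TGACGTGA", p=0.97):
    mat = np.full((4, len(consensus)), (1 - p) / 3)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = p
    return PWM("m", mat)


def test_background_pwm_yields_no_positive_hits():
    pwm = PWM("uniform", np.full((4, 6), 0.25))
    assert scan_pwm("ACGT" * 20, pwm) == []


def test_consensus_found_at_exact_offset():
    pwm = _consensus_pwm()
    seq = "A" * 37 + "TGACGTGA" + "A" * 30
    hits = scan_pwm(seq, pwm)
    assert [(h.offset, h.strand) for h in hits] == [(37, "+")]


def test_reverse_complement_sequence_hits_opposite_strand():
    pwm = _consensus_pwm("TGACGA")
    seq = "C" * 30 + "TGACGA" + "C" * 25
    complement = str.maketrans("ACGT", "TGCA")
    rc = seq.translate(complement)[::-1]
    fwd_hits = scan_pwm(seq, pwm)
    rc_hits = scan_pwm(rc, pwm)
    assert len(fwd_hits) == len(rc_hits) == 1
    assert fwd_hits[0].strand == "+" and rc_hits[0].strand == "-"
    assert fwd_hits[0].score == pytest.approx(rc_hits[0].score)


def test_prepending_background_shifts_offsets_exactly():
    pwm = _consensus_pwm()
    seq = "A" * 20 + "TGACGTGA" + "A" * 20
    base = scan_pwm(seq, pwm)
    shifted = scan_pwm("C" * 13 + seq, pwm)
    assert [h.offset + 13 for h in base] == [h.offset for h in shifted]


def test_n_bases_score_as_background():
    pwm = _consensus_pwm()
    hits = scan_pwm("N" * 30 + "TGACGTGA" + "N" * 30, pwm)
    assert [h.offset for h in hits] == [30]


def test_short_sequence_gives_empty_result():
    assert scan_pwm("ACG", _consensus_pwm()) == []


# ---------------------------------------------------------------------------
# motif enrichment


def test_planted_motif_recovered_rank_one(bundle):
    pwm = bundle.pwms[0]
    fg, bg = simulate_motif_sequences(pwm, 60, 60, 0.8, 0.05, seed=11)
    res = motif_enrichment(fg, bg, bundle.pwms)
    assert res.iloc[0]["pwm"] == pwm.name
    assert res.iloc[0]["fdr"] < 0.05


def test_equal_rates_give_no_discoveries(bundle):
    pwm = bundle.pwms[0]
    fg, bg = simulate_motif_sequences(pwm, 50, 50, 0.2, 0.2, seed=4)
    res = motif_enrichment(fg, bg, bundle.pwms)
    assert (res["fdr"] >= 0.05).all()


def test_single_hit_foreground_brute_force_p():
    pwm = _consensus_pwm()
    fg = {"f0": "A" * 30 + "TGACGTGA" + "A" * 30}
    bg = {f"b{i}": "C" * 68 for i in range(100)}
    res = motif_enrichment(fg, bg, [pwm])
    # one draw from 101 sequences, 1 carries a hit: P = C(1,1)*C(100,0)/C(101,1)
    assert res.iloc[0]["p_value"] == pytest.approx(1 / 101, abs=1e-12)


def test_empty_inputs_rejected(bundle):
    with pytest.raises(ValueError):
        motif_enrichment({}, {"b": "ACGT"}, bundle.pwms)
    with pytest.raises(ValueError):
        motif_enrichment({"a": "ACGT"}, {"b": "ACGT"}, [])


def test_tf_target_correlation_perfect_for_shared_profile():
    import pandas as pd

    stages = list("abcd")
    tf = pd.Series([1.0, 2.0, 3.0, 4.0], index=stages)
    targets = pd.DataFrame([[2, 4, 6, 8], [1, 3, 5, 7]], columns=stages)
    assert tf_target_correlation(tf, targets) == pytest.approx(1.0)
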