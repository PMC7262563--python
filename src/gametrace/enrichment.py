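"""Over-representation machinery: term enrichment and promoter motif scanning.

Term enrichment is the one-sided hypergeometric over-representation test
with Benjamini-Hochberg FDR across tested terms.  Motif analysis extracts
±250 bp promoter sequences, scans both strands with log-odds position
weight matrices, and tests promoters-with-a-hit counts against a background
promoter set with the same hypergeometric machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import hypergeom, spearmanr
from statsmodels.stats.multitest import multipletests

from .io_formats import PWM, TermSets, TranscriptRecord

__all__ = [
    "MotifHit",
    "hypergeom_test",
    "term_enrichment",
    "extract_promoter_seqs",
    "scan_pwm",
    "motif_enrichment",
    "tf_target_correlation",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based position of the match start on the forward sequence
    strand: str
    score: float


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): over-representation p-value.

    ``k`` observed overlap, ``K`` annotated set size, ``n`` query size,
    ``N`` universe size.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric instance k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def term_enrichment(
    query: Sequence[str],
    terms: TermSets,
    universe: Sequence[str],
    p_max: float = 0.05,
    report_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query set.

    Terms are intersected with the universe; terms with zero overlap are
    dropped.  BH-FDR is computed across all tested terms; the default
    report keeps terms with p < ``p_max`` (set ``report_all`` to keep all).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query) & universe_set
    if set(query) - universe_set:
        raise ValueError("query contains genes outside the universe")
    N, n = len(universe_set), len(query_set)

    rows = []
    for tid, (name, genes) in terms:
        gset = genes & universe_set
        if not gset:
            continue
        k = len(gset & query_set)
        if k == 0:
            continue
        rows.append(
            dict(
                term_id=tid,
                term_name=name,
                k=k,
                K=len(gset),
                n=n,
                N=N,
                p_value=hypergeom_test(k, len(gset), n, N),
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    if not report_all:
        df = df[df["p_value"] < p_max].reset_index(drop=True)
    return df


def extract_promoter_seqs(
    transcripts: Sequence[TranscriptRecord],
    genome: Mapping[str, str],
    flank: int = 250,
) -> dict[str, str]:
    """±flank sequence around each TSS, reverse-complemented on the - strand.

    ``genome`` maps chromosome name to sequence (a ``pyfaidx.Fasta`` works:
    slices are taken 0-based half-open and stringified).
    """
    seqs: dict[str, str] = {}
    for t in transcripts:
        if t.chrom not in genome:
            raise KeyError(f"chromosome {t.chrom} missing from genome")
        chrom_seq = genome[t.chrom]
        start = max(0, t.tss - flank)
        end = t.tss + flank
        seq = str(chrom_seq[start:end]).upper()
        if t.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        seqs[t.transcript_id] = seq
    return seqs


def _log_odds(pwm: PWM, background: np.ndarray) -> np.ndarray:
    """5 x L log2-odds table; row 4 (N) scores 0."""
    lod = np.zeros((5, pwm.length))
    lod[:4] = np.log2(pwm.matrix / background[:, None])
    return lod


def scan_pwm(
    seq: str,
    pwm: PWM,
    background: np.ndarray | None = None,
    score_fraction: float = 0.8,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Scan both strands for log-odds matches above a fractional threshold.

    A hit requires log-odds >= ``score_fraction`` times the maximum
    attainable score.  ``N`` bases contribute zero log-odds.  Reverse-strand
    hits report the match start offset on the forward sequence.
    """
    if background is None:
        background = np.full(4, 0.25)
    L = pwm.length
    if L > len(seq):
        return []
    lod = _log_odds(pwm, background)
    max_score = lod[:4].max(axis=0).sum()
    if max_score <= 0:
        return []  # PWM no more informative than background: nothing to find
    threshold = score_fraction * max_score

    codes = np.fromiter((_CODE.get(c, 4) for c in seq.upper()), dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    cols = np.arange(L)
    fwd = lod[windows, cols].sum(axis=1)
    # reverse strand: scan with the reverse-complemented matrix
    rc = lod[:4, ::-1][::-1]
    lod_rc = np.vstack([rc, np.zeros(L)])
    rev = lod_rc[windows, cols].sum(axis=1)

    hits = [
        MotifHit(sequence_id, int(i), "+", float(s))
        for i, s in enumerate(fwd)
        if s >= threshold
    ]
    hits += [
        MotifHit(sequence_id, int(i), "-", float(s))
        for i, s in enumerate(rev)
        if s >= threshold
    ]
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def motif_enrichment(
    foreground: Mapping[str, str],
    background: Mapping[str, str],
    pwms: Sequence[PWM],
    score_fraction: float = 0.8,
    nucleotide_background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-PWM over-representation of promoters-with-a-hit in the foreground.

    k counts foreground sequences with >= 1 hit; the universe is
    foreground + background sequences; BH-FDR across PWMs.
    """
    if not foreground or not background:
        raise ValueError("foreground and background sequence sets must be non-empty")
    if not pwms:
        raise ValueError("empty PWM list")
    overlap = set(foreground) & set(background)
    if overlap:
        raise ValueError(f"sequences in both sets: {sorted(overlap)[:3]}")

    n = len(foreground)
    N = n + len(background)
    rows = []
    for pwm in pwms:
        k = sum(
            1
            for sid, s in foreground.items()
            if scan_pwm(s, pwm, nucleotide_background, score_fraction, sid)
        )
        bg_hits = sum(
            1
            for sid, s in background.items()
            if scan_pwm(s, pwm, nucleotide_background, score_fraction, sid)
        )
        K = k + bg_hits
        p = hypergeom_test(k, K, n, N) if K else 1.0
        rows.append(dict(pwm=pwm.name, k=k, K=K, n=n, N=N, p_value=p))
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "pwm"]).reset_index(drop=True)


def tf_target_correlation(
    tf_stage_means: pd.Series, target_stage_means: pd.DataFrame
) -> float:
    """Spearman correlation between a TF's stage profile and the mean
    trajectory of its motif-hit target transcripts."""
    if list(tf_stage_means.index) != list(target_stage_means.columns):
        raise ValueError("stage grids must match")
    mean_target = target_stage_means.mean(axis=0)
    return float(spearmanr(tf_stage_means.to_numpy(), mean_target.to_numpy()).statistic)
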