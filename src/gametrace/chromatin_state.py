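"""Promoter chromatin-state analysis from H3K4me3 / H3K27me3 coverage.

Promoters are ±``flank`` windows around the TSS, binned at ``bin_size`` in
the direction of transcription.  Binned coverage is normalized to counts
per million and log2(1+x)-transformed, promoters are clustered with k-means
on the concatenated per-bin-standardized [K4 ‖ K27] profile vectors, and
clusters are labeled with the four-state vocabulary high_K4 / low_K4 /
bivalent / K4minus_K27minus using quantile thresholds on the central-2 kb
signal.  ``trace_states`` re-derives each cluster's label from another
compartment's coverage to call the sperm-derived state maintained, lost, or
changed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_formats import CoverageTrack, ExpressionMatrix, SampleSheet, TranscriptRecord

log = logging.getLogger(__name__)

__all__ = [
    "STATES",
    "PromoterWindow",
    "PromoterSignalMatrix",
    "ChromatinAssignment",
    "LabelThresholds",
    "promoter_windows",
    "signal_matrix",
    "cluster_promoters",
    "central_means",
    "label_thresholds",
    "label_clusters",
    "expression_by_state",
    "trace_states",
]

STATES = ("high_K4", "low_K4", "bivalent", "K4minus_K27minus")


@dataclass(frozen=True)
class PromoterWindow:
    """A ±flank window around one TSS, binned along transcription direction.

    ``window_start``/``window_end`` are genomic (0-based half-open) and may
    conceptually start before position 0; bins falling outside the
    chromosome are flagged missing and zero-filled, never dropped.
    Bin 0 is ``flank`` bp upstream of the TSS in transcription direction.
    """

    transcript_id: str
    chrom: str
    window_start: int
    window_end: int
    strand: str
    bins: int
    bin_size: int

    @property
    def bin_edges(self) -> np.ndarray:
        """Genomic bin edges, ascending (length bins + 1)."""
        return self.window_start + self.bin_size * np.arange(self.bins + 1)

    @property
    def missing_bins(self) -> np.ndarray:
        """Boolean mask (in transcription-direction bin order) of bins that
        overhang the chromosome start."""
        edges = self.bin_edges
        missing = edges[:-1] < 0
        if self.strand == "-":
            missing = missing[::-1]
        return missing


def promoter_windows(
    transcripts: Sequence[TranscriptRecord],
    flank: int = 10_000,
    bin_size: int = 100,
) -> list[PromoterWindow]:
    """One ±flank window per transcript, centered on its TSS."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    if (2 * flank) % bin_size != 0:
        raise ValueError("2*flank must be divisible by bin_size")
    bins = (2 * flank) // bin_size
    return [
        PromoterWindow(
            transcript_id=t.transcript_id,
            chrom=t.chrom,
            window_start=t.tss - flank,
            window_end=t.tss + flank,
            strand=t.strand,
            bins=bins,
            bin_size=bin_size,
        )
        for t in transcripts
    ]


@dataclass
class PromoterSignalMatrix:
    """Transcripts x bins normalized promoter signal for one mark/compartment.

    Values are log2(1 + CPM-scaled mean bin coverage).
    """

    mark: str
    compartment: str
    transcript_ids: list[str]
    matrix: np.ndarray
    bin_size: int
    flank: int
    normalization: str = "cpm_log2"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.transcript_ids):
            raise ValueError("row count must match transcript_ids")
        if not np.isfinite(self.matrix).all():
            raise ValueError("signal matrix contains non-finite values")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def central(self, half_width: int = 1000) -> np.ndarray:
        """Per-transcript mean signal over the central ±half_width region."""
        n = self.n_bins
        k = half_width // self.bin_size
        lo, hi = n // 2 - k, n // 2 + k
        return self.matrix[:, lo:hi].mean(axis=1)

    def subset(self, transcript_ids: Sequence[str]) -> "PromoterSignalMatrix":
        index = {t: i for i, t in enumerate(self.transcript_ids)}
        rows = [index[t] for t in transcript_ids]
        return PromoterSignalMatrix(
            mark=self.mark,
            compartment=self.compartment,
            transcript_ids=list(transcript_ids),
            matrix=self.matrix[rows],
            bin_size=self.bin_size,
            flank=self.flank,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.matrix,
            index=self.transcript_ids,
            columns=[f"bin_{i}" for i in range(self.n_bins)],
        ).to_csv(path, sep="\t", index_label="transcript_id")


def signal_matrix(
    track: CoverageTrack, windows: Sequence[PromoterWindow]
) -> PromoterSignalMatrix:
    """Mean coverage per bin, CPM-scaled by the track library size, log2(1+x).

    Bins overhanging the chromosome start contribute zero signal.
    """
    lib = track.library_size
    if lib <= 0:
        raise ValueError("coverage track has zero library size")
    if not windows:
        raise ValueError("no windows given")
    bins = windows[0].bins
    bin_size = windows[0].bin_size
    out = np.zeros((len(windows), bins), dtype=float)

    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        if w.bins != bins or w.bin_size != bin_size:
            raise ValueError("windows must share bin layout")
        by_chrom.setdefault(w.chrom, []).append(i)

    for chrom, idxs in by_chrom.items():
        edges = np.stack([np.clip(windows[i].bin_edges, 0, None) for i in idxs])
        integrals = track.integral(chrom, edges.ravel()).reshape(edges.shape)
        means = (integrals[:, 1:] - integrals[:, :-1]) / bin_size
        for row, i in enumerate(idxs):
            vec = means[row]
            if windows[i].strand == "-":
                vec = vec[::-1]
            out[i] = vec

    cpm = out * (1e6 / lib)
    return PromoterSignalMatrix(
        mark=track.mark,
        compartment=track.compartment,
        transcript_ids=[w.transcript_id for w in windows],
        matrix=np.log2(1.0 + cpm),
        bin_size=bin_size,
        flank=bins * bin_size // 2,
    )


# ---------------------------------------------------------------------------
# Clustering


def _feature_matrix(
    k4: PromoterSignalMatrix, k27: PromoterSignalMatrix, sd_floor_fraction: float = 0.25
) -> np.ndarray:
    """Concatenated per-bin standardized profiles with a variance floor.

    Near-constant flank bins would be amplified into dominant unit-variance
    noise by plain standardization; flooring each bin's sd at a fraction of
    the largest bin sd keeps the informative promoter-proximal bins in
    charge of the geometry.
    """
    if k4.transcript_ids != k27.transcript_ids:
        raise ValueError("K4 and K27 matrices must share transcript_ids")
    x = np.hstack([k4.matrix, k27.matrix])
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    floor = sd_floor_fraction * sd.max()
    if floor == 0:
        floor = 1.0
    return (x - mu) / np.maximum(sd, floor)


def cluster_promoters(
    k4: PromoterSignalMatrix,
    k27: PromoterSignalMatrix,
    k: int | str = "auto",
    seed: int = 0,
    k_range: range = range(2, 7),
    silhouette_subsample: int = 2000,
) -> np.ndarray:
    """k-means cluster promoters on concatenated standardized profiles.

    ``k='auto'`` selects k over ``k_range`` by mean silhouette score on a
    seeded subsample; the silhouette is evaluated on the central-2 kb
    (K4, K27) summary plane — the scale the state vocabulary is defined
    on — rather than on the high-dimensional profile vectors, where
    flank-bin noise washes out cluster separation.  Returns integer cluster
    ids aligned with ``k4.transcript_ids``.
    """
    x = _feature_matrix(k4, k27)
    n = x.shape[0]
    if np.allclose(x, x[0]):
        warnings.warn("all promoter profiles identical; returning one cluster")
        return np.zeros(n, dtype=int)

    if k == "auto":
        rng = np.random.default_rng(seed)
        sub = (
            rng.choice(n, size=silhouette_subsample, replace=False)
            if n > silhouette_subsample
            else np.arange(n)
        )
        central = np.column_stack([k4.central(), k27.central()])
        best_k, best_score = None, -np.inf
        for kk in k_range:
            if kk >= n:
                break
            km = KMeans(n_clusters=kk, n_init=10, max_iter=300, random_state=seed)
            labels = km.fit_predict(x[sub])
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(central[sub], labels)
            log.info("auto-k: k=%d silhouette=%.4f", kk, score)
            if score > best_score:
                best_k, best_score = kk, score
        if best_k is None:
            raise ValueError("auto-k failed: no k produced >=2 clusters")
        k = best_k

    k = int(k)
    if not 2 <= k <= n:
        raise ValueError(f"need n >= k >= 2, got k={k}, n={n}")
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
    return km.fit_predict(x)


# ---------------------------------------------------------------------------
# Labeling


@dataclass(frozen=True)
class LabelThresholds:
    """Quantile thresholds on central signal used by the labeling rule."""

    k4_q50: float
    k4_q75: float
    k27_q50: float
    k27_q75: float


def central_means(
    k4: PromoterSignalMatrix, k27: PromoterSignalMatrix, half_width: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    return k4.central(half_width), k27.central(half_width)


def label_thresholds(
    k4: PromoterSignalMatrix,
    k27: PromoterSignalMatrix,
    quantiles: tuple[float, float] = (50.0, 75.0),
    half_width: int = 1000,
) -> LabelThresholds:
    """Promoter-wide quantiles of central K4/K27 signal (the state cutoffs)."""
    c4, c27 = central_means(k4, k27, half_width)
    q50_4, q75_4 = np.percentile(c4, quantiles)
    q50_27, q75_27 = np.percentile(c27, quantiles)
    return LabelThresholds(q50_4, q75_4, q50_27, q75_27)


def _label_one(mean_k4: float, mean_k27: float, thr: LabelThresholds) -> str:
    if mean_k4 >= thr.k4_q50 and mean_k27 >= thr.k27_q75:
        return "bivalent"
    if mean_k4 >= thr.k4_q75:
        return "high_K4"
    if mean_k4 >= thr.k4_q50:
        return "low_K4"
    return "K4minus_K27minus"


@dataclass
class ChromatinAssignment:
    """Per-transcript cluster id and chromatin-state label."""

    df: pd.DataFrame  # index transcript_id; cluster_id, state_label,
    # central_K4, central_K27
    cluster_states: dict[int, str]

    @property
    def state_label(self) -> pd.Series:
        return self.df["state_label"]

    def transcripts(self, state: str) -> list[str]:
        return list(self.df.index[self.df["state_label"] == state])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="transcript_id")


def label_clusters(
    cluster_ids: np.ndarray,
    k4: PromoterSignalMatrix,
    k27: PromoterSignalMatrix,
    thresholds: LabelThresholds | None = None,
    half_width: int = 1000,
) -> ChromatinAssignment:
    """Assign a four-state label to every cluster from its mean central signal.

    ``thresholds`` default to promoter-wide quantiles of the matrices given;
    pass thresholds computed on the full promoter universe when labeling a
    subgroup.
    """
    cluster_ids = np.asarray(cluster_ids)
    if len(cluster_ids) != len(k4.transcript_ids):
        raise ValueError("cluster ids must align with matrices")
    if thresholds is None:
        thresholds = label_thresholds(k4, k27, half_width=half_width)
    c4, c27 = central_means(k4, k27, half_width)

    cluster_states: dict[int, str] = {}
    for cid in np.unique(cluster_ids):
        sel = cluster_ids == cid
        if not sel.any():
            raise ValueError(f"cluster {cid} is empty")
        cluster_states[int(cid)] = _label_one(
            float(c4[sel].mean()), float(c27[sel].mean()), thresholds
        )

    df = pd.DataFrame(
        {
            "cluster_id": cluster_ids,
            "state_label": [cluster_states[int(c)] for c in cluster_ids],
            "central_K4": c4,
            "central_K27": c27,
        },
        index=pd.Index(k4.transcript_ids, name="transcript_id"),
    )
    return ChromatinAssignment(df, cluster_states)


# ---------------------------------------------------------------------------
# Expression-by-state and persistence tracing


def expression_by_state(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    assignment: ChromatinAssignment,
    sperm_compartment: str = "sperm",
    compartments: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per (state x compartment) log2(TPM+1) summaries plus the Spearman
    correlation between central K4 signal and mean sperm expression."""
    common = [t for t in assignment.df.index if t in expr.df.index]
    logx = np.log2(expr.df.loc[common] + 1.0)
    states = assignment.df.loc[common, "state_label"]
    if compartments is None:
        compartments = sorted(set(sheet.df["compartment"]))

    rows = []
    for state in sorted(states.unique()):
        sel = states == state
        for compartment in compartments:
            samples = [s for s in sheet.samples(compartment) if s in logx.columns]
            if not samples:
                continue
            vals = logx.loc[sel.to_numpy(), samples].to_numpy().ravel()
            rows.append(
                dict(
                    state=state,
                    compartment=compartment,
                    n=int(sel.sum()),
                    median=float(np.median(vals)) if vals.size else np.nan,
                    q1=float(np.percentile(vals, 25)) if vals.size else np.nan,
                    q3=float(np.percentile(vals, 75)) if vals.size else np.nan,
                )
            )

    sp_samples = [s for s in sheet.samples(sperm_compartment) if s in logx.columns]
    rho = np.nan
    if sp_samples:
        sperm_expr = logx[sp_samples].mean(axis=1).to_numpy()
        central_k4 = assignment.df.loc[common, "central_K4"].to_numpy()
        rho = float(spearmanr(central_k4, sperm_expr).statistic)
    return pd.DataFrame(rows), rho


def trace_states(
    assignment: ChromatinAssignment,
    compartment_matrices: Mapping[str, tuple[PromoterSignalMatrix, PromoterSignalMatrix]],
    half_width: int = 1000,
) -> pd.DataFrame:
    """Re-derive each sperm cluster's state label in other compartments.

    For every (sperm cluster x compartment) the labeling rule is re-applied
    with thresholds recomputed from that compartment's full promoter signal
    distribution.  Status is ``maintained`` when the sperm label re-derives,
    ``lost`` when K4minus_K27minus re-derives for a marked sperm state, and
    ``changed:<label>`` otherwise.
    """
    if not compartment_matrices:
        raise ValueError("no compartment matrices given")
    rows = []
    for compartment, (k4, k27) in compartment_matrices.items():
        thr = label_thresholds(k4, k27, half_width=half_width)
        c4, c27 = central_means(k4, k27, half_width)
        pos = {t: i for i, t in enumerate(k4.transcript_ids)}
        for cid, sperm_label in sorted(assignment.cluster_states.items()):
            members = assignment.df.index[assignment.df["cluster_id"] == cid]
            missing = [t for t in members if t not in pos]
            if missing:
                raise ValueError(
                    f"compartment {compartment} lacks windows for "
                    f"{len(missing)} transcripts (e.g. {missing[0]})"
                )
            idx = [pos[t] for t in members]
            m4, m27 = float(c4[idx].mean()), float(c27[idx].mean())
            new_label = _label_one(m4, m27, thr)
            if new_label == sperm_label:
                status = "maintained"
            elif new_label == "K4minus_K27minus":
                status = "lost"
            else:
                status = f"changed:{new_label}"
            rows.append(
                dict(
                    cluster_id=cid,
                    sperm_state=sperm_label,
                    compartment=compartment,
                    new_state=new_label,
                    status=status,
                    central_K4=m4,
                    central_K27=m27,
                    n_transcripts=len(idx),
                )
            )
    return pd.DataFrame(rows)
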