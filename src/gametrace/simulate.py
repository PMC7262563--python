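"""Synthetic gamete/embryo bundles with planted truth labels.

The generator emulates the statistical structure the pipeline assumes:

* two-plus donor replicates per gamete with consistent, absent, or
  strictly partial (miscellaneous) expression per transcript;
* promoter-centred H3K4me3/H3K27me3 coverage with four planted chromatin
  states — narrow high/low K4 peaks, broad bivalent K27 domains, or
  background only — coupled to sperm expression level;
* stage-ordered preimplantation trajectories (ZGA activation of
  sperm-specific transcripts, decline of sperm-oocyte common ones),
  a spermatogenesis panel peaking in round spermatid for K4-marked
  transcripts, and germ-layer/tissue retention or loss of marks;
* tumor/normal cohorts per cancer code with planted log2 fold changes.

Expression noise is log-normal on the log2(TPM+1) scale (the pipeline
starts from TPM, so count-level realism is not modelled).  All draws come
from numpy Generators seeded as ``default_rng([seed, block])`` in a fixed
documented block order, so a bundle is byte-identical given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    PWM,
    Biotype,
    CoverageTrack,
    ExpressionMatrix,
    SampleSheet,
    TermSets,
    TranscriptRecord,
    write_annotation,
    write_coverage,
    write_expression,
    write_gmt,
    write_pwms,
)

__all__ = [
    "SimConfig",
    "TruthLabels",
    "Bundle",
    "GERM_LAYERS",
    "TISSUES",
    "simulate_bundle",
    "simulate_germlayer_coverage",
    "simulate_tumor_cohort",
    "simulate_motif_sequences",
]

GERM_LAYERS = ("ectoderm", "mesoderm", "endoderm")
TISSUES = ("brain", "heart", "thyroid")
PREIMPLANTATION_STAGES = ("zygote", "2cell", "4cell", "8cell", "morula", "late_blastocyst")
SPERMATOGENESIS_STAGES = (
    "A_dark",
    "A_pale",
    "leptotene_zygotene",
    "early_pachytene",
    "late_pachytene",
    "round_spermatid",
)

DEFAULT_CANCER_CODES = (
    "ACC", "BLCA", "BRCA", "CESC", "CHOL", "COAD", "ESCA", "GBM", "HNSC",
    "KICH", "KIRC", "KIRP", "LGG", "LIHC", "LUAD", "LUSC", "OV", "PAAD",
    "PRAD", "READ", "SARC", "SKCM", "STAD", "TGCT", "THCA", "UCEC",
)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults define the standard study bundle."""

    seed: int = 7
    organism: str = "human"
    n_transcripts: int = 1200
    n_replicates: int = 2

    biotype_fractions: dict = field(
        default_factory=lambda: {
            "lincRNA": 0.35,
            "protein_coding": 0.50,
            "other_ncRNA": 0.15,
        }
    )
    category_fractions: dict = field(
        default_factory=lambda: {
            "Sp": 0.35,
            "Oc": 0.12,
            "SpOc": 0.35,
            "Misc": 0.09,
            "NotExpressed": 0.09,
        }
    )
    #: chromatin states planted for sperm-expressed (Sp/SpOc) transcripts;
    #: lincRNA promoters get three states, protein-coding four (bivalent).
    state_fractions: dict = field(
        default_factory=lambda: {
            "lincRNA": {"high_K4": 0.40, "low_K4": 0.35, "K4minus_K27minus": 0.25},
            "protein_coding": {
                "high_K4": 0.30,
                "low_K4": 0.25,
                "bivalent": 0.30,
                "K4minus_K27minus": 0.15,
            },
            "other_ncRNA": {"high_K4": 0.35, "low_K4": 0.35, "K4minus_K27minus": 0.30},
        }
    )

    # expression model, log2(TPM+1) scale
    expression_threshold: float = 1.0
    state_expression_mean: dict = field(
        default_factory=lambda: {
            "high_K4": 6.5,
            "low_K4": 5.0,
            "bivalent": 4.2,
            "K4minus_K27minus": 3.5,
        }
    )
    oocyte_mean: dict = field(default_factory=lambda: {"Oc": 5.4, "SpOc": 5.8})
    misc_mean: float = 5.0
    expressed_sd: float = 0.55
    background_sd: float = 0.15
    stage_sd: float = 0.30
    dropout_misc: float = 0.0

    # chromatin model
    flank: int = 10_000
    bin_size: int = 100
    k4_peak_sd: float = 500.0
    k27_peak_sd: float = 2000.0
    peak_amplitudes: dict = field(
        default_factory=lambda: {
            "high_K4": (30.0, 0.0),
            "low_K4": (8.0, 0.0),
            "bivalent": (10.0, 20.0),
            "K4minus_K27minus": (0.0, 0.0),
        }
    )
    coverage_background: float = 1.0
    coverage_noise_sd: float = 0.5
    amplitude_jitter_sd: float = 0.05  # log2-scale multiplicative jitter

    #: (category, biotype, state) combinations whose K4/K27 peaks are lost
    #: (background only) in germ layers and tissues; everything else retains.
    lost_in_soma: tuple = (
        ("Sp", "lincRNA", "high_K4"),
        ("Sp", "lincRNA", "low_K4"),
        ("Sp", "protein_coding", "high_K4"),
        ("Sp", "protein_coding", "low_K4"),
    )

    # tumor design
    cancer_codes: tuple = DEFAULT_CANCER_CODES
    n_tumor: int = 12
    n_normal: int = 12
    tumor_base_mean: float = 3.0
    tumor_sd: float = 0.5
    focus_n_codes: int = 21
    focus_lfc: float = 2.0
    other_dereg_code_fraction: float = 0.3
    n_fallback_codes: int = 5

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per gamete")
        for sd in (self.expressed_sd, self.background_sd, self.stage_sd):
            if sd < 0:
                raise ValueError("noise sd must be >= 0")
        if not 0 <= self.dropout_misc <= 1:
            raise ValueError("dropout must be a probability")


@dataclass
class TruthLabels:
    """Planted per-transcript labels, plus the tumor log2fc design."""

    df: pd.DataFrame  # index transcript_id; biotype, gamete_category,
    # chromatin_state, trajectory_class, panel_peak
    tumor_lfc: pd.DataFrame  # transcripts x cancer codes

    def to_tsv(self, path) -> None:
        out = self.df.join(self.tumor_lfc.add_prefix("tumor_lfc_"))
        out.to_csv(path, sep="\t", index_label="transcript_id")


@dataclass
class Bundle:
    """Everything the pipeline consumes, in memory, plus the planted truth."""

    config: SimConfig
    transcripts: list[TranscriptRecord]
    expression: ExpressionMatrix
    sheet: SampleSheet
    coverage: dict  # (mark, compartment) -> CoverageTrack
    tumor_expression: ExpressionMatrix
    tumor_sheet: SampleSheet
    tumor_fallback_sheet: SampleSheet
    pwms: list[PWM]
    term_sets: TermSets
    truth: TruthLabels
    genome: dict | None = None

    @property
    def biotypes(self) -> pd.Series:
        return self.truth.df["biotype"]

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "coverage").mkdir(exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.gtf",
            "expression": outdir / "expression.tsv",
            "samples": outdir / "samples.tsv",
            "tumor_expression": outdir / "tumor_expression.tsv",
            "tumor_samples": outdir / "tumor_samples.tsv",
            "tumor_fallback_samples": outdir / "tumor_fallback_samples.tsv",
            "pwms": outdir / "motifs.jaspar",
            "gmt": outdir / "terms.gmt",
            "truth": outdir / "truth.tsv",
        }
        write_annotation(self.transcripts, paths["annotation"])
        write_expression(self.expression, self.sheet, paths["expression"], paths["samples"])
        write_expression(
            self.tumor_expression,
            self.tumor_sheet,
            paths["tumor_expression"],
            paths["tumor_samples"],
        )
        self.tumor_fallback_sheet.df.to_csv(
            paths["tumor_fallback_samples"], sep="\t", index=False
        )
        for (mark, compartment), track in sorted(self.coverage.items()):
            p = outdir / "coverage" / f"{mark}_{compartment}.bedGraph"
            write_coverage(track, p)
            paths[f"coverage/{mark}_{compartment}"] = p
        write_pwms(self.pwms, paths["pwms"], counts_scale=1e6)
        write_gmt(self.term_sets, paths["gmt"])
        self.truth.to_tsv(paths["truth"])
        if self.genome is not None:
            paths["genome"] = outdir / "genome.fa"
            with open(paths["genome"], "w") as fh:
                for chrom, seq in self.genome.items():
                    fh.write(f">{chrom}\n")
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i : i + 60] + "\n")
        return paths


# ---------------------------------------------------------------------------
# helpers


def _largest_remainder(fractions: dict, total: int) -> dict:
    """Integer counts summing to total, proportional to fractions."""
    keys = list(fractions)
    raw = np.array([fractions[k] for k in keys], dtype=float)
    raw = raw / raw.sum() * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return dict(zip(keys, counts))


def _log2_tpm_draw(rng, mean, sd) -> np.ndarray:
    """TPM from a clipped normal on the log2(TPM+1) scale."""
    x = np.clip(rng.normal(mean, sd), 0.0, None)
    return np.exp2(x) - 1.0


def _zga_start_index(organism: str) -> int:
    # human ZGA window 4cell-8cell; mouse 2cell-4cell
    return 2 if organism == "human" else 1


def _trajectory_profile(traj: str, organism: str, n_stages: int) -> np.ndarray:
    """Planted log2(TPM+1) stage means for one trajectory class."""
    zga = _zga_start_index(organism)
    prof = np.zeros(n_stages)
    if traj == "zga_activated":
        prof[zga] = 2.8
        for i in range(zga + 1, n_stages):
            prof[i] = max(5.0 - 0.2 * (i - zga - 1), 0.5)
    elif traj == "early_then_degraded":
        prof[:zga] = 5.0
        decline = [4.5, 2.5, 1.2, 0.3, 0.1, 0.05]
        for j, i in enumerate(range(zga, n_stages)):
            prof[i] = decline[min(j, len(decline) - 1)]
    elif traj == "flat_on":
        prof[:] = 4.5
    elif traj == "flat_off":
        prof[:] = 0.0
    else:
        raise ValueError(traj)
    return prof


# ---------------------------------------------------------------------------
# main generator


def _plant_layout(config: SimConfig, rng) -> pd.DataFrame:
    """Per-transcript biotype, category, chromatin state and misc design."""
    n = config.n_transcripts
    bio_counts = _largest_remainder(config.biotype_fractions, n)
    biotype = np.concatenate(
        [np.full(c, b, dtype=object) for b, c in bio_counts.items()]
    )

    category = np.empty(n, dtype=object)
    state = np.full(n, "K4minus_K27minus", dtype=object)
    start = 0
    for b, c in bio_counts.items():
        cat_counts = _largest_remainder(config.category_fractions, c)
        cats = np.concatenate(
            [np.full(cc, cat, dtype=object) for cat, cc in cat_counts.items()]
        )
        rng.shuffle(cats)
        category[start : start + c] = cats
        # chromatin states for sperm-expressed transcripts only
        marked = np.flatnonzero(np.isin(cats, ("Sp", "SpOc"))) + start
        st_counts = _largest_remainder(config.state_fractions[b], len(marked))
        states = np.concatenate(
            [np.full(sc, s, dtype=object) for s, sc in st_counts.items()]
        )
        rng.shuffle(states)
        state[marked] = states
        start += c

    traj_map = {
        "Sp": "zga_activated",
        "SpOc": "early_then_degraded",
        "Oc": "flat_on",
        "Misc": "flat_off",
        "NotExpressed": "flat_off",
    }
    trajectory = np.array([traj_map[c] for c in category], dtype=object)

    # miscellaneous design: one gamete with a strict nonempty replicate subset
    misc_gamete = np.full(n, "", dtype=object)
    misc_reps = [()] * n
    for i in np.flatnonzero(category == "Misc"):
        gamete = "sperm" if rng.random() < 0.5 else "oocyte"
        k = int(rng.integers(1, max(config.n_replicates, 2)))
        reps = tuple(sorted(rng.choice(config.n_replicates, size=k, replace=False)))
        misc_gamete[i] = gamete
        misc_reps[i] = reps

    # spermatogenesis panel peak: K4-marked sperm-expressed transcripts peak
    # in round spermatid; other sperm-expressed ones in an earlier cell type
    panel_peak = np.full(n, "", dtype=object)
    for i in range(n):
        if category[i] in ("Sp", "SpOc"):
            if state[i] in ("high_K4", "low_K4"):
                panel_peak[i] = "round_spermatid"
            else:
                panel_peak[i] = SPERMATOGENESIS_STAGES[int(rng.integers(0, 5))]

    ids = [f"T{i:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "biotype": biotype,
            "gamete_category": category,
            "chromatin_state": state,
            "trajectory_class": trajectory,
            "panel_peak": panel_peak,
            "misc_gamete": misc_gamete,
            "misc_reps": misc_reps,
        },
        index=pd.Index(ids, name="transcript_id"),
    )


def _make_transcripts(layout: pd.DataFrame, config: SimConfig, rng) -> list[TranscriptRecord]:
    spacing = 2 * config.flank + 1000
    records = []
    for i, (tid, row) in enumerate(layout.iterrows()):
        tss = config.flank + i * spacing
        length = int(rng.integers(2000, 8001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss - length + 1, tss + 1
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=tid.replace("T", "G"),
                biotype=Biotype(row["biotype"]),
                chrom="chr1",
                start=start,
                end=end,
                strand=strand,
            )
        )
    return records


def _gamete_block(layout, config: SimConfig, rng, gamete: str) -> np.ndarray:
    """TPM (n x replicates) for one gamete compartment."""
    n, reps = len(layout), config.n_replicates
    mean = np.zeros((n, reps))
    sd = np.full((n, reps), config.background_sd)
    cat = layout["gamete_category"].to_numpy()
    state = layout["chromatin_state"].to_numpy()

    if gamete == "sperm":
        expressed = np.isin(cat, ("Sp", "SpOc"))
        means = np.array([config.state_expression_mean[s] for s in state])
        mean[expressed] = means[expressed, None]
    else:
        for catname, m in config.oocyte_mean.items():
            mean[cat == catname] = m
        expressed = np.isin(cat, ("Oc", "SpOc"))
    sd[expressed] = config.expressed_sd

    for i in np.flatnonzero(cat == "Misc"):
        if layout["misc_gamete"].iloc[i] == gamete:
            for r in layout["misc_reps"].iloc[i]:
                mean[i, r] = config.misc_mean
                sd[i, r] = config.expressed_sd

    tpm = _log2_tpm_draw(rng, mean, sd)
    if config.dropout_misc > 0:
        misc_expressed = (mean > 0) & (cat == "Misc")[:, None]
        drop = rng.random(mean.shape) < config.dropout_misc
        tpm[misc_expressed & drop] = 0.0
    return tpm


def _stage_block(layout, config: SimConfig, rng, stages, profile_for) -> np.ndarray:
    """TPM (n x len(stages)*reps) for an ordered stage panel."""
    n, reps = len(layout), config.n_replicates
    means = np.zeros((n, len(stages)))
    for i in range(n):
        means[i] = profile_for(layout.iloc[i])
    mean_full = np.repeat(means, reps, axis=1)
    sd_full = np.where(mean_full > 0, config.stage_sd, config.background_sd)
    return _log2_tpm_draw(rng, mean_full, sd_full)


def _coverage_for(
    transcripts,
    layout,
    config: SimConfig,
    mark: str,
    compartment: str,
    rng,
    lost_mask: np.ndarray | None = None,
) -> CoverageTrack:
    """Bin-resolution bedGraph coverage over every promoter window."""
    n = len(transcripts)
    bins = 2 * config.flank // config.bin_size
    offsets = (np.arange(bins) + 0.5) * config.bin_size - config.flank  # to TSS
    peak_sd = config.k4_peak_sd if mark == "H3K4me3" else config.k27_peak_sd
    shape = np.exp(-0.5 * (offsets / peak_sd) ** 2)

    amp_index = 0 if mark == "H3K4me3" else 1
    amps = np.array(
        [config.peak_amplitudes[s][amp_index] for s in layout["chromatin_state"]]
    )
    if lost_mask is not None:
        amps = np.where(lost_mask, 0.0, amps)
    jitter = np.exp2(rng.normal(0.0, config.amplitude_jitter_sd, size=n))
    values = (
        config.coverage_background
        + (amps * jitter)[:, None] * shape[None, :]
        + rng.normal(0.0, config.coverage_noise_sd, size=(n, bins))
    )
    values = np.clip(values, 0.0, None)

    starts = np.concatenate(
        [t.tss - config.flank + np.arange(bins) * config.bin_size for t in transcripts]
    )
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + config.bin_size,
            "value": np.round(values.ravel(), 6),
        }
    )
    return CoverageTrack(mark=mark, compartment=compartment, intervals=df)


def simulate_germlayer_coverage(
    truth: TruthLabels,
    config: SimConfig,
    transcripts: list[TranscriptRecord],
    compartments: tuple = GERM_LAYERS + TISSUES,
) -> dict:
    """Coverage per germ layer / tissue applying the retention design.

    Promoters whose (category, biotype, state) is in ``config.lost_in_soma``
    get background-only signal for both marks; everything else retains its
    sperm peaks.
    """
    if len(truth.df) == 0:
        return {}
    layout = truth.df
    lost = np.zeros(len(layout), dtype=bool)
    for cat, bio, state in config.lost_in_soma:
        lost |= (
            (layout["gamete_category"] == cat)
            & (layout["biotype"] == bio)
            & (layout["chromatin_state"] == state)
        ).to_numpy()
    out = {}
    for ci, compartment in enumerate(compartments):
        rng = np.random.default_rng([config.seed, 1000 + ci])
        for mark in ("H3K4me3", "H3K27me3"):
            out[(mark, compartment)] = _coverage_for(
                transcripts, layout, config, mark, compartment, rng, lost_mask=lost
            )
    return out


def simulate_tumor_cohort(
    gene_ids,
    lfc: pd.DataFrame,
    codes,
    n_tumor: int,
    n_normal: int,
    seed,
    base_mean: float = 3.0,
    sd: float = 0.5,
    fallback_codes: tuple = (),
    n_fallback: int = 0,
) -> tuple[ExpressionMatrix, SampleSheet, SampleSheet]:
    """Tumor/normal cohorts with planted per-(gene x code) log2 fold changes.

    Codes in ``fallback_codes`` get no matched normals; their normals go to
    the returned fallback sheet instead (the GTEx stand-in).
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    cols, comps, reps = [], [], []
    blocks = []
    fb_cols, fb_comps, fb_reps = [], [], []
    fb_blocks = []
    for code in codes:
        shift = lfc[code].to_numpy() if code in lfc.columns else np.zeros(n)
        tumor = _log2_tpm_draw(
            rng, np.tile((base_mean + shift)[:, None], (1, n_tumor)), sd
        )
        normal = _log2_tpm_draw(rng, np.full((n, n_normal), base_mean), sd)
        blocks.append(tumor)
        cols += [f"{code}_T{r}" for r in range(n_tumor)]
        comps += [f"tumor:{code}"] * n_tumor
        reps += [str(r) for r in range(n_tumor)]
        if code in fallback_codes:
            k = n_fallback or n_normal
            fb_blocks.append(normal[:, :k])
            fb_cols += [f"{code}_F{r}" for r in range(k)]
            fb_comps += [f"normal:{code}"] * k
            fb_reps += [str(r) for r in range(k)]
        else:
            blocks.append(normal)
            cols += [f"{code}_N{r}" for r in range(n_normal)]
            comps += [f"normal:{code}"] * n_normal
            reps += [str(r) for r in range(n_normal)]

    all_cols = cols + fb_cols
    matrix = np.hstack(blocks + fb_blocks) if fb_blocks else np.hstack(blocks)
    expr = ExpressionMatrix(pd.DataFrame(matrix, index=gene_ids, columns=all_cols))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": cols,
                "organism": "human",
                "compartment": comps,
                "replicate": reps,
            }
        )
    )
    fallback_sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": fb_cols,
                "organism": "human",
                "compartment": fb_comps,
                "replicate": fb_reps,
            }
        )
    )
    return expr, sheet, fallback_sheet


def _make_pwms(rng) -> list[PWM]:
    """One sharp planted motif plus informative decoys."""
    pwms = []
    planted = "TGACGTCA"
    mat = np.full((4, len(planted)), 0.01)
    for j, b in enumerate(planted):
        mat["ACGT".index(b), j] = 0.97
    pwms.append(PWM(name="PLANTED_TGACGTCA", matrix=mat / mat.sum(axis=0)))
    for i in range(9):
        L = int(rng.integers(8, 11))
        consensus = rng.integers(0, 4, size=L)
        mat = np.full((4, L), 0.04)
        mat[consensus, np.arange(L)] = 0.88
        pwms.append(PWM(name=f"DECOY_{i:02d}", matrix=mat / mat.sum(axis=0)))
    return pwms


def _make_terms(layout: pd.DataFrame, rng) -> TermSets:
    """GO-style term sets; one term is loaded with Sp high-K4 genes."""
    genes = [t.replace("T", "G") for t in layout.index]
    sp_high = [
        t.replace("T", "G")
        for t in layout.index[
            (layout["gamete_category"] == "Sp")
            & (layout["chromatin_state"] == "high_K4")
        ]
    ]
    terms = {}
    k = min(40, len(sp_high))
    if k >= 2:
        chosen = list(rng.choice(sp_high, size=k, replace=False))
        terms["T_SPERMATOGENESIS"] = ("spermatogenesis-like planted term", frozenset(chosen))
    for i in range(29):
        size = int(rng.integers(20, 51))
        terms[f"T{i:04d}"] = (
            f"random term {i}",
            frozenset(rng.choice(genes, size=size, replace=False)),
        )
    return TermSets(terms)


def simulate_motif_sequences(
    pwm: PWM,
    n_foreground: int,
    n_background: int,
    fg_rate: float,
    bg_rate: float,
    length: int = 500,
    seed: int = 11,
) -> tuple[dict, dict]:
    """Random promoter-like sequences with the PWM consensus planted at the
    given rates.  Returns (foreground, background) id->sequence maps."""
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus

    def make(n, rate, prefix):
        out = {}
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            if rng.random() < rate:
                pos = int(rng.integers(0, length - len(consensus) + 1))
                seq = seq[:pos] + consensus + seq[pos + len(consensus) :]
            out[f"{prefix}{i:04d}"] = seq
        return out

    return make(n_foreground, fg_rate, "fg"), make(n_background, bg_rate, "bg")


def _make_genome(transcripts, layout, pwm: PWM, rng, plant_rate: float = 0.8) -> dict:
    """Random chr1 sequence with the planted motif near Sp-lincRNA TSSs."""
    length = max(t.end for t in transcripts) + 1000
    seq = rng.choice(np.array(list("ACGT")), size=length)
    consensus = pwm.consensus
    target = (layout["gamete_category"] == "Sp") & (layout["biotype"] == "lincRNA")
    for t, hit in zip(transcripts, target.to_numpy()):
        if hit and rng.random() < plant_rate:
            pos = t.tss + int(rng.integers(-200, 200 - len(consensus)))
            seq[pos : pos + len(consensus)] = list(consensus)
    return {"chr1": "".join(seq)}


def simulate_bundle(config: SimConfig | None = None, include_genome: bool = False) -> Bundle:
    """Generate the full synthetic study bundle (see module docstring).

    Deterministic given ``config.seed``; every file it writes parses with
    :mod:`gametrace.io_formats`.
    """
    if config is None:
        config = SimConfig()
    n_reps = config.n_replicates

    layout = _plant_layout(config, np.random.default_rng([config.seed, 0]))
    transcripts = _make_transcripts(layout, config, np.random.default_rng([config.seed, 1]))

    # --- expression: gametes + preimplantation + spermatogenesis + soma
    rng_expr = np.random.default_rng([config.seed, 2])
    blocks, cols, comps = [], [], []

    for gamete in ("sperm", "oocyte"):
        blocks.append(_gamete_block(layout, config, rng_expr, gamete))
        cols += [f"{gamete}_rep{r}" for r in range(n_reps)]
        comps += [gamete] * n_reps

    zga = _zga_start_index(config.organism)

    def preimpl_profile(row):
        return np.exp2(
            _trajectory_profile(
                row["trajectory_class"], config.organism, len(PREIMPLANTATION_STAGES)
            )
        ) - 1.0

    pre_means = np.log2(
        1.0
        + np.stack([preimpl_profile(layout.iloc[i]) for i in range(len(layout))])
    )
    blocks.append(
        _stage_block(
            layout,
            config,
            rng_expr,
            PREIMPLANTATION_STAGES,
            lambda row: pre_means[layout.index.get_loc(row.name)],
        )
    )
    for stage in PREIMPLANTATION_STAGES:
        cols += [f"{stage}_rep{r}" for r in range(n_reps)]
        comps += [stage] * n_reps

    def sperm_panel_profile(row):
        prof = np.zeros(len(SPERMATOGENESIS_STAGES))
        if row["panel_peak"]:
            prof[SPERMATOGENESIS_STAGES.index(row["panel_peak"])] = 5.5
        return prof

    blocks.append(
        _stage_block(layout, config, rng_expr, SPERMATOGENESIS_STAGES, sperm_panel_profile)
    )
    for stage in SPERMATOGENESIS_STAGES:
        cols += [f"{stage}_rep{r}" for r in range(n_reps)]
        comps += [stage] * n_reps

    soma_on = (
        layout["gamete_category"].isin(("SpOc", "Oc"))
        | (
            (layout["gamete_category"] == "Sp")
            & (layout["biotype"] == "protein_coding")
            & (layout["chromatin_state"] == "bivalent")
        )
    ).to_numpy()

    def soma_profile(row):
        i = layout.index.get_loc(row.name)
        return np.full(1, 4.0) if soma_on[i] else np.zeros(1)

    for compartment in GERM_LAYERS + TISSUES:
        blocks.append(_stage_block(layout, config, rng_expr, (compartment,), soma_profile))
        cols += [f"{compartment}_rep{r}" for r in range(n_reps)]
        comps += [compartment] * n_reps

    expr = ExpressionMatrix(
        pd.DataFrame(np.hstack(blocks), index=layout.index, columns=cols)
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": cols,
                "organism": config.organism,
                "compartment": comps,
                "replicate": [c.rsplit("rep", 1)[-1] for c in cols],
            }
        )
    )

    # --- coverage: sperm, then germ layers / tissues with retention design
    coverage = {}
    rng_cov = np.random.default_rng([config.seed, 3])
    for mark in ("H3K4me3", "H3K27me3"):
        coverage[(mark, "sperm")] = _coverage_for(
            transcripts, layout, config, mark, "sperm", rng_cov
        )

    # --- tumor design
    rng_tum = np.random.default_rng([config.seed, 4])
    codes = list(config.cancer_codes)
    gene_ids = list(layout.index)
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=codes)
    sp_high = list(
        layout.index[
            (layout["gamete_category"] == "Sp")
            & (layout["biotype"] == "lincRNA")
            & (layout["chromatin_state"] == "high_K4")
        ]
    )
    focus = sp_high[0] if sp_high else gene_ids[0]
    lfc.loc[focus, codes[: config.focus_n_codes]] = config.focus_lfc
    for tid in sp_high[1:]:
        hit = rng_tum.random(len(codes)) < config.other_dereg_code_fraction
        signs = np.where(rng_tum.random(len(codes)) < 0.5, 1.0, -1.0)
        lfc.loc[tid, :] = np.where(hit, 2.0 * signs, 0.0)
    fallback_codes = tuple(codes[-config.n_fallback_codes :]) if config.n_fallback_codes else ()
    tumor_expr, tumor_sheet, fb_sheet = simulate_tumor_cohort(
        gene_ids,
        lfc,
        codes,
        config.n_tumor,
        config.n_normal,
        seed=[config.seed, 5],
        base_mean=config.tumor_base_mean,
        sd=config.tumor_sd,
        fallback_codes=fallback_codes,
        n_fallback=config.n_normal,
    )

    truth = TruthLabels(
        df=layout[
            [
                "biotype",
                "gamete_category",
                "chromatin_state",
                "trajectory_class",
                "panel_peak",
            ]
        ].copy(),
        tumor_lfc=lfc,
    )

    coverage.update(simulate_germlayer_coverage(truth, config, transcripts))

    pwms = _make_pwms(np.random.default_rng([config.seed, 6]))
    term_sets = _make_terms(layout, np.random.default_rng([config.seed, 7]))
    genome = (
        _make_genome(transcripts, layout, pwms[0], np.random.default_rng([config.seed, 8]))
        if include_genome
        else None
    )

    return Bundle(
        config=config,
        transcripts=transcripts,
        expression=expr,
        sheet=sheet,
        coverage=coverage,
        tumor_expression=tumor_expr,
        tumor_sheet=tumor_sheet,
        tumor_fallback_sheet=fb_sheet,
        pwms=pwms,
        term_sets=term_sets,
        truth=truth,
        genome=genome,
    )
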