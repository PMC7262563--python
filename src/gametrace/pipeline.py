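"""File-level orchestration of the analysis stages.

Stages communicate through documented TSVs (inspectability, partial
reruns): classify -> chromatin -> dynamics -> enrich -> tumor.  Each stage
function reads its inputs from disk, writes its outputs under
``config.outdir``, and returns the written paths; ``run_all`` simply runs
them in order and writes a manifest with content hashes, so a stagewise run
is bit-identical to ``run_all``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    read_annotation,
    read_coverage,
    read_expression,
    read_gmt,
    read_pwms,
)
from .gamete_classify import call_expressed, classify_gamete
from .chromatin_state import (
    cluster_promoters,
    label_clusters,
    label_thresholds,
    promoter_windows,
    signal_matrix,
    trace_states,
)
from .expression_dynamics import (
    HUMAN_PREIMPLANTATION,
    MOUSE_PREIMPLANTATION,
    aggregate_stages,
    call_trajectory,
    log_transform,
    zscore_rows,
)
from .enrichment import extract_promoter_seqs, motif_enrichment, term_enrichment
from .tumor_dereg import deregulation_call, normal_source_merge, pan_cancer_summary

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_all",
    "stage_classify",
    "stage_chromatin",
    "stage_dynamics",
    "stage_enrich",
    "stage_tumor",
    "GROUPS",
]

#: chromatin clustering runs within each (category, biotype) analysis group
GROUPS = (
    ("Sp", "lincRNA"),
    ("SpOc", "lincRNA"),
    ("Sp", "protein_coding"),
    ("SpOc", "protein_coding"),
)

MARKS = ("H3K4me3", "H3K27me3")


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    annotation: str
    expression: str
    sheet: str
    coverage_dir: str
    outdir: str
    pwms: str | None = None
    gmt: str | None = None
    genome: str | None = None
    tumor_expression: str | None = None
    tumor_sheet: str | None = None
    tumor_fallback_sheet: str | None = None

    organism: str = "human"
    seed: int = 0
    expression_threshold: float = 1.0
    flank: int = 10_000
    bin_size: int = 100
    k: int | str = "auto"
    lfc_min: float = 1.0
    alpha: float = 0.05

    def validate(self) -> None:
        required = ["annotation", "expression", "sheet", "coverage_dir"]
        missing = [f for f in required if not Path(getattr(self, f)).exists()]
        optional = [
            f
            for f in ("pwms", "gmt", "genome", "tumor_expression", "tumor_sheet")
            if getattr(self, f) and not Path(getattr(self, f)).exists()
        ]
        if missing or optional:
            raise FileNotFoundError(f"missing inputs: {missing + optional}")

    @property
    def out(self) -> Path:
        p = Path(self.outdir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def _coverage_path(cfg: RunConfig, mark: str, compartment: str) -> Path:
    return Path(cfg.coverage_dir) / f"{mark}_{compartment}.bedGraph"


def _biotypes(cfg: RunConfig) -> pd.Series:
    records = read_annotation(cfg.annotation)
    return pd.Series(
        {r.transcript_id: r.biotype.value for r in records}, name="biotype"
    )


def stage_classify(cfg: RunConfig) -> list[Path]:
    expr, sheet = read_expression(cfg.expression, cfg.sheet)
    flags = call_expressed(expr, cfg.expression_threshold)
    classification = classify_gamete(flags, sheet)
    out = cfg.out / "classification.tsv"
    classification.to_tsv(out, biotypes=_biotypes(cfg))
    return [out]


def _load_classification(cfg: RunConfig) -> pd.DataFrame:
    path = cfg.out / "classification.tsv"
    if not path.exists():
        raise FileNotFoundError("run the classify stage first")
    return pd.read_csv(path, sep="\t", index_col=0)


def stage_chromatin(cfg: RunConfig) -> list[Path]:
    records = read_annotation(cfg.annotation)
    windows = promoter_windows(records, cfg.flank, cfg.bin_size)
    sperm = {
        mark: signal_matrix(
            read_coverage(_coverage_path(cfg, mark, "sperm"), mark, "sperm"), windows
        )
        for mark in MARKS
    }
    thresholds = label_thresholds(sperm["H3K4me3"], sperm["H3K27me3"])
    classification = _load_classification(cfg)

    written = []
    assignments = {}
    offset = 0
    frames = []
    for category, biotype in GROUPS:
        ids = classification.index[
            (classification["category"] == category)
            & (classification["biotype"] == biotype)
        ]
        if len(ids) < 3:
            continue
        k4 = sperm["H3K4me3"].subset(list(ids))
        k27 = sperm["H3K27me3"].subset(list(ids))
        clusters = cluster_promoters(k4, k27, k=cfg.k, seed=cfg.seed)
        assignment = label_clusters(clusters, k4, k27, thresholds=thresholds)
        assignment.df["cluster_id"] += offset
        assignment.cluster_states = {
            cid + offset: s for cid, s in assignment.cluster_states.items()
        }
        offset = int(assignment.df["cluster_id"].max()) + 1
        assignments[(category, biotype)] = assignment
        frame = assignment.df.copy()
        frame.insert(0, "group", f"{category}-{biotype}")
        frames.append(frame)

    out = cfg.out / "chromatin_assignment.tsv"
    pd.concat(frames).to_csv(out, sep="\t", index_label="transcript_id")
    written.append(out)

    for mark in MARKS:
        p = cfg.out / f"signal_{mark}_sperm.tsv"
        sperm[mark].to_tsv(p)
        written.append(p)

    # persistence across every other compartment with coverage on disk
    compartments = sorted(
        {
            p.stem.split("_", 1)[1]
            for p in Path(cfg.coverage_dir).glob("*.bedGraph")
            if p.stem.split("_", 1)[1] != "sperm"
        }
    )
    if compartments:
        comp_mats = {
            comp: tuple(
                signal_matrix(
                    read_coverage(_coverage_path(cfg, mark, comp), mark, comp), windows
                )
                for mark in MARKS
            )
            for comp in compartments
        }
        traces = []
        for (category, biotype), assignment in assignments.items():
            t = trace_states(assignment, comp_mats)
            t.insert(0, "group", f"{category}-{biotype}")
            traces.append(t)
        out = cfg.out / "persistence.tsv"
        pd.concat(traces, ignore_index=True).to_csv(out, sep="\t", index=False)
        written.append(out)
    return written


def stage_dynamics(cfg: RunConfig) -> list[Path]:
    expr, sheet = read_expression(cfg.expression, cfg.sheet)
    grid = HUMAN_PREIMPLANTATION if cfg.organism == "human" else MOUSE_PREIMPLANTATION
    stage_means = aggregate_stages(expr, sheet, grid)
    calls = call_trajectory(stage_means, grid, threshold=cfg.expression_threshold)
    out1 = cfg.out / "trajectory.tsv"
    calls.to_tsv(out1)
    z = zscore_rows(log_transform(stage_means))
    out2 = cfg.out / "stage_zscores.tsv"
    z.to_csv(out2, sep="\t", index_label="transcript_id")
    return [out1, out2]


def stage_enrich(cfg: RunConfig) -> list[Path]:
    classification = _load_classification(cfg)
    written = []
    gene_of = {
        r.transcript_id: r.gene_id for r in read_annotation(cfg.annotation)
    }
    universe = sorted({gene_of[t] for t in classification.index if t in gene_of})
    if cfg.gmt:
        terms = read_gmt(cfg.gmt)
        frames = []
        for category in ("Sp", "Oc", "SpOc"):
            query = sorted(
                {
                    gene_of[t]
                    for t in classification.index[
                        classification["category"] == category
                    ]
                    if t in gene_of
                }
            )
            if not query:
                continue
            res = term_enrichment(query, terms, universe, report_all=True)
            res.insert(0, "query_category", category)
            frames.append(res)
        out = cfg.out / "term_enrichment.tsv"
        pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False)
        written.append(out)
    if cfg.genome and cfg.pwms:
        from pyfaidx import Fasta

        records = read_annotation(cfg.annotation)
        genome = Fasta(cfg.genome)
        pwms = read_pwms(cfg.pwms)
        fg_ids = set(
            classification.index[
                (classification["category"] == "Sp")
                & (classification["biotype"] == "lincRNA")
            ]
        )
        fg = extract_promoter_seqs([r for r in records if r.transcript_id in fg_ids], genome)
        bg = extract_promoter_seqs(
            [r for r in records if r.transcript_id not in fg_ids], genome
        )
        res = motif_enrichment(fg, bg, pwms)
        out = cfg.out / "motif_enrichment.tsv"
        res.to_csv(out, sep="\t", index=False)
        written.append(out)
    return written


def stage_tumor(cfg: RunConfig) -> list[Path]:
    if not (cfg.tumor_expression and cfg.tumor_sheet):
        return []
    from .io_formats import ExpressionMatrix, SampleSheet

    # fallback-normal columns live in the matrix but belong to a separate
    # sheet until merged, so validate sample coverage after the merge
    expr = ExpressionMatrix(pd.read_csv(cfg.tumor_expression, sep="\t", index_col=0))
    sheet = SampleSheet(pd.read_csv(cfg.tumor_sheet, sep="\t", dtype=str))
    codes = sorted(
        {
            c.split(":", 1)[1]
            for c in sheet.df["compartment"]
            if c.startswith("tumor:")
        }
    )
    provenance = {c: "matched" for c in codes}
    if cfg.tumor_fallback_sheet:
        fallback = SampleSheet(pd.read_csv(cfg.tumor_fallback_sheet, sep="\t", dtype=str))
        sheet, provenance, excluded = normal_source_merge(sheet, fallback, codes)
        codes = [c for c in codes if c not in excluded]
    table = deregulation_call(
        expr, sheet, codes, lfc_min=cfg.lfc_min, alpha=cfg.alpha, provenance=provenance
    )
    out1 = cfg.out / "deregulation.tsv"
    table.to_tsv(out1)
    out2 = cfg.out / "pan_cancer.tsv"
    pan_cancer_summary(table).to_csv(out2, sep="\t", index=False)
    return [out1, out2]


STAGES = {
    "classify": stage_classify,
    "chromatin": stage_chromatin,
    "dynamics": stage_dynamics,
    "enrich": stage_enrich,
    "tumor": stage_tumor,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> Path:
    """Run every stage in order; write a manifest of emitted files.

    On a stage failure the manifest still records the completed stages and
    marks the failed one, then the exception propagates.
    """
    cfg.validate()
    manifest: dict = {
        "version": __version__,
        "config": {k: str(v) for k, v in asdict(cfg).items()},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    manifest_path = cfg.out / "manifest.json"
    try:
        for name, fn in STAGES.items():
            paths = fn(cfg)
            manifest["stages"][name] = {
                "files": {
                    str(p.relative_to(cfg.out)): {
                        "sha256": _sha256(p),
                        "rows": sum(1 for _ in open(p)) - 1,
                    }
                    for p in paths
                },
            }
            log.info("stage %s: wrote %d files", name, len(paths))
    except Exception as exc:
        manifest["failed_stage"] = name
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
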