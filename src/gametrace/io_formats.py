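"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are internal 0-based half-open; conversion to the
1-based inclusive convention of GTF happens only at the parse/serialize
boundary.  Every writer emits UTF-8, tab-separated text with ``.`` for
missing values, and every format written here round-trips through its
reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

log = logging.getLogger(__name__)

__all__ = [
    "Biotype",
    "TranscriptRecord",
    "SampleSheet",
    "ExpressionMatrix",
    "CoverageTrack",
    "PWM",
    "TermSets",
    "FormatError",
    "read_annotation",
    "write_annotation",
    "read_expression",
    "write_expression",
    "read_coverage",
    "write_coverage",
    "read_pwms",
    "write_pwms",
    "read_gmt",
    "write_gmt",
    "write_bed6",
]


class FormatError(ValueError):
    """A file violated its format contract."""


class Biotype(str, Enum):
    lincRNA = "lincRNA"
    protein_coding = "protein_coding"
    other_ncRNA = "other_ncRNA"


#: Annotation biotype -> internal three-way partition.  Anything not listed
#: collapses to other_ncRNA so the mapping is total.
DEFAULT_BIOTYPE_MAP: Mapping[str, Biotype] = {
    "lincRNA": Biotype.lincRNA,
    "protein_coding": Biotype.protein_coding,
}


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript with its transcription start site.

    ``start``/``end`` are 0-based half-open; ``tss`` is ``start`` on the +
    strand and ``end - 1`` on the - strand.
    """

    transcript_id: str
    gene_id: str
    biotype: Biotype
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"{self.transcript_id}: start must be < end "
                f"(got {self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class SampleSheet:
    """Sample metadata: one row per sample with organism, compartment, replicate.

    Compartment tokens are free-form stage/tissue names; tumor cohorts use
    ``tumor:<code>`` / ``normal:<code>``.
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "organism", "compartment", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        dup = self.df["sample_id"][self.df["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample_ids: {sorted(dup)}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def samples(self, compartment: str) -> list[str]:
        sel = self.df["compartment"] == compartment
        return list(self.df.loc[sel, "sample_id"])

    def compartment_of(self, sample_id: str) -> str:
        row = self.df.loc[self.df["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["compartment"].iloc[0])

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        keep = self.df[self.df["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep.copy())


@dataclass
class ExpressionMatrix:
    """Transcripts x samples TPM matrix with unique, ordered labels."""

    df: pd.DataFrame  # index: transcript_id, columns: sample_id

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates or self.df.columns.has_duplicates:
            raise FormatError("expression matrix labels must be unique")
        values = self.df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise FormatError("expression matrix contains negative TPM values")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping coverage intervals for one histone mark.

    ``library_size`` is the total signal integral sum(value * length), used
    downstream for counts-per-million normalization.
    """

    mark: str
    compartment: str
    intervals: pd.DataFrame  # chrom, start, end, value

    def __post_init__(self) -> None:
        df = self.intervals
        expect = ["chrom", "start", "end", "value"]
        if list(df.columns) != expect:
            raise FormatError(f"coverage intervals need columns {expect}")
        if len(df):
            if (df["value"].to_numpy() < 0).any():
                raise FormatError("coverage values must be >= 0")
            if (df["start"].to_numpy() >= df["end"].to_numpy()).any():
                raise FormatError("coverage intervals must have start < end")
            df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
                drop=True
            )
            for chrom, sub in df.groupby("chrom", sort=False):
                s = sub["start"].to_numpy()
                e = sub["end"].to_numpy()
                if (s[1:] < e[:-1]).any():
                    i = int(np.argmax(s[1:] < e[:-1]))
                    raise FormatError(
                        f"overlapping intervals on {chrom} near position {s[i + 1]}"
                    )
            self.intervals = df
        self._chrom_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}

    @property
    def library_size(self) -> float:
        df = self.intervals
        if not len(df):
            return 0.0
        lengths = df["end"].to_numpy() - df["start"].to_numpy()
        return float((df["value"].to_numpy() * lengths).sum())

    def _chrom_arrays(self, chrom: str):
        """(starts, ends, values, exclusive cumulative integral) for one chrom."""
        cached = self._chrom_cache.get(chrom)
        if cached is None:
            sub = self.intervals[self.intervals["chrom"] == chrom]
            s = sub["start"].to_numpy(dtype=np.int64)
            e = sub["end"].to_numpy(dtype=np.int64)
            v = sub["value"].to_numpy(dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(v * (e - s))])
            cached = (s, e, v, cum)
            self._chrom_cache[chrom] = cached
        return cached

    def integral(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Cumulative signal integral F(x) over [-inf, x) at each edge."""
        s, e, v, cum = self._chrom_arrays(chrom)
        edges = np.asarray(edges, dtype=np.int64)
        if not len(s):
            return np.zeros(edges.shape, dtype=float)
        idx = np.searchsorted(s, edges, side="right") - 1
        safe = np.clip(idx, 0, len(s) - 1)
        inside = np.clip(edges - s[safe], 0, e[safe] - s[safe])
        out = cum[safe] + v[safe] * inside
        return np.where(idx >= 0, out, 0.0)


@dataclass
class PWM:
    """Position weight matrix: 4 x L probabilities, rows A, C, G, T."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise FormatError(f"PWM {self.name}: need 4 x L matrix with L >= 4")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise FormatError(f"PWM {self.name}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass
class TermSets:
    """term_id -> (term_name, gene set) mapping for over-representation tests."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise FormatError(f"term {tid} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotation(
    path: str | Path,
    biotype_map: Mapping[str, Biotype] | None = None,
) -> list[TranscriptRecord]:
    """Read transcript records from an Ensembl-dialect GTF.

    Only ``transcript`` features are used.  GTF 1-based inclusive coordinates
    become 0-based half-open.  Transcripts without a strand are rejected and
    logged; malformed lines raise :class:`FormatError` naming the line.
    """
    if biotype_map is None:
        biotype_map = DEFAULT_BIOTYPE_MAP
    records: list[TranscriptRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            (_, _, feature, start_s, end_s, _, strand, _, attrs_s) = fields
            if feature != "transcript":
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_gtf_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}: line {lineno}: missing transcript_id")
            if strand not in ("+", "-"):
                log.warning(
                    "%s: line %d: transcript %s has no strand, rejected",
                    path,
                    lineno,
                    tid,
                )
                continue
            raw_biotype = (
                attrs.get("transcript_biotype")
                or attrs.get("gene_biotype")
                or attrs.get("biotype")
                or ""
            )
            records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_id=attrs.get("gene_id", tid),
                    biotype=biotype_map.get(raw_biotype, Biotype.other_ncRNA),
                    chrom=fields[0],
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                )
            )
    return records


def write_annotation(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcript records as Ensembl-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for r in records:
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                f'transcript_biotype "{r.biotype.value}";'
            )
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        "gametrace",
                        "transcript",
                        str(r.start + 1),
                        str(r.end),
                        ".",
                        r.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed6(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.transcript_id}\t.\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# Expression TSV + sample sheet


def read_expression(
    matrix_path: str | Path, sheet_path: str | Path
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Read a TPM TSV (first column transcript_id) and its sample sheet."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    sheet = SampleSheet(pd.read_csv(sheet_path, sep="\t", dtype=str))
    missing = [s for s in df.columns if s not in set(sheet.sample_ids)]
    if missing:
        raise FormatError(f"samples missing from sheet: {missing}")
    return ExpressionMatrix(df), sheet


def write_expression(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    matrix_path: str | Path,
    sheet_path: str | Path,
) -> None:
    expr.df.to_csv(matrix_path, sep="\t", index_label="transcript_id")
    sheet.df.to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coverage (bedGraph, plus a minimal fixedStep dialect)


def _read_fixedstep(path: str | Path) -> pd.DataFrame:
    rows: list[tuple[str, int, int, float]] = []
    chrom, pos, step, span = None, 0, 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv["step"])
                span = int(kv.get("span", step))
                continue
            if chrom is None:
                raise FormatError(f"{path}: line {lineno}: data before fixedStep header")
            try:
                value = float(line)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric value") from exc
            rows.append((chrom, pos, pos + span, value))
            pos += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_coverage(path: str | Path, mark: str, compartment: str) -> CoverageTrack:
    """Read a 4-column bedGraph (or fixedStep wiggle) into a CoverageTrack."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("fixedStep"):
        df = _read_fixedstep(path)
    else:
        try:
            df = pd.read_csv(
                path,
                sep=r"\s+",
                header=None,
                comment="#",
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"{path}: not parseable as bedGraph: {exc}") from exc
        if df.empty:
            df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        else:
            for col in ("start", "end", "value"):
                converted = pd.to_numeric(df[col], errors="coerce")
                if converted.isna().any():
                    bad = int(np.argmax(converted.isna().to_numpy())) + 1
                    raise FormatError(f"{path}: line {bad}: non-numeric {col}")
                df[col] = converted
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
    return CoverageTrack(mark=mark, compartment=compartment, intervals=df)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


# ---------------------------------------------------------------------------
# PWMs (JASPAR-style) and GMT term sets

PSEUDOCOUNT = 0.5


def read_pwms(path: str | Path, pseudocount: float = PSEUDOCOUNT) -> list[PWM]:
    """Read JASPAR-style count blocks into probability PWMs.

    Counts get ``pseudocount`` added per cell, then each column is
    normalized to sum to 1.
    """
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms: list[PWM] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        colsums = counts.sum(axis=0)
        if (colsums == 0).any():
            raise FormatError(f"PWM {m.name}: column with zero total count")
        probs = (counts + pseudocount) / (colsums + 4 * pseudocount)
        name = m.name or m.matrix_id
        pwms.append(PWM(name=str(name), matrix=probs))
    return pwms


def write_pwms(
    pwms: Iterable[PWM], path: str | Path, counts_scale: float = 100.0
) -> None:
    """Write PWMs as JASPAR-style blocks (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.name}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(
                    f"{v * counts_scale:.4f}" for v in pwm.matrix[i]
                )
                fh.write(f"{base} [ {vals} ]\n")


def read_gmt(path: str | Path) -> TermSets:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT needs term, description, >=1 gene"
                )
            tid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: term {tid} has no genes")
            terms[tid] = (desc, frozenset(genes))
    return TermSets(terms)


def write_gmt(term_sets: TermSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, genes) in term_sets:
            fh.write("\t".join([tid, desc or ".", *sorted(genes)]) + "\n")
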