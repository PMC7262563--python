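"""Stage-ordered expression dynamics: log/Z transforms and trajectory calls.

Stage grids carry the organism's ordered developmental stages and its
zygotic-genome-activation (ZGA) window — the four-to-eight-cell transition
in human, two-to-four-cell in mouse.  Trajectory calling classifies each
transcript's stage-mean profile into a closed five-pattern vocabulary:

* ``zga_activated`` — silent before the ZGA window, activated from it on;
* ``early_then_degraded`` — present through the early stages and then
  monotonically declining from ZGA onset (the maternal/paternal transcript
  degradation pattern);
* ``flat_on`` / ``flat_off`` — always above / below the expression
  threshold without substantial fold change;
* ``other`` — anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleSheet

__all__ = [
    "StageGrid",
    "HUMAN_PREIMPLANTATION",
    "MOUSE_PREIMPLANTATION",
    "SPERMATOGENESIS",
    "TrajectoryCall",
    "log_transform",
    "zscore_rows",
    "aggregate_stages",
    "call_trajectory",
    "panel_specificity",
]

PATTERNS = ("zga_activated", "early_then_degraded", "flat_on", "flat_off", "other")


@dataclass(frozen=True)
class StageGrid:
    """Ordered stage tokens for one organism, with an optional ZGA window."""

    organism: str
    stages: tuple[str, ...]
    zga_window: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage tokens must be unique")
        if self.zga_window is not None:
            a, b = self.zga_window
            if a not in self.stages or b not in self.stages:
                raise ValueError("ZGA window stages must be in the grid")
            if self.stages.index(a) >= self.stages.index(b):
                raise ValueError("ZGA window must be ordered")

    @property
    def zga_start_index(self) -> int:
        if self.zga_window is None:
            raise ValueError(f"{self.organism} grid has no ZGA window")
        return self.stages.index(self.zga_window[0])


HUMAN_PREIMPLANTATION = StageGrid(
    organism="human",
    stages=("zygote", "2cell", "4cell", "8cell", "morula", "late_blastocyst"),
    zga_window=("4cell", "8cell"),
)

MOUSE_PREIMPLANTATION = StageGrid(
    organism="mouse",
    stages=("zygote", "2cell", "4cell", "8cell", "morula", "late_blastocyst"),
    zga_window=("2cell", "4cell"),
)

SPERMATOGENESIS = StageGrid(
    organism="human",
    stages=(
        "A_dark",
        "A_pale",
        "leptotene_zygotene",
        "early_pachytene",
        "late_pachytene",
        "round_spermatid",
    ),
)


def log_transform(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(TPM + 1)."""
    df = expr.df if isinstance(expr, ExpressionMatrix) else expr
    if (df.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return np.log2(df + 1.0)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z score with sample (n-1) standard deviation.

    Constant rows become all zeros rather than NaN so heatmap exports stay
    finite.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z scoring needs >= 2 columns")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    # rows constant up to float rounding (sd ~ eps*|mu|) count as constant,
    # otherwise the rounding residue itself would be standardized to +-1
    degenerate = sd <= 1e-12 * np.maximum(np.abs(mu), 1.0)
    z = np.divide(x - mu, sd, out=np.zeros_like(x), where=~degenerate)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def aggregate_stages(
    expr: ExpressionMatrix, sheet: SampleSheet, grid: StageGrid
) -> pd.DataFrame:
    """Mean TPM across replicates per stage, columns ordered by the grid."""
    cols = {}
    for stage in grid.stages:
        samples = [s for s in sheet.samples(stage) if s in expr.df.columns]
        if not samples:
            raise ValueError(f"stage {stage} has no samples")
        cols[stage] = expr.df[samples].mean(axis=1)
    return pd.DataFrame(cols)[list(grid.stages)]


@dataclass
class TrajectoryCall:
    """Per-transcript trajectory pattern, peak stage and specificity flag."""

    df: pd.DataFrame  # index transcript_id; pattern, peak_stage, stage_specific
    z: pd.DataFrame = field(repr=False, default=None)

    @property
    def pattern(self) -> pd.Series:
        return self.df["pattern"]

    def to_tsv(self, path) -> None:
        out = self.df.join(self.z.add_prefix("z_"))
        out.to_csv(path, sep="\t", index_label="transcript_id")


def _stage_specific(z: np.ndarray, peak_z: float = 1.5, other_z: float = 0.5) -> np.ndarray:
    """A transcript is stage-specific when its peak Z reaches ``peak_z`` and
    every other stage stays below ``other_z``."""
    order = np.argsort(z, axis=1)
    best = z[np.arange(len(z)), order[:, -1]]
    second = z[np.arange(len(z)), order[:, -2]]
    return (best >= peak_z) & (second < other_z)


def call_trajectory(
    stage_means: pd.DataFrame,
    grid: StageGrid,
    threshold: float = 1.0,
    fold: float = 2.0,
    decline_tolerance: float = 0.10,
    peak_z: float = 1.5,
    other_z: float = 0.5,
) -> TrajectoryCall:
    """Classify stage-mean TPM profiles into the five-pattern vocabulary.

    Flat patterns use a max/min fold-ratio on TPM+1 (pseudocount keeps the
    ratio defined near zero).  The decline check allows consecutive stage
    means to rise by at most ``decline_tolerance`` (relative) from ZGA
    onset.
    """
    if list(stage_means.columns) != list(grid.stages):
        raise ValueError("stage_means columns must match the grid order")
    if len(grid.stages) < 4:
        raise ValueError("grid must have >= 4 stages")
    zga = grid.zga_start_index

    x = stage_means.to_numpy(dtype=float)
    n = x.shape[0]
    pre = x[:, :zga]  # strictly before ZGA onset
    early = x[:, : zga + 1]  # up to and including ZGA onset
    from_zga = x[:, zga:]

    zga_activated = (pre < threshold).all(axis=1) & (
        from_zga.max(axis=1) >= threshold * fold
    )

    max_early = early.max(axis=1)
    ratios = from_zga[:, 1:] / np.maximum(from_zga[:, :-1], 1e-12)
    non_increasing = (ratios <= 1.0 + decline_tolerance).all(axis=1)
    early_then_degraded = (
        (early >= threshold).all(axis=1)
        & (x[:, -1] <= max_early / fold)
        & non_increasing
    )

    ratio_flat = (x.max(axis=1) + 1.0) / (x.min(axis=1) + 1.0)
    flat_on = (x >= threshold).all(axis=1) & (ratio_flat < fold)
    flat_off = (x < threshold).all(axis=1) & (ratio_flat < fold)

    pattern = np.full(n, "other", dtype=object)
    for name, mask in [
        ("flat_off", flat_off),
        ("flat_on", flat_on),
        ("early_then_degraded", early_then_degraded),
        ("zga_activated", zga_activated),
    ]:
        pattern[mask] = name

    z = zscore_rows(np.log2(stage_means + 1.0))
    peak_stage = stage_means.columns.to_numpy()[x.argmax(axis=1)]
    specific = _stage_specific(z.to_numpy(), peak_z, other_z)

    df = pd.DataFrame(
        {"pattern": pattern, "peak_stage": peak_stage, "stage_specific": specific},
        index=stage_means.index,
    )
    return TrajectoryCall(df, z)


def panel_specificity(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    panel: list[str],
    peak_z: float = 1.5,
    other_z: float = 0.5,
) -> pd.DataFrame:
    """Row Z across a compartment panel: argmax compartment and specificity.

    The specificity rule matches trajectory calling: peak Z >= ``peak_z``
    with every other panel member below ``other_z``.
    """
    if len(panel) < 2:
        raise ValueError("panel needs >= 2 compartments")
    cols = {}
    for comp in panel:
        samples = [s for s in sheet.samples(comp) if s in expr.df.columns]
        if not samples:
            raise ValueError(f"panel compartment {comp} has no samples")
        cols[comp] = expr.df[samples].mean(axis=1)
    means = pd.DataFrame(cols)[panel]
    z = zscore_rows(np.log2(means + 1.0))
    zx = z.to_numpy()
    out = pd.DataFrame(
        {
            "peak_compartment": means.columns.to_numpy()[zx.argmax(axis=1)],
            "peak_z": zx.max(axis=1),
            "specific": _stage_specific(zx, peak_z, other_z),
        },
        index=means.index,
    )
    return out.join(z.add_prefix("z_"))
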