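"""Partition transcripts into Sp / Oc / SpOc / Misc / NotExpressed.

A transcript is *consistently* expressed in a gamete when every donor
replicate of that gamete reaches the TPM threshold, and *absent* when no
replicate does.  Sperm-specific (Sp) means consistent in sperm and absent in
oocyte; oocyte-specific (Oc) the mirror image; SpOc consistent in both;
NotExpressed absent in both.  Any strict partial replicate pattern in either
gamete — inconsistent expression between donors — makes the transcript
miscellaneous (Misc), which downstream stages exclude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleSheet

__all__ = [
    "GameteClassification",
    "call_expressed",
    "classify_gamete",
    "category_expression_summary",
]

CATEGORIES = ("Sp", "Oc", "SpOc", "Misc", "NotExpressed")


@dataclass
class GameteClassification:
    """Per-transcript category plus expressed-replicate counts per gamete."""

    df: pd.DataFrame  # index transcript_id; columns category,
    # sperm_expressed_reps, sperm_total_reps, oocyte_expressed_reps, oocyte_total_reps

    @property
    def category(self) -> pd.Series:
        return self.df["category"]

    def transcripts(self, category: str) -> list[str]:
        return list(self.df.index[self.df["category"] == category])

    def counts(self) -> pd.Series:
        return self.df["category"].value_counts().reindex(CATEGORIES, fill_value=0)

    def to_tsv(self, path, biotypes: pd.Series | None = None) -> None:
        out = self.df.copy()
        if biotypes is not None:
            out.insert(0, "biotype", biotypes.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="transcript_id")


def call_expressed(expr: ExpressionMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean transcripts x samples matrix: TPM >= threshold."""
    if threshold <= 0:
        raise ValueError("expression threshold must be > 0")
    return expr.df >= threshold


def classify_gamete(
    flags: pd.DataFrame,
    sheet: SampleSheet,
    sperm_compartment: str = "sperm",
    oocyte_compartment: str = "oocyte",
    min_fraction: float = 1.0,
) -> GameteClassification:
    """Apply the replicate-consistency rule to expressed/absent flags.

    ``min_fraction`` relaxes "all replicates" to "at least this fraction";
    the default 1.0 is the strict all-donors rule.  Absence always means no
    replicate expressed.
    """
    sp_samples = [s for s in sheet.samples(sperm_compartment) if s in flags.columns]
    oc_samples = [s for s in sheet.samples(oocyte_compartment) if s in flags.columns]
    if not sp_samples or not oc_samples:
        raise ValueError(
            f"need >=1 sample for both gametes; got sperm={len(sp_samples)}, "
            f"oocyte={len(oc_samples)}"
        )

    sp_n = flags[sp_samples].sum(axis=1).to_numpy()
    oc_n = flags[oc_samples].sum(axis=1).to_numpy()
    n_sp, n_oc = len(sp_samples), len(oc_samples)

    sp_consistent = sp_n >= np.ceil(min_fraction * n_sp)
    oc_consistent = oc_n >= np.ceil(min_fraction * n_oc)
    sp_absent = sp_n == 0
    oc_absent = oc_n == 0

    category = np.full(len(flags), "Misc", dtype=object)
    category[sp_consistent & oc_absent] = "Sp"
    category[oc_consistent & sp_absent] = "Oc"
    category[sp_consistent & oc_consistent] = "SpOc"
    category[sp_absent & oc_absent] = "NotExpressed"

    df = pd.DataFrame(
        {
            "category": category,
            "sperm_expressed_reps": sp_n,
            "sperm_total_reps": n_sp,
            "oocyte_expressed_reps": oc_n,
            "oocyte_total_reps": n_oc,
        },
        index=flags.index,
    )
    return GameteClassification(df)


def category_expression_summary(
    expr: ExpressionMatrix,
    classification: GameteClassification,
    sheet: SampleSheet,
    biotypes: pd.Series | None = None,
    compartments: list[str] | None = None,
) -> pd.DataFrame:
    """Distribution summaries of log2(TPM+1) per (category x biotype x compartment).

    Returns median, quartiles and whisker range (1.5 IQR convention, clipped
    to the data), with n=0 rows carrying missing summaries.
    """
    if compartments is None:
        compartments = sorted(set(sheet.df["compartment"]))
    logx = np.log2(expr.df + 1.0)
    cats = classification.category.reindex(expr.df.index)
    if biotypes is None:
        biotypes = pd.Series("all", index=expr.df.index)
    else:
        biotypes = biotypes.reindex(expr.df.index)

    rows = []
    for category in sorted(cats.dropna().unique()):
        for biotype in sorted(biotypes.dropna().unique()):
            sel = (cats == category) & (biotypes == biotype)
            for compartment in compartments:
                samples = [s for s in sheet.samples(compartment) if s in logx.columns]
                if not samples:
                    continue
                vals = logx.loc[sel, samples].to_numpy().ravel()
                if vals.size == 0:
                    rows.append(
                        dict(
                            category=category,
                            biotype=biotype,
                            compartment=compartment,
                            n=0,
                            q1=np.nan,
                            median=np.nan,
                            q3=np.nan,
                            lo_whisker=np.nan,
                            hi_whisker=np.nan,
                        )
                    )
                    continue
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                iqr = q3 - q1
                lo = float(vals[vals >= q1 - 1.5 * iqr].min())
                hi = float(vals[vals <= q3 + 1.5 * iqr].max())
                rows.append(
                    dict(
                        category=category,
                        biotype=biotype,
                        compartment=compartment,
                        n=int(sel.sum()),
                        q1=q1,
                        median=med,
                        q3=q3,
                        lo_whisker=lo,
                        hi_whisker=hi,
                    )
                )
    return pd.DataFrame(rows)
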