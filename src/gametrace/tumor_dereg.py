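"""Tumor-vs-normal deregulation scoring per gene per cancer type.

All effect sizes work on log2(TPM+1).  The per-gene Z score uses a
Welch-style pooled standard error (cohort sizes between tumor panels and
fallback normals are highly unequal), the log fold change is the difference
of cohort means, and the significance call combines a tie-corrected
rank-sum test with BH-FDR within each cancer code and an absolute
fold-change gate: ``up``/``down`` require FDR < alpha and |log2FC| >=
lfc_min.  Pan-cancer deregulation counts the codes where a gene is called
either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleSheet

__all__ = [
    "DeregulationTable",
    "cohort_zscore",
    "log_fold_change",
    "deregulation_call",
    "normal_source_merge",
    "pan_cancer_summary",
]


def _cohorts(
    expr: ExpressionMatrix, sheet: SampleSheet, cancer_code: str, min_n: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    tumor = [s for s in sheet.samples(f"tumor:{cancer_code}") if s in expr.df.columns]
    normal = [s for s in sheet.samples(f"normal:{cancer_code}") if s in expr.df.columns]
    if len(tumor) < min_n or len(normal) < min_n:
        raise ValueError(
            f"{cancer_code}: need >= {min_n} tumor and normal samples, "
            f"got {len(tumor)}/{len(normal)}"
        )
    logx = np.log2(expr.df + 1.0)
    return logx[tumor], logx[normal]


def cohort_zscore(
    expr: ExpressionMatrix, sheet: SampleSheet, cancer_code: str
) -> pd.Series:
    """Per-gene Z = (mean_tumor - mean_normal) / sqrt(s_t^2/n_t + s_n^2/n_n)."""
    t, n = _cohorts(expr, sheet, cancer_code)
    mt, mn = t.mean(axis=1), n.mean(axis=1)
    vt = t.var(axis=1, ddof=1) / t.shape[1]
    vn = n.var(axis=1, ddof=1) / n.shape[1]
    se = np.sqrt(vt + vn)
    z = (mt - mn) / se.replace(0.0, np.nan)
    return z.fillna(0.0).rename("z")


def log_fold_change(
    expr: ExpressionMatrix, sheet: SampleSheet, cancer_code: str
) -> pd.Series:
    """Per-gene mean log2(TPM+1) difference, tumor minus normal."""
    t, n = _cohorts(expr, sheet, cancer_code)
    return (t.mean(axis=1) - n.mean(axis=1)).rename("log2fc")


@dataclass
class DeregulationTable:
    """Per (gene x cancer code) scores and calls, plus pan-cancer counts."""

    df: pd.DataFrame  # gene_id, cancer_code, n_tumor, n_normal,
    # normal_provenance, log2fc, z, p, fdr, call

    def pan_cancer_counts(self) -> pd.Series:
        calls = self.df[self.df["call"] != "none"]
        counts = calls.groupby("gene_id").size()
        genes = self.df["gene_id"].unique()
        return counts.reindex(genes, fill_value=0).rename("pan_cancer_count")

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def deregulation_call(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    codes: list[str],
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    provenance: dict[str, str] | None = None,
) -> DeregulationTable:
    """Rank-sum test tumor vs normal per gene, BH-FDR within each code.

    ``call`` is up/down when FDR < alpha and |log2fc| clears lfc_min, else
    none.
    """
    if not codes:
        raise ValueError("empty cancer code list")
    provenance = provenance or {}
    frames = []
    for code in codes:
        t, n = _cohorts(expr, sheet, code)
        tx, nx = t.to_numpy(), n.to_numpy()
        # tie-corrected normal approximation, two-sided
        res = mannwhitneyu(tx, nx, axis=1, alternative="two-sided", method="asymptotic")
        p = res.pvalue
        lfc = tx.mean(axis=1) - nx.mean(axis=1)
        vt = tx.var(axis=1, ddof=1) / tx.shape[1]
        vn = nx.var(axis=1, ddof=1) / nx.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(vt + vn > 0, lfc / np.sqrt(vt + vn), 0.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        call = np.where(
            (fdr < alpha) & (lfc >= lfc_min),
            "up",
            np.where((fdr < alpha) & (lfc <= -lfc_min), "down", "none"),
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": expr.df.index,
                    "cancer_code": code,
                    "n_tumor": tx.shape[1],
                    "n_normal": nx.shape[1],
                    "normal_provenance": provenance.get(code, "matched"),
                    "log2fc": lfc,
                    "z": z,
                    "p": p,
                    "fdr": fdr,
                    "call": call,
                }
            )
        )
    return DeregulationTable(pd.concat(frames, ignore_index=True))


def normal_source_merge(
    sheet: SampleSheet,
    fallback_normals: SampleSheet,
    codes: list[str],
    min_n: int = 2,
) -> tuple[SampleSheet, dict[str, str], list[str]]:
    """Attach fallback normal cohorts to codes lacking matched normals.

    Returns the augmented sheet, a per-code provenance map
    (``matched``/``fallback``), and the codes excluded for having neither.
    """
    provenance: dict[str, str] = {}
    excluded: list[str] = []
    extra_rows = []
    for code in codes:
        matched = sheet.samples(f"normal:{code}")
        if len(matched) >= min_n:
            provenance[code] = "matched"
            continue
        fallback = fallback_normals.df[
            fallback_normals.df["compartment"] == f"normal:{code}"
        ]
        if len(fallback) >= min_n:
            provenance[code] = "fallback"
            extra_rows.append(fallback)
        else:
            excluded.append(code)
    if excluded:
        import logging

        logging.getLogger(__name__).warning(
            "codes excluded for lacking normals: %s", excluded
        )
    df = sheet.df
    if extra_rows:
        df = pd.concat([df, *extra_rows], ignore_index=True)
    return SampleSheet(df), provenance, excluded


def pan_cancer_summary(table: DeregulationTable) -> pd.DataFrame:
    """Per-gene number of codes tested and codes with a deregulation call."""
    tested = table.df.groupby("gene_id")["cancer_code"].nunique()
    counts = table.pan_cancer_counts()
    return pd.DataFrame(
        {"n_codes_tested": tested, "pan_cancer_count": counts}
    ).reset_index(names="gene_id")
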